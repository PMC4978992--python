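"""Occurrence reading, filtering, and time-binning."""

import numpy as np
import pandas as pd
import pytest

from paleorange import occurrences as occ
from conftest import make_occurrence_frame


def write_csv(tmp_path, df, name="occ.csv"):
    p = tmp_path / name
    df.to_csv(p, index=False)
    return p


class TestRead:
    def test_three_valid_rows_give_three_records(self, tmp_path):
        df = make_occurrence_frame(
            [("Acme alpha", 10, 20, 5, 7), ("Acme beta", 11, 21, 5, 7), ("Acme alpha", 12, 19, 6, 8)]
        )
        ds = occ.read_occurrences(write_csv(tmp_path, df))
        assert len(ds.records) == 3
        assert ds.clade_id == "TestClade"

    def test_inverted_age_interval_rejected_and_logged(self, tmp_path):
        df = make_occurrence_frame([("Acme alpha", 10, 20, 5, 7), ("Acme beta", 11, 21, 9, 4)])
        ds = occ.read_occurrences(write_csv(tmp_path, df))
        assert len(ds.records) == 1
        assert any("rejected 1" in line for line in ds.provenance)

    def test_dialect_mapping_matches_canonical_order(self, tmp_path):
        df = make_occurrence_frame([("Acme alpha", 10, 20, 5, 7), ("Acme beta", 11, 21, 5, 7)])
        permuted = df[["max_ma", "species", "paleo_lat", "clade", "min_ma", "genus", "paleo_lng"]]
        permuted = permuted.rename(
            columns={"species": "accepted_name", "paleo_lng": "paleolng", "paleo_lat": "paleolat"}
        )
        dialect = {"accepted_name": "species", "paleolng": "paleo_lng", "paleolat": "paleo_lat"}
        a = occ.read_occurrences(write_csv(tmp_path, df, "a.csv"))
        b = occ.read_occurrences(write_csv(tmp_path, permuted, "b.csv"), dialect=dialect)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_missing_column_names_the_column(self, tmp_path):
        df = make_occurrence_frame([("Acme alpha", 10, 20, 5, 7)]).drop(columns=["min_ma"])
        with pytest.raises(occ.OccurrenceError, match="min_ma"):
            occ.read_occurrences(write_csv(tmp_path, df))

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("species,genus,clade,paleo_lng,paleo_lat,min_ma,max_ma\n")
        with pytest.raises(occ.OccurrenceError):
            occ.read_occurrences(p)


class TestOpenNomenclature:
    def test_sp_marker_removed(self):
        ds = occ.dataset_from_frame(
            make_occurrence_frame([("Acme alpha", 0, 0, 1, 2), ("Acme sp.", 1, 1, 1, 2)])
        )
        out = occ.filter_open_nomenclature(ds)
        assert set(out.records["species"]) == {"Acme alpha"}

    def test_clean_names_unchanged(self):
        ds = occ.dataset_from_frame(
            make_occurrence_frame([("Acme alpha", 0, 0, 1, 2), ("Belle beta", 1, 1, 1, 2)])
        )
        out = occ.filter_open_nomenclature(ds)
        assert len(out.records) == len(ds.records)

    def test_mixed_markers_all_flagged_species_removed(self):
        names = ["Acme alpha", "Acme cf. alpha", "Belle aff. beta", "Cara ?", "Dora indet.", "Eve spp."]
        ds = occ.dataset_from_frame(make_occurrence_frame([(n, 0, 0, 1, 2) for n in names]))
        # independent scan: a name is open nomenclature iff any post-genus
        # token is in the marker set
        expected_removed = {
            n for n in names if any(t in occ.OPEN_NOMENCLATURE_MARKERS for t in n.split()[1:])
        }
        out = occ.filter_open_nomenclature(ds)
        assert set(ds.records["species"]) - set(out.records["species"]) == expected_removed
        assert len(expected_removed) == 5


class TestContinuity:
    def _binned(self, species_bins):
        rows = []
        scheme = occ.make_scheme("TestClade", 30.0, 0.0, 5.0)
        for sp, bins in species_bins.items():
            for b in bins:
                mid = scheme.bin_midpoints[b]
                rows.append((sp, 0.0, 0.0, mid, mid))
        ds = occ.dataset_from_frame(make_occurrence_frame(rows), planar=True)
        return occ.assign_to_bins(ds, scheme)

    def test_contiguous_bins_retained(self):
        ds = self._binned({"Acme alpha": [5, 4, 3]})
        out = occ.filter_stratigraphic_continuity(ds)
        assert set(out.records["species"]) == {"Acme alpha"}

    def test_gap_removed_under_strict_rule(self):
        ds = self._binned({"Acme alpha": [5, 3]})
        out = occ.filter_stratigraphic_continuity(ds, max_gap_bins=0)
        assert len(out.records) == 0

    def test_gap_tolerated_when_allowed(self):
        ds = self._binned({"Acme alpha": [5, 3]})
        out = occ.filter_stratigraphic_continuity(ds, max_gap_bins=1)
        assert set(out.records["species"]) == {"Acme alpha"}

    def test_random_occupancy_matches_bruteforce_gap_scan(self):
        rng = np.random.default_rng(42)
        species_bins = {}
        for i in range(30):
            bins = sorted(rng.choice(6, size=rng.integers(1, 5), replace=False))
            species_bins[f"Gen{i:02d} sp{i:02d}"] = bins
        ds = self._binned(species_bins)
        out = occ.filter_stratigraphic_continuity(ds, max_gap_bins=0, by_genus=False)

        def continuous(bins):  # brute force: every bin between min and max occupied
            return all(b in bins for b in range(min(bins), max(bins) + 1))

        expected = {sp for sp, bins in species_bins.items() if continuous(bins)}
        assert set(out.records["species"]) == expected

    def test_requires_binning(self, small_dataset):
        with pytest.raises(occ.OccurrenceError, match="binning"):
            occ.filter_stratigraphic_continuity(small_dataset)


class TestMinOccurrences:
    @pytest.mark.parametrize("n_occ,k,kept", [(9, 10, False), (10, 10, True)])
    def test_boundary(self, n_occ, k, kept):
        rows = [("Acme alpha", float(i), 0.0, 1, 2) for i in range(n_occ)]
        ds = occ.dataset_from_frame(make_occurrence_frame(rows), planar=True)
        out = occ.filter_min_total_occurrences(ds, k)
        assert ("Acme alpha" in set(out.records["species"])) is kept

    def test_k1_is_identity(self, small_dataset):
        out = occ.filter_min_total_occurrences(small_dataset, 1)
        assert len(out.records) == len(small_dataset.records)


class TestBinning:
    def test_shortest_satisfying_candidate_wins(self, small_dataset):
        # 5-Myr bins hold 3 species x 3 occurrences each; 2-Myr bins split
        # species across bins leaving <3 occurrences per species per bin
        scheme = occ.choose_bin_length(small_dataset, [2.0, 5.0])
        assert scheme.bin_length == 5.0
        for b in range(scheme.n_bins):  # every bin satisfies the 3x3 rule
            sub = small_dataset.records[
                [(scheme.bin_of((r.min_ma + r.max_ma) / 2) == b) for r in small_dataset.records.itertuples()]
            ]
            per_species = sub.groupby("species").size()
            assert (per_species >= 3).sum() >= 3

    def test_single_candidate_returned(self, small_dataset):
        assert occ.choose_bin_length(small_dataset, [5.0]).bin_length == 5.0

    def test_no_valid_candidate_flagged(self):
        rows = [("Acme alpha", float(i), 0.0, 0.5, 1.5) for i in range(3)]
        rows += [("Acme beta", float(i), 1.0, 14.5, 15.5) for i in range(3)]
        ds = occ.dataset_from_frame(make_occurrence_frame(rows), planar=True)
        occ.choose_bin_length(ds, [5.0, 10.0])
        assert any("WARNING" in line for line in ds.provenance)

    def test_empty_candidates_rejected(self, small_dataset):
        with pytest.raises(occ.OccurrenceError):
            occ.choose_bin_length(small_dataset, [])

    def test_midpoint_assignment_arithmetic(self):
        scheme = occ.BinningScheme("TestClade", 5.0, np.array([15.0, 10.0, 5.0]))
        ds = occ.dataset_from_frame(
            make_occurrence_frame([("Acme alpha", 0, 0, 10.0, 12.0)]), planar=True
        )
        out = occ.assign_to_bins(ds, scheme)  # midpoint 11 -> [15, 10)
        assert out.records["bin"].tolist() == [0]

    def test_edge_age_goes_to_younger_bin(self):
        scheme = occ.BinningScheme("TestClade", 5.0, np.array([15.0, 10.0, 5.0]))
        ds = occ.dataset_from_frame(
            make_occurrence_frame([("Acme alpha", 0, 0, 9.0, 11.0)]), planar=True
        )
        out = occ.assign_to_bins(ds, scheme)  # midpoint exactly 10 -> [10, 5)
        assert out.records["bin"].tolist() == [1]

    def test_random_draw_deterministic(self, small_dataset):
        # cover the full min/max age envelope, not just the midpoints
        scheme = occ.make_scheme("TestClade", 15.0, 0.0, 5.0)
        a = occ.assign_to_bins(small_dataset, scheme, mode="random-draw", seed=7)
        b = occ.assign_to_bins(small_dataset, scheme, mode="random-draw", seed=7)
        assert a.records["bin"].tolist() == b.records["bin"].tolist()

    def test_out_of_span_occurrence_names_record(self, small_dataset):
        scheme = occ.BinningScheme("TestClade", 1.0, np.array([2.0, 1.0]))
        with pytest.raises(occ.OccurrenceError, match="Acme"):
            occ.assign_to_bins(small_dataset, scheme)


class TestInvariants:
    def test_filters_commute_with_row_order(self, small_dataset):
        rng = np.random.default_rng(0)
        shuffled = occ.CladeDataset(
            small_dataset.clade_id,
            small_dataset.records.sample(frac=1, random_state=rng.integers(1 << 30)).reset_index(
                drop=True
            ),
        )
        a = occ.filter_min_total_occurrences(occ.filter_open_nomenclature(small_dataset), 3)
        b = occ.filter_min_total_occurrences(occ.filter_open_nomenclature(shuffled), 3)
        assert set(a.records["species"]) == set(b.records["species"])

    def test_per_bin_counts_conserve_total(self, small_dataset):
        scheme = occ.choose_bin_length(small_dataset, [5.0])
        binned = occ.assign_to_bins(small_dataset, scheme)
        assert binned.records.groupby("bin").size().sum() == len(binned.records)
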