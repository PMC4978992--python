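"""Reading, validation, filtering, and time-binning of fossil occurrence data.

Occurrence tables follow the Paleobiology Database download convention: one
row per fossil find with a species name, clade, paleocoordinates (degrees),
and a minimum/maximum age of the fossil locality (Ma). Canonical column
names are ``species, genus, clade, paleo_lng, paleo_lat, min_ma, max_ma``;
a dialect mapping adapts other headers.

Bins are equal-length intervals of the clade's record, ordered oldest to
youngest, half-open toward the present: an occurrence of age ``a`` falls in
bin ``i`` when ``older_edge >= a > younger_edge`` except the oldest bin,
which is closed on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = ("species", "genus", "clade", "paleo_lng", "paleo_lat", "min_ma", "max_ma")
REQUIRED_COLUMNS = ("species", "clade", "paleo_lng", "paleo_lat", "min_ma", "max_ma")

#: Epithet markers flagging open nomenclature (uncertain taxonomic assignment).
OPEN_NOMENCLATURE_MARKERS = frozenset({"sp.", "spp.", "cf.", "aff.", "?", "indet."})

#: Candidate bin lengths (Myr) tried when none are supplied.
DEFAULT_CANDIDATE_BIN_LENGTHS = (1.0, 2.0, 2.5, 5.0, 10.0)


class OccurrenceError(ValueError):
    """Malformed occurrence data or configuration."""


@dataclass(frozen=True)
class BinningScheme:
    """Equal-length time bins for one clade, oldest first.

    ``bin_edges`` are ages in Ma, strictly decreasing toward the present;
    bin ``i`` spans ``[bin_edges[i], bin_edges[i+1])``.
    """

    clade_id: str
    bin_length: float
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.ndim != 1 or len(edges) < 2:
            raise OccurrenceError("need at least two bin edges")
        if not np.all(np.diff(edges) < 0):
            raise OccurrenceError("bin edges must strictly decrease toward the present")
        object.__setattr__(self, "bin_edges", edges)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def bin_midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def bin_of(self, age: float) -> int:
        """Bin index of an age (Ma); half-open toward the present."""
        edges = self.bin_edges
        if age > edges[0] or age < edges[-1]:
            raise OccurrenceError(f"age {age} Ma outside scheme span [{edges[-1]}, {edges[0]}]")
        if age == edges[0]:  # oldest bin closed on both ends
            return 0
        # half-open toward the present: an age equal to an interior edge
        # belongs to the younger bin starting at that edge
        idx = int(np.searchsorted(-edges, -age, side="right")) - 1
        return min(max(idx, 0), self.n_bins - 1)


@dataclass
class CladeDataset:
    """Occurrence records of one clade plus binning and a filter log.

    ``records`` is a DataFrame with the canonical columns (and ``bin`` once
    assigned). The provenance log is append-only.
    """

    clade_id: str
    records: pd.DataFrame
    binning: BinningScheme | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) and not (self.records["clade"] == self.clade_id).all():
            raise OccurrenceError("records contain a clade_id other than the dataset's")

    @property
    def n_species(self) -> int:
        return self.records["species"].nunique()

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def _derive(self, records: pd.DataFrame, message: str) -> "CladeDataset":
        out = CladeDataset(
            self.clade_id,
            records.reset_index(drop=True),
            binning=self.binning,
            provenance=list(self.provenance),
        )
        out.log(message)
        return out


def dataset_from_frame(
    raw: pd.DataFrame,
    dialect: dict[str, str] | None = None,
    clade_id: str | None = None,
    planar: bool = False,
    source: str = "<frame>",
) -> CladeDataset:
    """Validate an in-memory occurrence table into a :class:`CladeDataset`.

    ``planar=True`` marks synthetic coordinates already in km, skipping the
    degree-bounds check. Rows with unparseable coordinates or ages, ages
    with ``max_ma < min_ma``, or (in degree mode) out-of-bounds coordinates
    are rejected and counted in the provenance log, never silently dropped.
    """
    if raw.empty:
        raise OccurrenceError(f"empty occurrence table: {source}")
    if dialect:
        raw = raw.rename(columns=dialect)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise OccurrenceError(f"missing required column(s): {', '.join(missing)}")
    raw = raw.copy()
    if "genus" not in raw.columns:
        raw["genus"] = raw["species"].astype(str).str.split().str[0]
    df = raw.loc[:, list(CANONICAL_COLUMNS)].copy()
    for col in ("paleo_lng", "paleo_lat", "min_ma", "max_ma"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["species"] = df["species"].astype(str).str.strip()

    ok = (
        df[["paleo_lng", "paleo_lat", "min_ma", "max_ma"]].notna().all(axis=1)
        & (df["min_ma"] >= 0)
        & (df["max_ma"] >= df["min_ma"])
        & (df["species"].str.len() > 0)
    )
    if not planar:
        ok &= df["paleo_lng"].between(-180, 180) & df["paleo_lat"].between(-90, 90)
    n_bad = int((~ok).sum())
    if clade_id is None:
        clades = df.loc[ok, "clade"].unique()
        if len(clades) != 1:
            raise OccurrenceError(f"expected a single clade, found {sorted(map(str, clades))}")
        clade_id = str(clades[0])
    df["clade"] = clade_id
    ds = CladeDataset(clade_id, df[ok].reset_index(drop=True))
    ds.log(f"read {len(raw)} rows from {source}; rejected {n_bad} invalid row(s)")
    return ds


def read_occurrences(
    path,
    dialect: dict[str, str] | None = None,
    clade_id: str | None = None,
    planar: bool = False,
) -> CladeDataset:
    """Read an occurrence CSV into a :class:`CladeDataset`.

    ``dialect`` maps file column names to canonical names; validation and
    rejection logging as in :func:`dataset_from_frame`.
    """
    return dataset_from_frame(pd.read_csv(path), dialect, clade_id, planar, source=str(path))


def _has_open_nomenclature(species: str, markers: frozenset[str]) -> bool:
    tokens = species.split()
    return any(tok in markers for tok in tokens[1:]) or len(tokens) < 2


def filter_open_nomenclature(ds: CladeDataset, markers=OPEN_NOMENCLATURE_MARKERS) -> CladeDataset:
    """Drop species whose epithet carries an open-nomenclature marker.

    Names like ``"Acme sp."`` or ``"Acme cf. alpha"`` denote uncertain
    taxonomic assignment and are removed wholesale; removals are logged per
    species.
    """
    markers = frozenset(markers)
    flagged = sorted({s for s in ds.records["species"].unique() if _has_open_nomenclature(s, markers)})
    keep = ~ds.records["species"].isin(flagged)
    out = ds._derive(ds.records[keep], f"open-nomenclature filter removed {len(flagged)} species: {flagged}")
    return out


def _max_gap(bins: np.ndarray) -> int:
    """Largest run of empty bins strictly inside a species' occupied range."""
    occupied = np.unique(bins)
    return int(np.max(np.diff(occupied), initial=1)) - 1


def filter_stratigraphic_continuity(ds: CladeDataset, max_gap_bins: int = 0, by_genus: bool = True) -> CladeDataset:
    """Remove species (and genera) lacking a continuous stratigraphic range.

    A taxon is continuous when its occupied-bin sequence has no gap of more
    than ``max_gap_bins`` consecutive empty bins (default 0: strictly
    continuous). Requires bins to have been assigned.
    """
    if ds.binning is None or "bin" not in ds.records.columns:
        raise OccurrenceError("binning must be assigned before the continuity filter")
    rec = ds.records
    bad_species = sorted(
        sp for sp, grp in rec.groupby("species")["bin"] if _max_gap(grp.to_numpy()) > max_gap_bins
    )
    keep = ~rec["species"].isin(bad_species)
    msg = f"continuity filter (max gap {max_gap_bins} bins) removed {len(bad_species)} species"
    if by_genus and "genus" in rec.columns:
        sub = rec[keep]
        bad_genera = sorted(
            g for g, grp in sub.groupby("genus")["bin"] if _max_gap(grp.to_numpy()) > max_gap_bins
        )
        keep &= ~rec["genus"].isin(bad_genera)
        msg += f" and {len(bad_genera)} genera"
    return ds._derive(rec[keep], msg)


def filter_min_total_occurrences(ds: CladeDataset, k: int = 1) -> CladeDataset:
    """Drop species with fewer than ``k`` occurrences over the whole record.

    ``k=1`` is the identity (default pipeline); ``k=10`` reproduces the
    rare-species robustness variant.
    """
    if k < 1:
        raise OccurrenceError("k must be >= 1")
    counts = ds.records["species"].value_counts()
    bad = counts[counts < k].index
    keep = ~ds.records["species"].isin(bad)
    return ds._derive(ds.records[keep], f"min-occurrence filter (k={k}) removed {len(bad)} species")


def make_scheme(clade_id: str, oldest: float, youngest: float, bin_length: float) -> BinningScheme:
    """Equal-length scheme covering [youngest, oldest], oldest edge first."""
    n = max(1, int(np.ceil((oldest - youngest) / bin_length - 1e-9)))
    edges = oldest - bin_length * np.arange(n + 1)
    return BinningScheme(clade_id, float(bin_length), edges)


def _midpoint_ages(rec: pd.DataFrame) -> np.ndarray:
    return ((rec["min_ma"] + rec["max_ma"]) / 2.0).to_numpy()


def _count_violations(ds: CladeDataset, scheme: BinningScheme) -> int:
    """Bins spanned by the record with <3 species having >=3 occurrences."""
    ages = _midpoint_ages(ds.records)
    bins = np.array([scheme.bin_of(a) for a in ages])
    df = pd.DataFrame({"species": ds.records["species"].to_numpy(), "bin": bins})
    per = df.groupby(["bin", "species"]).size()
    good_species_per_bin = (per >= 3).groupby("bin").sum()
    spanned = range(bins.min(), bins.max() + 1)
    return sum(1 for b in spanned if good_species_per_bin.get(b, 0) < 3)


def choose_bin_length(ds: CladeDataset, candidate_lengths=DEFAULT_CANDIDATE_BIN_LENGTHS) -> BinningScheme:
    """Pick the shortest bin length keeping every bin range-estimable.

    Bins must retain at least three species with at least three occurrences
    each — the minimum to estimate a convex-hull range size. The shortest
    candidate (most bins) satisfying this everywhere wins; if none does, the
    candidate minimising the number of violating bins is returned and the
    choice is flagged in the provenance log.
    """
    cands = sorted(float(c) for c in candidate_lengths)
    if not cands:
        raise OccurrenceError("empty candidate bin-length list")
    if ds.records.empty:
        raise OccurrenceError("cannot choose a binning for an empty dataset")
    ages = _midpoint_ages(ds.records)
    oldest, youngest = float(ages.max()), float(ages.min())
    best, best_viol = None, None
    for length in cands:
        scheme = make_scheme(ds.clade_id, oldest, youngest, length)
        viol = _count_violations(ds, scheme)
        if viol == 0:
            ds.log(f"bin length {length} Myr chosen ({scheme.n_bins} bins, all bins satisfy 3x3 rule)")
            return scheme
        if best_viol is None or viol < best_viol:
            best, best_viol = scheme, viol
    ds.log(
        f"WARNING: no candidate bin length satisfies the 3x3 rule; "
        f"best effort {best.bin_length} Myr with {best_viol} violating bin(s)"
    )
    return best


def assign_to_bins(ds: CladeDataset, scheme: BinningScheme, mode: str = "midpoint", seed: int = 0) -> CladeDataset:
    """Assign each occurrence to a time bin.

    ``midpoint`` uses (min_ma+max_ma)/2; ``random-draw`` samples an age
    uniformly in [min_ma, max_ma] with the given seed. An occurrence whose
    age falls outside the scheme raises, naming the record.
    """
    rec = ds.records.copy()
    if mode == "midpoint":
        ages = _midpoint_ages(rec)
    elif mode == "random-draw":
        rng = np.random.default_rng(seed)
        ages = rng.uniform(rec["min_ma"].to_numpy(), rec["max_ma"].to_numpy())
    else:
        raise OccurrenceError(f"unknown assignment mode: {mode!r}")
    bins = np.empty(len(rec), dtype=int)
    for i, age in enumerate(ages):
        try:
            bins[i] = scheme.bin_of(float(age))
        except OccurrenceError as exc:
            raise OccurrenceError(f"record {i} ({rec['species'].iloc[i]}): {exc}") from exc
    rec["bin"] = bins
    out = CladeDataset(ds.clade_id, rec, binning=scheme, provenance=list(ds.provenance))
    out.log(f"assigned {len(rec)} occurrences to {scheme.n_bins} bins ({mode}, bin length {scheme.bin_length} Myr)")
    return out


def write_filtered(ds: CladeDataset, csv_path, log_path=None) -> None:
    """Write the filtered table and (optionally) the provenance log."""
    ds.records.to_csv(csv_path, index=False)
    if log_path is not None:
        with open(log_path, "w") as fh:
            fh.write("\n".join(ds.provenance) + "\n")
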