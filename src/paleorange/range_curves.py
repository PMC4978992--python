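"""The three range curves and the degree-of-sympatry statistic.

Per time bin: *total* range is the algebraic sum of species MCP areas,
*clade* range the area of the union of species polygons, and *average*
range the total divided by richness. Total and clade ranges accumulated
over consecutive bins (oldest → youngest) give the total and clade range
curves; the bin-wise ratio total/clade is the degree of sympatry (1 when
species ranges are pairwise disjoint, the richness when they coincide).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class CurveError(ValueError):
    """Inconsistent curve inputs."""


@dataclass(frozen=True)
class RangeCurveSet:
    """Per-bin and cumulative range statistics of one clade, oldest first."""

    clade_id: str
    bin_midpoints: np.ndarray  # Ma, decreasing (oldest -> youngest)
    richness: np.ndarray
    total_per_bin: np.ndarray  # km², Σ species MCP areas
    clade_per_bin: np.ndarray  # km², union area

    def __post_init__(self) -> None:
        arrays = {
            "bin_midpoints": np.asarray(self.bin_midpoints, dtype=float),
            "richness": np.asarray(self.richness, dtype=int),
            "total_per_bin": np.asarray(self.total_per_bin, dtype=float),
            "clade_per_bin": np.asarray(self.clade_per_bin, dtype=float),
        }
        n = {len(a) for a in arrays.values()}
        if len(n) != 1:
            raise CurveError("curve arrays must share one bin axis")
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)
        if np.any(self.clade_per_bin - self.total_per_bin > 1e-6 * np.maximum(self.total_per_bin, 1.0)):
            raise CurveError("clade (union) range exceeds total range in some bin")

    @property
    def average_per_bin(self) -> np.ndarray:
        """Mean species range per bin (km²); NaN where richness is 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.richness > 0, self.total_per_bin / np.maximum(self.richness, 1), np.nan)

    @property
    def cum_total(self) -> np.ndarray:
        return np.cumsum(self.total_per_bin)

    @property
    def cum_clade(self) -> np.ndarray:
        return np.cumsum(self.clade_per_bin)

    @property
    def sympatry_ratio(self) -> np.ndarray:
        """Degree of sympatry per bin: total/clade range; NaN for empty bins."""
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = self.total_per_bin / self.clade_per_bin
        ratio = np.where(self.clade_per_bin > 0, ratio, np.nan)
        bad = (self.clade_per_bin <= 0) & (self.total_per_bin > 0)
        if np.any(bad):
            raise CurveError("zero union area with nonzero total area (impossible state)")
        return ratio

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_mid_ma": self.bin_midpoints,
                "richness": self.richness,
                "total_km2": self.total_per_bin,
                "clade_km2": self.clade_per_bin,
                "avg_km2": self.average_per_bin,
                "cum_total_km2": self.cum_total,
                "cum_clade_km2": self.cum_clade,
                "sympatry_ratio": self.sympatry_ratio,
            }
        )


def build_curves(per_species_areas: pd.DataFrame, unions: pd.DataFrame, clade_id: str = "") -> RangeCurveSet:
    """Assemble a :class:`RangeCurveSet` from per-species-bin areas and unions.

    ``per_species_areas`` needs columns ``species, bin, bin_mid_ma,
    area_km2`` (degenerate zero-area species-bins should already be
    excluded); ``unions`` needs ``bin, clade_km2``. Bins missing from both
    tables get zeros (no species present).
    """
    if per_species_areas.empty:
        raise CurveError("no per-species areas")
    merged_bins = sorted(set(per_species_areas["bin"]) | set(unions["bin"]))
    per_bin = per_species_areas.groupby("bin").agg(
        richness=("species", "nunique"), total=("area_km2", "sum"), mid=("bin_mid_ma", "first")
    )
    uni = unions.set_index("bin")["clade_km2"]
    rows = []
    for b in merged_bins:
        if b in per_bin.index:
            r = per_bin.loc[b]
            rows.append((b, r["mid"], int(r["richness"]), float(r["total"]), float(uni.get(b, 0.0))))
        else:
            rows.append((b, np.nan, 0, 0.0, float(uni.get(b, 0.0))))
    df = pd.DataFrame(rows, columns=["bin", "mid", "richness", "total", "clade"]).sort_values(
        "mid", ascending=False
    )
    if not np.all(np.diff(df["mid"].dropna()) <= 0):
        raise CurveError("bin midpoints not aligned across inputs")
    return RangeCurveSet(
        clade_id,
        df["mid"].to_numpy(),
        df["richness"].to_numpy(),
        df["total"].to_numpy(),
        df["clade"].to_numpy(),
    )


def sympatry_series(curves: RangeCurveSet) -> tuple[np.ndarray, np.ndarray]:
    """(bin midpoints, degree of sympatry) restricted to bins with a union."""
    ratio = curves.sympatry_ratio
    mask = np.isfinite(ratio)
    return curves.bin_midpoints[mask], ratio[mask]


def average_range_series(curves: RangeCurveSet) -> tuple[np.ndarray, np.ndarray]:
    """(bin midpoints, mean species range km²) for bins with species."""
    avg = curves.average_per_bin
    mask = np.isfinite(avg)
    return curves.bin_midpoints[mask], avg[mask]


def cumulative_average_series(curves: RangeCurveSet) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative-total variant of the average range (sensitivity option)."""
    mask = curves.richness > 0
    return curves.bin_midpoints[mask], curves.cum_total[mask] / curves.richness[mask]


def plot_curves(curves: RangeCurveSet, path=None, shift_ages=()):
    """Diagnostic figure: the three range curves and the sympatry series.

    Total and clade range curves on a shared panel, average range and
    degree of sympatry below; optional vertical lines at shift ages.
    Returns the figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    mask = curves.richness > 0
    ages = curves.bin_midpoints[mask]
    fig, axes = plt.subplots(3, 1, figsize=(7, 8), sharex=True)
    axes[0].plot(ages, curves.cum_total[mask], color="forestgreen", label="total (cum.)")
    axes[0].plot(ages, curves.cum_clade[mask], color="goldenrod", label="clade (cum.)")
    axes[0].set_ylabel("range (km²)")
    axes[0].legend(frameon=False)
    a_ages, avg = average_range_series(curves)
    axes[1].plot(a_ages, avg, color="steelblue")
    axes[1].set_ylabel("avg range (km²)")
    s_ages, sym = sympatry_series(curves)
    axes[2].plot(s_ages, sym, color="firebrick")
    axes[2].set_ylabel("degree of sympatry")
    axes[2].set_xlabel("age (Ma)")
    for ax in axes:
        for s in shift_ages:
            ax.axvline(s, color="lightblue", lw=1)
    axes[2].set_xlim(max(ages) * 1.02, min(ages) * 0.98)  # oldest on the left
    fig.suptitle(curves.clade_id or "range curves")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
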