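"""Directionality tests on shifted clades and the summary report.

Four tests probe whether clade evolution splits into an expansive early
phase and a specialised late phase around a shift point:

* **area test** — the area between the cumulative total and cumulative
  clade range curves, per unit time, after versus before the shift
  (expressed as a percentage; the gap between the curves reflects range
  overlap among species);
* **slope test** — OLS regression of the average species range size on
  time restricted to post-shift bins (a significant negative slope means
  shrinking ranges toward the present);
* **net-rate test** — one-sided Mann-Whitney comparison of the per-Myr net
  diversification rates after versus before the shift;
* **binomial summaries** — across shifts and across clades, whether the
  number of compliant cases exceeds a fair-coin expectation (exact
  one-sided binomial tail at success probability 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass(frozen=True)
class AreaTestResult:
    ratio_pct: float | None  # 100 * (post gap per Myr) / (pre gap per Myr)
    defined: bool
    sympatry_increased: bool | None = None  # per-bin sympatry mean after > before


@dataclass(frozen=True)
class SlopeTestResult:
    slope: float | None  # km² per Myr of forward time
    p_value: float | None
    n_bins: int
    applicable: bool


@dataclass(frozen=True)
class SummaryEntry:
    test: str
    level: str  # "shift" or "clade"
    n_success: int
    n_trials: int

    @property
    def pct(self) -> float:
        return 100.0 * self.n_success / self.n_trials if self.n_trials else float("nan")

    @property
    def binomial_p(self) -> float:
        return binomial_tail(self.n_success, self.n_trials)


def _forward_time(ages: np.ndarray, origin_age: float) -> np.ndarray:
    return origin_age - ages


def area_test(
    ages: np.ndarray,
    cum_total: np.ndarray,
    cum_clade: np.ndarray,
    shift_age: float,
) -> AreaTestResult:
    """Post/pre per-Myr area between the two cumulative curves, as a %.

    Both curves share ``ages`` (Ma, decreasing oldest -> youngest). The gap
    ``cum_total - cum_clade`` is trapezoid-integrated over the pre-shift
    span [origin, shift] and the post-shift span [shift, end], each divided
    by its length; the result is 100 * post / pre. A zero pre-shift area
    makes the ratio undefined (flagged, not infinite).
    """
    ages = np.asarray(ages, dtype=float)
    gap = np.asarray(cum_total, dtype=float) - np.asarray(cum_clade, dtype=float)
    if not (ages[0] > shift_age > ages[-1]):
        return AreaTestResult(None, False)
    t = _forward_time(ages, ages[0])  # increasing forward time
    t_shift = ages[0] - shift_age
    gap_at_shift = float(np.interp(t_shift, t, gap))
    pre_t = np.concatenate([t[t < t_shift], [t_shift]])
    pre_g = np.concatenate([gap[t < t_shift], [gap_at_shift]])
    post_t = np.concatenate([[t_shift], t[t > t_shift]])
    post_g = np.concatenate([[gap_at_shift], gap[t > t_shift]])
    a_pre = float(np.trapezoid(pre_g, pre_t))
    a_post = float(np.trapezoid(post_g, post_t))
    t_pre = pre_t[-1] - pre_t[0]
    t_post = post_t[-1] - post_t[0]
    if a_pre <= 0 or t_pre <= 0 or t_post <= 0:
        return AreaTestResult(None, False)
    return AreaTestResult(100.0 * (a_post / t_post) / (a_pre / t_pre), True)


def classify_sympatry_increase(
    bin_ages: np.ndarray,
    sympatry: np.ndarray,
    shift_age: float,
    richness: np.ndarray | None = None,
) -> bool | None:
    """Did the mean per-bin degree of sympatry rise after the shift?

    Bins holding a single species are excluded when ``richness`` is given:
    the degree of overlap *among* species is vacuous there (the ratio is
    pinned to 1), and clade birth/terminal-collapse bins would otherwise
    dominate the comparison.
    """
    bin_ages = np.asarray(bin_ages, dtype=float)
    sympatry = np.asarray(sympatry, dtype=float)
    if richness is not None:
        keep = np.asarray(richness) >= 2
        bin_ages, sympatry = bin_ages[keep], sympatry[keep]
    before = sympatry[bin_ages > shift_age]
    after = sympatry[bin_ages < shift_age]
    if len(before) == 0 or len(after) == 0:
        return None
    return bool(np.nanmean(after) > np.nanmean(before))


def slope_test(avg_ages: np.ndarray, avg_values: np.ndarray, shift_age: float) -> SlopeTestResult:
    """OLS slope of the average range size on forward time, post-shift bins.

    Restricted to bins younger than ``shift_age``; fewer than 3 such bins
    gives a not-applicable result. The slope is per Myr of forward time,
    so negative means average ranges shrink toward the present; the
    p-value is the two-sided t-test on the slope.
    """
    avg_ages = np.asarray(avg_ages, dtype=float)
    avg_values = np.asarray(avg_values, dtype=float)
    mask = avg_ages < shift_age
    if mask.sum() < 3:
        return SlopeTestResult(None, None, int(mask.sum()), False)
    t = _forward_time(avg_ages[mask], float(np.max(avg_ages)))
    y = avg_values[mask]
    if np.allclose(y, y[0]):
        return SlopeTestResult(0.0, 1.0, int(mask.sum()), True)
    res = stats.linregress(t, y)
    return SlopeTestResult(float(res.slope), float(res.pvalue), int(mask.sum()), True)


def net_rate_wilcoxon(net_before: np.ndarray, net_after: np.ndarray) -> float:
    """One-sided Mann-Whitney p for net rates decreasing after the shift.

    Alternative: after < before. Exact null distribution for m + n <= 20
    (no ties); normal approximation with tie correction otherwise. All
    values tied gives p = 1 with a warning.
    """
    before = np.asarray(net_before, dtype=float)
    after = np.asarray(net_after, dtype=float)
    if len(before) < 2 or len(after) < 2:
        raise ValueError("need at least 2 net-rate values on each side of the shift")
    pooled = np.concatenate([before, after])
    if np.allclose(pooled, pooled[0]):
        import warnings

        warnings.warn("all net-rate values tied; Mann-Whitney p set to 1", stacklevel=2)
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(after, before, alternative="less", method=method)
    return float(res.pvalue)


def binomial_tail(n_success: int, n_trials: int, p: float = 0.5) -> float:
    """Exact one-sided binomial tail P(X >= n_success | n_trials, p)."""
    if not 0 <= n_success <= n_trials:
        raise ValueError("need 0 <= n_success <= n_trials")
    if n_trials == 0:
        return float("nan")
    return float(stats.binom.sf(n_success - 1, n_trials, p))


def binomial_summary(n_success: int, n_trials: int, test: str = "", level: str = "shift") -> SummaryEntry:
    return SummaryEntry(test, level, n_success, n_trials)


# ---------------------------------------------------------------------------
# report assembly


def summarize_report(rows: pd.DataFrame, alpha: float = ALPHA) -> list[SummaryEntry]:
    """Shift- and clade-level binomial summaries of a per-shift report table.

    ``rows`` needs columns ``clade, p_dist, area_test, net_p, slope,
    slope_p`` (one row per matched shift triple; NaN marks inapplicable
    entries). Compliance rules: p_dist < alpha; area_test < 100 (the
    convention matching increased post-shift sympatry in the printed
    tables); net_p < alpha; slope significant (slope_p < alpha) and
    negative. A clade complies with a test when at least one of its shifts
    does.
    """
    rows = rows.copy()
    compliance = pd.DataFrame(index=rows.index)
    compliance["p_dist"] = rows["p_dist"] < alpha
    compliance["area_test"] = rows["area_test"] < 100.0
    compliance["net_t"] = rows["net_p"] < alpha
    compliance["slope_test"] = (rows["slope_p"] < alpha) & (rows["slope"] < 0)
    entries = []
    for test in compliance.columns:
        ok = compliance[test].fillna(False)
        applicable = rows[_APPLICABILITY_COLUMN[test]].notna()
        entries.append(SummaryEntry(test, "shift", int((ok & applicable).sum()), int(applicable.sum())))
        by_clade = (ok & applicable).groupby(rows["clade"]).any()
        app_clade = applicable.groupby(rows["clade"]).any()
        entries.append(SummaryEntry(test, "clade", int(by_clade[app_clade].sum()), int(app_clade.sum())))
    return entries


_APPLICABILITY_COLUMN = {
    "p_dist": "p_dist",
    "area_test": "area_test",
    "net_t": "net_p",
    "slope_test": "slope_p",
}


def shift_table_counts(table2: pd.DataFrame, alpha: float = ALPHA) -> dict[str, int]:
    """Compliance tallies of a per-shift results table (table-2 layout).

    Expects columns ``clade, p_dist, area_test, net_p, slope, p_slope``
    (NaN = not applicable). Rules: coincidence at strict ``p_dist < alpha``
    (``p_dist_clades_marked`` additionally honours a ``p_dist_bold`` column
    when present, for tables whose printed marks deviate from the strict
    rule); sympatry increase as ``area_test < 100``; net-rate decrease at
    ``net_p < alpha``; slope both as significant-at-alpha and as
    significant-and-negative.
    """
    t = table2
    out = {
        "n_shifts": len(t),
        "n_clades": t["clade"].nunique(),
        "p_dist_sig": int((t["p_dist"] < alpha).sum()),
        "p_dist_clades": int((t["p_dist"] < alpha).groupby(t["clade"]).any().sum()),
        "area_lt100": int((t["area_test"] < 100).sum()),
        "area_clades": int((t["area_test"] < 100).groupby(t["clade"]).any().sum()),
        "net_sig": int((t["net_p"] < alpha).sum()),
        "net_clades": int((t["net_p"] < alpha).groupby(t["clade"]).any().sum()),
        "slope_sig": int((t["p_slope"] < alpha).sum()),
        "slope_sig_negative": int(((t["p_slope"] < alpha) & (t["slope"] < 0)).sum()),
        "slope_neg_clades": int(
            ((t["p_slope"] < alpha) & (t["slope"] < 0)).groupby(t["clade"]).any().sum()
        ),
    }
    if "p_dist_bold" in t.columns:
        out["p_dist_clades_marked"] = int(
            (t["p_dist_bold"] == 1).groupby(t["clade"]).any().sum()
        )
    return out


def gamma_table_counts(table4: pd.DataFrame) -> dict[str, int]:
    """Significant-correlation tallies of a covariate-model summary table.

    Expects per-clade posterior means and 95% CI bounds for gamma_lambda
    and gamma_mu. A correlation is significant when its CI excludes 0;
    compliance is a significant *negative* speciation correlation or a
    significant *positive* extinction correlation.
    """
    t = table4
    lam_sig_neg = (t["gamma_lambda_hi"] < 0) & (t["gamma_lambda_mean"] < 0)
    mu_sig_pos = (t["gamma_mu_lo"] > 0) & (t["gamma_mu_mean"] > 0)
    return {
        "n_clades": len(t),
        "lambda_neg_sig": int(lam_sig_neg.sum()),
        "mu_pos_sig": int(mu_sig_pos.sum()),
        "either": int((lam_sig_neg | mu_sig_pos).sum()),
    }


def summary_frame(entries: list[SummaryEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "test": e.test,
                "level": e.level,
                "n_success": e.n_success,
                "n_trials": e.n_trials,
                "pct": e.pct,
                "binomial_p": e.binomial_p,
            }
            for e in entries
        ]
    )
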