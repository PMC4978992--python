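"""Shift points on range, sympatry, and net-diversification curves.

A shift point is a statistically supported change in the *trend* of a
curve. Each candidate model is a continuous piecewise-linear function of
time (a hinge regression: breakpoints add slope changes, not level jumps);
the number of breakpoints (0..max) is selected by the Bayesian information
criterion under Gaussian residuals. Breakpoint placement is exhaustive on
the observed ages for short series and by cross-entropy stochastic search
above that, matching how penalized trend-shift searches are done for
cumulative paleo curves.

Coincidence of the shifts found on the three curves (net diversification,
cumulative total range, degree of sympatry) is tested by randomization:
the observed mean pairwise age distance within a shift triple is compared
with triples drawn at random from the curves' own age supports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np

CURVE_IDS = ("net_div", "cum_total", "sympatry")

#: Minimum points per linear segment for a breakpoint to be considered.
MIN_SEGMENT_POINTS = 3

#: Series length above which breakpoint search switches to cross-entropy.
EXHAUSTIVE_MAX_N = 80

_CE_POPULATION = 200
_CE_ELITE_FRAC = 0.1
_CE_ITERATIONS = 50


@dataclass(frozen=True)
class ShiftPoint:
    curve_id: str
    age: float  # Ma
    bic_with: float
    bic_without: float  # BIC of the best model with one fewer breakpoint

    def __post_init__(self) -> None:
        if not self.bic_with < self.bic_without:
            raise ValueError("a reported shift must improve BIC")


@dataclass
class ShiftTriple:
    """Matched shift ages on the three curves (keyed by curve id)."""

    ages: dict[str, float]
    p_dist: float | None = None

    @property
    def mean_age(self) -> float:
        return float(np.mean(list(self.ages.values())))

    @property
    def mean_pairwise_distance(self) -> float:
        vals = list(self.ages.values())
        return float(np.mean([abs(a - b) for a, b in combinations(vals, 2)]))


def _hinge_rss(x: np.ndarray, y: np.ndarray, breaks: np.ndarray) -> float:
    cols = [np.ones_like(x), x] + [np.maximum(x - b, 0.0) for b in breaks]
    X = np.column_stack(cols)
    _, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1] or len(res) == 0:
        fitted = X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(np.sum((y - fitted) ** 2))
    return float(res[0])


def _step_rss(x: np.ndarray, y: np.ndarray, breaks: np.ndarray) -> float:
    """Piecewise-constant fit: segment means between breakpoints."""
    edges = np.concatenate([[-np.inf], np.sort(breaks), [np.inf]])
    rss = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        seg = y[(x > lo) & (x <= hi)]
        if len(seg):
            rss += float(np.sum((seg - seg.mean()) ** 2))
    return rss


_RSS_FN = {"linear": _hinge_rss, "constant": _step_rss}
_BASE_PARAMS = {"linear": 3, "constant": 2}  # incl. sigma


def _bic(rss: float, n: int, n_breaks: int, model: str = "linear") -> float:
    # ordinary parameters cost log n each; every breakpoint costs 3 log n
    # (its shape parameter plus an optimized location, which behaves like
    # more than one ordinary parameter under model search)
    k = _BASE_PARAMS[model] + 3 * n_breaks
    return n * np.log(max(rss, 1e-12) / n) + k * np.log(n)


def _candidate_positions(n: int) -> np.ndarray:
    """Indices usable as breakpoints with MIN_SEGMENT_POINTS on each side."""
    lo, hi = MIN_SEGMENT_POINTS - 1, n - MIN_SEGMENT_POINTS
    return np.arange(lo, hi + 1)


def _best_breaks_exhaustive(x, y, b: int, rss_fn) -> tuple[float, np.ndarray]:
    cand = _candidate_positions(len(x))
    best_rss, best = np.inf, None
    for idxs in combinations(cand, b):
        idxs = np.asarray(idxs)
        if b > 1 and np.any(np.diff(idxs) < MIN_SEGMENT_POINTS):
            continue
        rss = rss_fn(x, y, x[idxs])
        if rss < best_rss:
            best_rss, best = rss, x[idxs]
    return best_rss, best


def _best_breaks_cross_entropy(x, y, b: int, rng: np.random.Generator, rss_fn) -> tuple[float, np.ndarray]:
    lo, hi = x[MIN_SEGMENT_POINTS - 1], x[-MIN_SEGMENT_POINTS]
    mean = np.linspace(lo, hi, b + 2)[1:-1]
    sd = np.full(b, (hi - lo) / 4.0)
    n_elite = max(2, int(_CE_POPULATION * _CE_ELITE_FRAC))
    best_rss, best = np.inf, mean.copy()
    for _ in range(_CE_ITERATIONS):
        pop = np.sort(rng.normal(mean, sd, size=(_CE_POPULATION, b)), axis=1)
        pop = np.clip(pop, lo, hi)
        rss = np.array([rss_fn(x, y, row) for row in pop])
        order = np.argsort(rss)
        elite = pop[order[:n_elite]]
        if rss[order[0]] < best_rss:
            best_rss, best = float(rss[order[0]]), pop[order[0]].copy()
        mean, sd = elite.mean(axis=0), elite.std(axis=0) + 1e-9
        if np.all(sd < 1e-6 * (hi - lo)):
            break
    return best_rss, best


def detect_shifts(
    ages: np.ndarray,
    values: np.ndarray,
    max_breaks: int = 3,
    curve_id: str = "",
    seed: int = 0,
    model: str = "linear",
) -> list[ShiftPoint]:
    """Locate trend shift points on one curve by BIC over hinge regressions.

    ``ages`` (Ma, strictly ordered either way) and ``values`` define the
    series. ``model`` selects the segment family: ``linear`` (continuous
    hinge regression — trend changes, for cumulative/trending curves) or
    ``constant`` (piecewise-constant means — level changes, the natural
    family for rate series). Returns one :class:`ShiftPoint` per
    breakpoint of the BIC-selected model (possibly none). Series shorter
    than 6 points give an empty result.
    """
    rss_fn = _RSS_FN[model]
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(ages)
    x, y = ages[order], values[order]
    n = len(x)
    if n < 2 * MIN_SEGMENT_POINTS or np.any(np.diff(x) <= 0):
        return []
    rng = np.random.default_rng(seed)

    bics, breaks_by_b = [], []
    rss0 = rss_fn(x, y, np.array([]))
    bics.append(_bic(rss0, n, 0, model))
    breaks_by_b.append(np.array([]))
    max_b = min(max_breaks, (n // MIN_SEGMENT_POINTS) - 1)
    for b in range(1, max_b + 1):
        if n <= EXHAUSTIVE_MAX_N:
            rss, brk = _best_breaks_exhaustive(x, y, b, rss_fn)
        else:
            rss, brk = _best_breaks_cross_entropy(x, y, b, rng, rss_fn)
        if brk is None:
            break
        bics.append(_bic(rss, n, b, model))
        breaks_by_b.append(brk)
    chosen = int(np.argmin(bics))
    if chosen == 0:
        return []
    return [
        ShiftPoint(curve_id, float(b), bic_with=bics[chosen], bic_without=bics[chosen - 1])
        for b in breaks_by_b[chosen]
    ]


def match_triples(shifts_by_curve: dict[str, list[ShiftPoint]]) -> tuple[list[ShiftTriple], list[ShiftPoint]]:
    """Greedy nearest-age matching of per-curve shifts into triples.

    All cross-curve candidate triples are ordered by mean pairwise age
    distance; disjoint triples are accepted in order (each shift used at
    most once). Returns (triples, unmatched shifts). Any curve with zero
    shifts yields no triples.
    """
    curves = list(shifts_by_curve)
    if any(not shifts_by_curve[c] for c in curves) or len(curves) < 2:
        leftovers = [s for lst in shifts_by_curve.values() for s in lst]
        return [], leftovers
    candidates = []
    for combo in product(*(range(len(shifts_by_curve[c])) for c in curves)):
        ages = {c: shifts_by_curve[c][i].age for c, i in zip(curves, combo)}
        t = ShiftTriple(ages)
        candidates.append((t.mean_pairwise_distance, combo, t))
    candidates.sort(key=lambda item: item[0])
    used = {c: set() for c in curves}
    triples = []
    for _, combo, t in candidates:
        if any(i in used[c] for c, i in zip(curves, combo)):
            continue
        triples.append(t)
        for c, i in zip(curves, combo):
            used[c].add(i)
    unmatched = [
        shifts_by_curve[c][i]
        for c in curves
        for i in range(len(shifts_by_curve[c]))
        if i not in used[c]
    ]
    _swap_improve(triples, curves)
    triples.sort(key=lambda t: -t.mean_age)
    return triples, unmatched


def _swap_improve(triples: list[ShiftTriple], curves: list[str]) -> None:
    """Hill-climb on single within-curve swaps until locally optimal."""
    improved = True
    while improved:
        improved = False
        for c in curves:
            for i in range(len(triples)):
                for j in range(i + 1, len(triples)):
                    before = triples[i].mean_pairwise_distance + triples[j].mean_pairwise_distance
                    triples[i].ages[c], triples[j].ages[c] = triples[j].ages[c], triples[i].ages[c]
                    after = triples[i].mean_pairwise_distance + triples[j].mean_pairwise_distance
                    if after < before - 1e-12:
                        improved = True
                    else:
                        triples[i].ages[c], triples[j].ages[c] = (
                            triples[j].ages[c],
                            triples[i].ages[c],
                        )


def coincidence_test(
    triple: ShiftTriple,
    bin_midpoints: np.ndarray,
    rate_ages: np.ndarray,
    n_rand: int = 9999,
    seed: int = 0,
) -> float:
    """Randomization p-value for the temporal coincidence of a shift triple.

    Two ages are drawn (with replacement) from the curve time-bin midpoints
    and one from the 1-Myr net-rate grid, ``n_rand`` times; the p-value is
    the (add-one corrected) fraction of random triples whose mean pairwise
    distance is at most the observed one.
    """
    rng = np.random.default_rng(seed)
    mids = np.asarray(bin_midpoints, dtype=float)
    grid = np.asarray(rate_ages, dtype=float)
    a = rng.choice(mids, size=n_rand)
    b = rng.choice(mids, size=n_rand)
    c = rng.choice(grid, size=n_rand)
    rand_dist = (np.abs(a - b) + np.abs(a - c) + np.abs(b - c)) / 3.0
    obs = triple.mean_pairwise_distance
    p = (1.0 + np.sum(rand_dist <= obs)) / (n_rand + 1.0)
    triple.p_dist = float(p)
    return float(p)
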