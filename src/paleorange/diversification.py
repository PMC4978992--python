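"""Lineage times, diversification rates, and the sympatry covariate model.

Fossil preservation is modelled as a homogeneous Poisson process with rate
``q`` (expected occurrences per lineage per Myr). Under that model the
occurrence record of each species constrains its true origination (ts) and
extinction (te) ages: a Metropolis-within-Gibbs sampler draws (ts, te) for
every lineage jointly with ``q``, conditioning on each lineage being
sampled at least once.

Speciation and extinction rates through time are then estimated per 1-Myr
cell as events per lineage-Myr from the posterior (ts, te) draws; the net
diversification rate is their difference.

Finally, a birth-death model with an exponential link ties the rates to a
time-varying covariate (here the degree of sympatry s_t, standardized):

    lambda(t) = lambda0 * exp(gamma_lambda * s_t)
    mu(t)     = mu0     * exp(gamma_mu     * s_t)

gamma_lambda and gamma_mu are estimated by Metropolis-Hastings MCMC; a
correlation is called significant when 0 falls outside the 95% credible
interval of its gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln


class DiversificationError(ValueError):
    """Inconsistent lineage or covariate inputs."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class LineageTimes:
    """Origination/extinction ages (Ma) of one species, point or posterior."""

    species_name: str
    ts: float  # origination age, Ma
    te: float  # extinction age, Ma
    n_occurrences: int
    posterior_samples: np.ndarray | None = None  # (n_samples, 2) of (ts, te)

    def __post_init__(self) -> None:
        if not self.ts > self.te >= 0:
            raise DiversificationError(
                f"{self.species_name}: need ts > te >= 0, got ts={self.ts}, te={self.te}"
            )


@dataclass(frozen=True)
class PreservationModel:
    """Homogeneous Poisson preservation rate (occurrences/lineage/Myr)."""

    q: float

    def __post_init__(self) -> None:
        if not self.q > 0:
            raise DiversificationError("preservation rate q must be > 0")


@dataclass(frozen=True)
class RatesTimeline:
    """Posterior rates per 1-Myr cell; ages decrease oldest -> youngest."""

    grid_ages: np.ndarray  # cell midpoints, Ma
    lam: np.ndarray  # posterior mean speciation rate
    mu: np.ndarray  # posterior mean extinction rate
    lam_ci: np.ndarray  # (n_cells, 2)
    mu_ci: np.ndarray
    net_ci: np.ndarray

    @property
    def net(self) -> np.ndarray:
        return self.lam - self.mu

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_ma": self.grid_ages,
                "lambda_mean": self.lam,
                "lambda_lo": self.lam_ci[:, 0],
                "lambda_hi": self.lam_ci[:, 1],
                "mu_mean": self.mu,
                "mu_lo": self.mu_ci[:, 0],
                "mu_hi": self.mu_ci[:, 1],
                "net_mean": self.net,
                "net_lo": self.net_ci[:, 0],
                "net_hi": self.net_ci[:, 1],
            }
        )


@dataclass(frozen=True)
class CovariateBDPosterior:
    """Posterior of (lambda0, mu0, gamma_lambda, gamma_mu)."""

    samples: np.ndarray  # (n, 4) columns lambda0, mu0, gamma_lambda, gamma_mu
    acceptance_rate: float

    PARAM_NAMES = ("lambda0", "mu0", "gamma_lambda", "gamma_mu")

    @property
    def means(self) -> dict[str, float]:
        return dict(zip(self.PARAM_NAMES, self.samples.mean(axis=0)))

    @property
    def credible_intervals(self) -> dict[str, tuple[float, float]]:
        lo = np.percentile(self.samples, 2.5, axis=0)
        hi = np.percentile(self.samples, 97.5, axis=0)
        return {n: (float(a), float(b)) for n, a, b in zip(self.PARAM_NAMES, lo, hi)}

    @property
    def significant(self) -> dict[str, bool]:
        """True when the 95% CI of a gamma excludes 0."""
        ci = self.credible_intervals
        return {
            g: not (ci[g][0] <= 0.0 <= ci[g][1])
            for g in ("gamma_lambda", "gamma_mu")
        }

    def summary_row(self, clade_id: str = "") -> dict:
        m, ci, sig = self.means, self.credible_intervals, self.significant
        return {
            "clade": clade_id,
            "gamma_lambda_mean": m["gamma_lambda"],
            "gamma_lambda_lo": ci["gamma_lambda"][0],
            "gamma_lambda_hi": ci["gamma_lambda"][1],
            "gamma_lambda_sig": sig["gamma_lambda"],
            "gamma_mu_mean": m["gamma_mu"],
            "gamma_mu_lo": ci["gamma_mu"][0],
            "gamma_mu_hi": ci["gamma_mu"][1],
            "gamma_mu_sig": sig["gamma_mu"],
        }


# ---------------------------------------------------------------------------
# preservation likelihood


def preservation_loglik(q: float, lineage: LineageTimes, conditioned: bool = True) -> float:
    """Log-probability of a lineage's occurrence count under Poisson(q).

    With duration d = ts - te and k occurrences, the unconditioned term is
    the Poisson pmf ``k*log(q*d) - q*d - log(k!)``. ``conditioned=True``
    restricts to sampled lineages (k >= 1) by subtracting
    ``log(1 - exp(-q*d))``.
    """
    if lineage.ts <= lineage.te:
        raise DiversificationError("ts must exceed te")
    if q <= 0:
        raise DiversificationError("q must be > 0")
    d = lineage.ts - lineage.te
    k = lineage.n_occurrences
    ll = k * np.log(q * d) - q * d - gammaln(k + 1)
    if conditioned:
        ll -= np.log1p(-np.exp(-q * d))
    return float(ll)


def _point_process_loglik(q: float, dur: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Per-lineage log-density of the observed occurrence *times*.

    ``q^k * exp(-q*d)`` conditioned on k >= 1 — the form whose dependence
    on (ts, te) is correct when the occurrence ages themselves are data
    (the count pmf's d^k factor belongs to the integrated-out positions).
    """
    qd = q * dur
    return k * np.log(q) - qd - np.log1p(-np.exp(-qd))


# ---------------------------------------------------------------------------
# (ts, te) Gibbs sampler


@dataclass(frozen=True)
class McmcConfig:
    iterations: int = 20000
    burnin: int = 5000
    thin: int = 50
    seed: int = 0
    window: float = 2.0  # sliding-window half width, Myr
    duration_prior_rate: float = 0.05  # exponential prior on lineage duration
    q_prior_mean: float = 1.0


def sample_lineage_times(
    occurrence_ages: dict[str, np.ndarray],
    mcmc: McmcConfig = McmcConfig(),
) -> tuple[list[LineageTimes], np.ndarray]:
    """Posterior (ts, te) per species and preservation rate q.

    ``occurrence_ages`` maps species name to its occurrence ages (Ma).
    Metropolis-within-Gibbs: sliding-window proposals on every ts (bounded
    below by the species' oldest occurrence) and te (bounded above by the
    youngest, below by 0), and a multiplier proposal on q (exponential
    prior, mean ``q_prior_mean``). A weak exponential prior on lineage
    duration stands in for the constant-rate birth-death prior. Returns the
    species list with thinned posterior samples attached (posterior means
    as point ts/te) and the q samples.
    """
    names = sorted(occurrence_ages)
    if not names:
        raise DiversificationError("no species supplied")
    oldest = np.array([float(np.max(occurrence_ages[s])) for s in names])
    youngest = np.array([float(np.min(occurrence_ages[s])) for s in names])
    counts = np.array([len(occurrence_ages[s]) for s in names])
    if np.any(counts < 1):
        raise DiversificationError("every species needs at least one occurrence")
    rng = np.random.default_rng(mcmc.seed)

    eps = 1e-6
    ts = oldest + 0.5
    te = np.maximum(youngest - 0.5, 0.0)
    te = np.minimum(te, youngest)  # te may equal youngest but stay < ts
    q = 1.0

    def full_ll(ts_v, te_v, q_v):
        dur = ts_v - te_v
        ll = _point_process_loglik(q_v, dur, counts) - mcmc.duration_prior_rate * dur
        return ll

    ll = full_ll(ts, te, q)
    if not np.all(np.isfinite(ll)):
        bad = names[int(np.argmax(~np.isfinite(ll)))]
        raise DiversificationError(f"non-finite likelihood at initialization for {bad}")

    n_samples = max(0, (mcmc.iterations - mcmc.burnin) // mcmc.thin)
    ts_out = np.empty((n_samples, len(names)))
    te_out = np.empty((n_samples, len(names)))
    q_out = np.empty(n_samples)
    acc = np.zeros(3)
    tries = np.zeros(3)
    k_stored = 0

    for it in range(mcmc.iterations):
        # ts update (elementwise MH; lineages independent given q)
        prop = ts + rng.uniform(-mcmc.window, mcmc.window, size=len(ts))
        ok = prop > np.maximum(oldest, te + eps)
        ll_prop = full_ll(np.where(ok, prop, ts), te, q)
        accept = ok & (np.log(rng.uniform(size=len(ts))) < ll_prop - ll)
        ts = np.where(accept, prop, ts)
        ll = np.where(accept, ll_prop, ll)
        acc[0] += accept.sum()
        tries[0] += ok.sum() + 1e-12

        # te update
        prop = te + rng.uniform(-mcmc.window, mcmc.window, size=len(te))
        ok = (prop >= 0) & (prop <= youngest) & (prop < ts - eps)
        ll_prop = full_ll(ts, np.where(ok, prop, te), q)
        accept = ok & (np.log(rng.uniform(size=len(te))) < ll_prop - ll)
        te = np.where(accept, prop, te)
        ll = np.where(accept, ll_prop, ll)
        acc[1] += accept.sum()
        tries[1] += ok.sum() + 1e-12

        # q update: multiplier proposal with Jacobian q'/q
        u = rng.uniform(-0.3, 0.3)
        q_prop = q * np.exp(u)
        ll_prop = full_ll(ts, te, q_prop)
        log_ratio = (
            ll_prop.sum()
            - ll.sum()
            - (q_prop - q) / mcmc.q_prior_mean
            + u  # Jacobian of the multiplier move
        )
        tries[2] += 1
        if np.log(rng.uniform()) < log_ratio:
            q, ll = q_prop, ll_prop
            acc[2] += 1

        if it >= mcmc.burnin and (it - mcmc.burnin) % mcmc.thin == 0 and k_stored < n_samples:
            ts_out[k_stored], te_out[k_stored], q_out[k_stored] = ts, te, q
            k_stored += 1

    ts_out, te_out, q_out = ts_out[:k_stored], te_out[:k_stored], q_out[:k_stored]
    lineages = []
    for j, name in enumerate(names):
        ts_mean = float(ts_out[:, j].mean()) if k_stored else float(ts[j])
        te_mean = float(te_out[:, j].mean()) if k_stored else float(te[j])
        lineages.append(
            LineageTimes(
                name,
                ts_mean,
                max(te_mean, 0.0),
                int(counts[j]),
                posterior_samples=np.column_stack([ts_out[:, j], te_out[:, j]]),
            )
        )
    return lineages, q_out


# ---------------------------------------------------------------------------
# rates through time


def rates_timeline(
    lineages: list[LineageTimes], grid_step: float = 1.0, min_exposure: float = 2.0
) -> RatesTimeline:
    """Per-1-Myr speciation/extinction rates from posterior (ts, te) draws.

    Within each posterior sample and grid cell, lambda is the number of
    origination events in the cell divided by the lineage-Myr of exposure
    in the cell (mu likewise with extinctions). Cells with less than
    ``min_exposure`` lineage-Myr (default 2) are masked: a per-lineage rate
    estimated from under two lineage-Myr is dominated by noise, and such
    cells occur only at the clade's very origin and terminal collapse.
    Summaries are the mean and 2.5/97.5 percentiles across samples.
    """
    samples = [lin.posterior_samples for lin in lineages]
    if any(s is None or len(s) == 0 for s in samples):
        # fall back to the point estimates as a single "sample"
        samples = [np.array([[lin.ts, lin.te]]) for lin in lineages]
    n_draws = min(len(s) for s in samples)
    ts_mat = np.column_stack([s[:n_draws, 0] for s in samples])  # (draws, species)
    te_mat = np.column_stack([s[:n_draws, 1] for s in samples])

    top = float(np.ceil(ts_mat.max() / grid_step) * grid_step)
    edges = np.arange(top, -grid_step / 2, -grid_step)  # decreasing ages
    old, young = edges[:-1], edges[1:]
    mids = (old + young) / 2.0
    n_cells = len(mids)

    lam = np.full((n_draws, n_cells), np.nan)
    mu = np.full((n_draws, n_cells), np.nan)
    for d in range(n_draws):
        ts_d, te_d = ts_mat[d], te_mat[d]
        # exposure of each lineage in each cell (lineage-Myr)
        ov = np.clip(
            np.minimum(ts_d[None, :], old[:, None]) - np.maximum(te_d[None, :], young[:, None]),
            0.0,
            None,
        )
        exposure = ov.sum(axis=1)
        births = ((ts_d[None, :] <= old[:, None]) & (ts_d[None, :] > young[:, None])).sum(axis=1)
        # te == 0 marks survival to the present, not an extinction event
        deaths = (
            (te_d[None, :] < old[:, None])
            & (te_d[None, :] >= young[:, None])
            & (te_d[None, :] > 1e-12)
        ).sum(axis=1)
        usable = exposure >= max(min_exposure, 1e-12)
        with np.errstate(invalid="ignore", divide="ignore"):
            lam[d] = np.where(usable, births / np.maximum(exposure, 1e-12), np.nan)
            mu[d] = np.where(usable, deaths / np.maximum(exposure, 1e-12), np.nan)

    def summarize(mat):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(mat, axis=0)
            lo = np.nanpercentile(mat, 2.5, axis=0)
            hi = np.nanpercentile(mat, 97.5, axis=0)
        return mean, np.column_stack([lo, hi])

    lam_mean, lam_ci = summarize(lam)
    mu_mean, mu_ci = summarize(mu)
    net_mean, net_ci = summarize(lam - mu)
    keep = np.isfinite(lam_mean)
    return RatesTimeline(mids[keep], lam_mean[keep], mu_mean[keep], lam_ci[keep], mu_ci[keep], net_ci[keep])


# ---------------------------------------------------------------------------
# covariate birth-death model


@dataclass(frozen=True)
class SympatryCovariate:
    """Stepwise-constant covariate over time bins (ages in Ma).

    ``bin_edges`` decrease oldest -> youngest and bound ``values`` (one per
    bin). Values are standardized to zero mean and unit variance at
    construction, so the baseline rates of the covariate model are the
    rates at mean sympatry.
    """

    bin_edges: np.ndarray
    values: np.ndarray
    standardize: bool = True

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if len(edges) != len(vals) + 1 or not np.all(np.diff(edges) < 0):
            raise DiversificationError("need decreasing edges bounding one value per bin")
        if self.standardize:
            sd = vals.std()
            vals = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "values", vals)

    def at(self, ages: np.ndarray) -> np.ndarray:
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        out = np.empty(len(ages))
        for i, a in enumerate(ages):
            if a > self.bin_edges[0] + 1e-9 or a < self.bin_edges[-1] - 1e-9:
                raise DiversificationError(f"age {a} Ma outside covariate coverage")
            idx = int(np.searchsorted(-self.bin_edges, -a, side="right")) - 1
            out[i] = self.values[min(max(idx, 0), len(self.values) - 1)]
        return out


def _bd_sufficient_stats(lineages: list[LineageTimes], covariate: SympatryCovariate, grid_step: float = 1.0):
    """Precompute everything the covariate likelihood needs.

    Births are all originations except the clade's oldest (the root
    lineage's appearance is not a speciation event); deaths are all
    extinctions above age 0.
    """
    ts = np.array([lin.ts for lin in lineages])
    te = np.array([lin.te for lin in lineages])
    cov_old, cov_young = covariate.bin_edges[0], covariate.bin_edges[-1]
    if ts.max() > cov_old + 1e-9 or te.min() < cov_young - 1e-9:
        raise DiversificationError("covariate does not cover the clade's full time span")
    birth_ages = np.delete(ts, int(np.argmax(ts)))
    death_ages = te[te > 1e-9]
    s_births = covariate.at(birth_ages) if len(birth_ages) else np.array([])
    s_deaths = covariate.at(death_ages) if len(death_ages) else np.array([])

    top = ts.max()
    bottom = te.min()
    edges = np.arange(top, bottom - grid_step / 2, -grid_step)
    if edges[-1] > bottom:
        edges = np.append(edges, bottom)
    old, young = edges[:-1], edges[1:]
    ov = np.clip(np.minimum(ts[None, :], old[:, None]) - np.maximum(te[None, :], young[:, None]), 0.0, None)
    exposure = ov.sum(axis=1)  # lineage-Myr per cell
    s_cells = covariate.at((old + young) / 2.0)
    return {
        "n_births": len(birth_ages),
        "n_deaths": len(death_ages),
        "sum_s_births": float(s_births.sum()),
        "sum_s_deaths": float(s_deaths.sum()),
        "exposure": exposure,
        "s_cells": s_cells,
    }


def covariate_bd_loglik(
    lambda0: float,
    mu0: float,
    gamma_lambda: float,
    gamma_mu: float,
    covariate: SympatryCovariate,
    lineages: list[LineageTimes],
    _stats: dict | None = None,
) -> float:
    """Birth-death log-likelihood with exponentially covariate-linked rates.

    ``sum_births log lambda(t_b) + sum_deaths log mu(t_d)
    - sum_cells exposure * (lambda + mu)`` over 1-Myr integration cells,
    with exposure the exact lineage-Myr in the cell. With both gammas 0
    this reduces to the constant-rate closed form
    ``B log lambda0 + D log mu0 - (lambda0 + mu0) * total lineage-Myr``.
    """
    if lambda0 <= 0 or mu0 <= 0:
        raise DiversificationError("baseline rates must be positive")
    st = _stats if _stats is not None else _bd_sufficient_stats(lineages, covariate)
    ll = st["n_births"] * np.log(lambda0) + gamma_lambda * st["sum_s_births"]
    ll += st["n_deaths"] * np.log(mu0) + gamma_mu * st["sum_s_deaths"]
    ll -= lambda0 * float(st["exposure"] @ np.exp(gamma_lambda * st["s_cells"]))
    ll -= mu0 * float(st["exposure"] @ np.exp(gamma_mu * st["s_cells"]))
    return float(ll)


def covariate_bd_mcmc(
    lineages: list[LineageTimes],
    covariate: SympatryCovariate,
    iterations: int = 50000,
    thin: int = 50,
    burnin_samples: int = 200,
    seed: int = 0,
    gamma_prior_sd: float = 10.0,
) -> CovariateBDPosterior:
    """Posterior of (lambda0, mu0, gamma_lambda, gamma_mu) by MCMC.

    Metropolis-Hastings with multiplier proposals on the baseline rates
    (exponential priors, mean 1) and Gaussian random walks on the gammas
    (normal priors, sd ``gamma_prior_sd``). Defaults are a desk-scale
    reduction of a 1e6-iteration chain thinned to 1000 samples with the
    first 200 discarded; the thinning fraction is preserved.
    """
    st = _bd_sufficient_stats(lineages, covariate)
    rng = np.random.default_rng(seed)

    def log_post(theta):
        l0, m0, gl, gm = theta
        ll = covariate_bd_loglik(l0, m0, gl, gm, covariate, lineages, _stats=st)
        ll += -l0 - m0  # exponential(mean 1) priors on the baselines
        ll += -(gl**2 + gm**2) / (2 * gamma_prior_sd**2)
        return ll

    theta = np.array([0.2, 0.2, 0.0, 0.0])
    lp = log_post(theta)
    n_samples = iterations // thin
    out = np.empty((n_samples, 4))
    stored = 0
    accepted = 0
    for it in range(iterations):
        prop = theta.copy()
        which = it % 4
        if which < 2:  # multiplier on a baseline rate
            u = rng.uniform(-0.4, 0.4)
            prop[which] = theta[which] * np.exp(u)
            jac = u
        else:  # random walk on a gamma
            prop[which] = theta[which] + rng.normal(0, 0.3)
            jac = 0.0
        lp_prop = log_post(prop)
        if np.log(rng.uniform()) < lp_prop - lp + jac:
            theta, lp = prop, lp_prop
            accepted += 1
        if (it + 1) % thin == 0 and stored < n_samples:
            out[stored] = theta
            stored += 1
    samples = out[:stored][burnin_samples:]
    if len(samples) == 0:
        samples = out[:stored]
    rate = accepted / iterations
    if not 0.05 <= rate <= 0.8:
        import warnings

        warnings.warn(
            f"MCMC acceptance rate {rate:.2f} outside [0.05, 0.8]; "
            "retune proposal scales or run longer",
            stacklevel=2,
        )
    return CovariateBDPosterior(samples, rate)
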