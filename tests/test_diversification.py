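"""Preservation model, lineage-time sampling, rate timelines, covariate BD."""

import numpy as np
import pytest
from scipy import stats

from paleorange import diversification as dv


def lin(ts, te, k=1, name="sp"):
    return dv.LineageTimes(name, ts, te, k)


def make_covariate(edges, values, standardize=True):
    return dv.SympatryCovariate(np.asarray(edges, float), np.asarray(values, float), standardize)


def simulate_covariate_bd(
    lambda0, mu0, gamma_lambda, gamma_mu, covariate, seed, n_roots=5, t_top=50.0, cap=2000
):
    """Forward birth-death with rates driven by a given stepwise covariate.

    Time runs forward from age ``t_top`` to 0; roots start at t_top. Used
    as the generating process for parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    ts_list, te_list = [], []
    alive = [t_top] * n_roots  # birth ages of standing lineages
    out_ts, out_te = [], []
    age = t_top
    while alive and age > 0:
        s = float(covariate.at(np.array([age - 1e-9]))[0])
        lam = lambda0 * np.exp(gamma_lambda * s)
        mu = mu0 * np.exp(gamma_mu * s)
        total = len(alive) * (lam + mu)
        wait = rng.exponential(1.0 / total)
        # covariate is stepwise per 1 Myr: advance to the next edge and
        # redraw rather than let one draw straddle a rate change
        boundary = np.ceil(age - 1e-9) - 1.0
        if age - wait <= boundary:
            age = boundary
            continue
        age -= wait
        if age <= 0:
            break
        if rng.uniform() < lam / (lam + mu):
            alive.append(age)
            if len(alive) + len(out_ts) > cap:
                return None
        else:
            i = rng.integers(len(alive))
            out_ts.append(alive.pop(i))
            out_te.append(age)
    for a in alive:  # lineages reaching the present: te = 0 (not deaths)
        out_ts.append(a)
        out_te.append(0.0)
    return [lin(t1, t2, name=f"s{i}") for i, (t1, t2) in enumerate(zip(out_ts, out_te)) if t1 > t2]


class TestPreservationLoglik:
    def test_poisson_closed_form(self):
        # q=1, duration 2, k=2: log(e^-2 * 2^2 / 2!) = log 2 - 2
        ll = dv.preservation_loglik(1.0, lin(3.0, 1.0, k=2), conditioned=False)
        assert ll == pytest.approx(np.log(2.0) - 2.0)

    def test_unconditioned_mle_is_count_over_duration(self):
        lineage = lin(9.0, 2.0, k=5)
        qs = np.linspace(0.1, 3.0, 400)
        lls = [dv.preservation_loglik(q, lineage, conditioned=False) for q in qs]
        assert qs[int(np.argmax(lls))] == pytest.approx(5.0 / 7.0, abs=0.01)

    def test_matches_scipy_poisson_pmf(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            q = rng.uniform(0.2, 5.0)
            d = rng.uniform(0.5, 20.0)
            k = int(rng.integers(1, 30))
            ll = dv.preservation_loglik(q, lin(d + 1.0, 1.0, k=k), conditioned=False)
            assert ll == pytest.approx(stats.poisson.logpmf(k, q * d), abs=1e-10)

    def test_conditioning_subtracts_sampling_probability(self):
        lineage = lin(4.0, 1.5, k=3)
        q = 0.8
        uncond = dv.preservation_loglik(q, lineage, conditioned=False)
        cond = dv.preservation_loglik(q, lineage, conditioned=True)
        assert cond - uncond == pytest.approx(-np.log1p(-np.exp(-q * 2.5)))

    def test_inverted_times_rejected(self):
        with pytest.raises(dv.DiversificationError):
            lin(1.0, 3.0)


def simulate_occurrences(ts, te, q, rng):
    out = {}
    for i, (a, b) in enumerate(zip(ts, te)):
        k = rng.poisson(q * (a - b))
        if k > 0:
            out[f"s{i:03d}"] = rng.uniform(b, a, size=k)
    return out


class TestSampleLineageTimes:
    def test_same_seed_same_chains(self):
        rng = np.random.default_rng(1)
        ages = simulate_occurrences(rng.uniform(20, 40, 10), rng.uniform(0, 15, 10), 2.0, rng)
        cfg = dv.McmcConfig(iterations=2000, burnin=500, thin=20, seed=4)
        la, qa = dv.sample_lineage_times(ages, cfg)
        lb, qb = dv.sample_lineage_times(ages, cfg)
        assert np.array_equal(qa, qb)
        assert all(
            np.array_equal(x.posterior_samples, y.posterior_samples) for x, y in zip(la, lb)
        )

    def test_origination_hugs_oldest_occurrence_when_q_large(self):
        rng = np.random.default_rng(2)
        occ = {"s0": rng.uniform(5.0, 25.0, size=200)}  # q ~ 10/Myr
        cfg = dv.McmcConfig(iterations=6000, burnin=2000, thin=20, seed=0)
        lineages, _ = dv.sample_lineage_times(occ, cfg)
        gap = lineages[0].ts - occ["s0"].max()
        assert 0 < gap < 0.5  # ~1/q above the oldest find

    def test_preservation_rate_recovered(self):
        rng = np.random.default_rng(3)
        n = 50
        ts = rng.uniform(25, 45, n)
        te = np.maximum(ts - rng.uniform(5, 20, n), 0.0)
        ages = simulate_occurrences(ts, te, 3.0, rng)
        cfg = dv.McmcConfig(iterations=20000, burnin=5000, thin=50, seed=1)
        _, q_samples = dv.sample_lineage_times(ages, cfg)
        assert 2.4 <= q_samples.mean() <= 3.6


class TestRatesTimeline:
    def test_ratio_definition(self):
        # two lineages each exposed 1 Myr in the cell [2, 1); one ts in it
        lineages = [lin(2.5, 0.5, name="a"), lin(2.0, 1.0, name="b")]
        for x in lineages:
            x.posterior_samples = np.array([[x.ts, x.te]])
        tl = dv.rates_timeline(lineages)
        cell = np.argmin(abs(tl.grid_ages - 1.5))
        assert tl.lam[cell] == pytest.approx(0.5, rel=0.01)

    def test_no_extinctions_gives_zero_mu(self):
        lineages = [lin(5.0, 0.0, name=f"s{i}") for i in range(4)]
        for x in lineages:
            x.posterior_samples = np.array([[x.ts, x.te]])
        tl = dv.rates_timeline(lineages)
        assert np.allclose(tl.mu, 0.0)
        assert np.allclose(tl.net, tl.lam)

    def test_constant_rate_recovery(self):
        rng = np.random.default_rng(8)
        cov = make_covariate([200.0, 0.0], [0.0], standardize=False)
        lineages = None
        seed = 0
        while lineages is None or len(lineages) < 150:
            lineages = simulate_covariate_bd(0.4, 0.2, 0.0, 0.0, cov, seed, n_roots=20, t_top=30.0)
            seed += 1
        for x in lineages:
            x.posterior_samples = np.array([[x.ts, x.te]])
        tl = dv.rates_timeline(lineages)
        # exposure-weighted time-average of the per-cell rates
        exposure = np.array(
            [sum(max(0.0, min(x.ts, a + 0.5) - max(x.te, a - 0.5)) for x in lineages) for a in tl.grid_ages]
        )
        lam_avg = np.nansum(tl.lam * exposure) / exposure.sum()
        mu_avg = np.nansum(tl.mu * exposure) / exposure.sum()
        assert lam_avg == pytest.approx(0.4, rel=0.25)
        assert mu_avg == pytest.approx(0.2, rel=0.25)

    def test_birth_conservation_across_cells(self):
        rng = np.random.default_rng(5)
        lineages = [
            lin(float(ts), float(max(ts - d, 0.0) + 1e-6), name=f"s{i}")
            for i, (ts, d) in enumerate(zip(rng.uniform(5, 40, 30), rng.uniform(1, 10, 30)))
        ]
        for x in lineages:
            x.posterior_samples = np.array([[x.ts, x.te]])
        top = np.ceil(max(x.ts for x in lineages))
        edges = np.arange(top, -0.5, -1.0)
        births = sum(
            int(np.sum([(x.ts <= a) and (x.ts > b) for x in lineages]))
            for a, b in zip(edges[:-1], edges[1:])
        )
        assert births == len(lineages)


class TestCovariateLoglik:
    def test_zero_gamma_reduces_to_constant_rate_closed_form(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            n = 20
            ts = rng.uniform(10, 45, n)
            te = np.maximum(ts - rng.uniform(0.5, 9, n), 1e-6)
            lineages = [lin(float(a), float(b), name=f"s{i}") for i, (a, b) in enumerate(zip(ts, te))]
            cov = make_covariate([50.0, 25.0, 0.0], rng.normal(size=2))
            l0, m0 = rng.uniform(0.05, 1.0, 2)
            got = dv.covariate_bd_loglik(l0, m0, 0.0, 0.0, cov, lineages)
            total_lmyr = float(np.sum(ts - te))
            births = n - 1
            deaths = int(np.sum(te > 1e-9))
            closed = births * np.log(l0) + deaths * np.log(m0) - (l0 + m0) * total_lmyr
            assert got == pytest.approx(closed, abs=1e-10)

    def test_hand_worked_two_lineage_example(self):
        # two lineages: A lives ages 4 -> 1, B (daughter) 2.5 -> 0.5;
        # covariate s = +1 on ages [4, 2), s = -1 on [2, 0); rates
        # lambda(t) = 0.3 e^{0.5 s}, mu(t) = 0.1 e^{-0.25 s}
        lineages = [lin(4.0, 1.0, name="A"), lin(2.5, 0.5, name="B")]
        cov = make_covariate([4.0, 2.0, 0.0], [1.0, -1.0])  # standardizes to +-1
        l0, m0, gl, gm = 0.3, 0.1, 0.5, -0.25
        # births: B at age 2.5 (s=+1); deaths: A at 1 (s=-1), B at 0.5 (s=-1)
        births_term = np.log(l0 * np.exp(gl * 1.0))
        deaths_term = 2 * np.log(m0 * np.exp(gm * -1.0))
        # exposure by 1-Myr cells from age 4: [4,3): A (1); [3,2): A plus
        # B's post-origination sliver (1 + 0.5); [2,1): A+B (2);
        # [1,0.5): B (0.5). Cells [2,1) and younger carry s = -1.
        integral = (
            (l0 * np.exp(gl) + m0 * np.exp(gm)) * (1.0 + 1.5)
            + (l0 * np.exp(-gl) + m0 * np.exp(-gm)) * (2.0 + 0.5)
        )
        expected = births_term + deaths_term - integral
        got = dv.covariate_bd_loglik(l0, m0, gl, gm, cov, lineages)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_standardization_makes_covariate_scale_free(self):
        lineages = [lin(9.0, 2.0, name="A"), lin(6.0, 1.0, name="B"), lin(5.0, 0.5, name="C")]
        vals = np.array([1.0, 3.0, 2.0])
        cov1 = make_covariate([10.0, 6.0, 3.0, 0.0], vals)
        cov2 = make_covariate([10.0, 6.0, 3.0, 0.0], 2.0 * vals)
        a = dv.covariate_bd_loglik(0.3, 0.2, 0.7, -0.4, cov1, lineages)
        b = dv.covariate_bd_loglik(0.3, 0.2, 0.7, -0.4, cov2, lineages)
        assert a == pytest.approx(b, abs=1e-10)

    def test_covariate_gap_rejected(self):
        lineages = [lin(20.0, 1.0, name="A")]
        cov = make_covariate([10.0, 0.0], [0.0], standardize=False)
        with pytest.raises(dv.DiversificationError, match="cover"):
            dv.covariate_bd_loglik(0.3, 0.2, 0.1, 0.1, cov, lineages)


def sine_covariate(t_top=50.0, period=20.0, amplitude=0.5):
    """Oscillating driver; at |gamma| = 2 the rates swing by e^{±1}, strong
    but survivable for the simulated populations (standardization at
    inference restores a unit-variance covariate)."""
    edges = np.arange(t_top, -0.5, -1.0)
    mids = (edges[:-1] + edges[1:]) / 2.0
    return make_covariate(edges, amplitude * np.sin(2 * np.pi * mids / period))


class TestCovariateMcmc:
    def _recover(self, gamma_lambda, gamma_mu, seed, iterations=15000):
        cov = sine_covariate()
        lineages = None
        s = seed
        while lineages is None or len(lineages) < 80:
            lineages = simulate_covariate_bd(0.3, 0.15, gamma_lambda, gamma_mu, cov, s, n_roots=8)
            s += 1000
        return dv.covariate_bd_mcmc(
            lineages, cov, iterations=iterations, thin=iterations // 500, burnin_samples=100, seed=seed
        )

    def test_same_seed_same_summaries(self):
        a = self._recover(0.0, 0.0, seed=1, iterations=4000)
        b = self._recover(0.0, 0.0, seed=1, iterations=4000)
        assert a.means == b.means and a.credible_intervals == b.credible_intervals

    def test_null_gamma_rarely_flagged(self):
        flags = 0
        for seed in range(20):
            post = self._recover(0.0, 0.0, seed=seed)
            flags += post.significant["gamma_lambda"] + post.significant["gamma_mu"]
        # 40 gamma CIs at nominal 95%: expect ~2 false flags
        assert flags <= 6

    def test_positive_extinction_link_recovered(self):
        hits = 0
        for seed in range(10):
            post = self._recover(0.0, 2.0, seed=seed)
            hits += post.means["gamma_mu"] > 0 and post.significant["gamma_mu"]
        assert hits >= 8
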