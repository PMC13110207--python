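"""One-factor latent risk model: recovery, calibration, composites."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from rbmscore.composite import CompositeConfig
from rbmscore.latent import (
    IndicatorData,
    LatentFactorModel,
    McmcConfig,
    bayes_composite,
    fit_one_factor,
)


def _simulated_binomial_model(seed, n_sites=20, n=150, loading=1.0, sigma=0.3, k=2):
    rng = np.random.default_rng(seed)
    R = rng.normal(0, 1, n_sites)
    inds = []
    for j in range(k):
        b0 = rng.normal(-1.0, 0.5)
        eta = b0 + loading * R + rng.normal(0, sigma, n_sites)
        inds.append(
            IndicatorData(f"k{j}", "binomial", rng.binomial(n, expit(eta)), np.full(n_sites, n))
        )
    return R, [f"S{i:02d}" for i in range(n_sites)], inds


class TestModelValidation:
    def test_needs_two_indicators(self):
        with pytest.raises(ValueError, match="two indicators"):
            LatentFactorModel(["A"] * 5, [IndicatorData("x", "bernoulli", np.zeros(5))])

    def test_needs_five_sites(self):
        inds = [IndicatorData("x", "bernoulli", np.zeros(3)),
                IndicatorData("y", "bernoulli", np.ones(3))]
        with pytest.raises(ValueError, match="5 sites"):
            LatentFactorModel(["A", "B", "C"], inds)

    def test_binomial_needs_denominators(self):
        with pytest.raises(ValueError, match="denominators"):
            IndicatorData("x", "binomial", np.array([1, 2]))

    def test_mcmc_config_validation(self):
        with pytest.raises(ValueError):
            McmcConfig(iterations=100, warmup=100)


class TestRecovery:
    def test_latent_risk_recovered_from_binomial_layers(self):
        R, sites, inds = _simulated_binomial_model(seed=1, k=3)
        res = fit_one_factor(sites, inds, McmcConfig(chains=2, iterations=2000, warmup=800, seed=2))
        corr = np.corrcoef(res.posterior_R()["mean"], R)[0, 1]
        assert corr > 0.7

    def test_monotone_in_observed_risk(self):
        """Raising one site's counts raises its posterior latent risk."""
        R, sites, inds = _simulated_binomial_model(seed=3, n_sites=10)
        res_lo = fit_one_factor(sites, inds, McmcConfig(chains=2, iterations=1500, warmup=600, seed=4))
        bumped = []
        for ind in inds:
            y = ind.y.copy()
            y[0] = min(float(ind.n[0]), y[0] + 0.6 * (ind.n[0] - y[0]))
            bumped.append(IndicatorData(ind.name, "binomial", y, ind.n))
        res_hi = fit_one_factor(sites, bumped, McmcConfig(chains=2, iterations=1500, warmup=600, seed=4))
        assert res_hi.posterior_R()["mean"][0] > res_lo.posterior_R()["mean"][0]

    def test_site_relabeling_equivariance(self):
        """Permuting sites permutes posteriors (up to Monte-Carlo error)."""
        R, sites, inds = _simulated_binomial_model(seed=5, n_sites=12, n=400, k=3)
        cfg = McmcConfig(chains=2, iterations=2000, warmup=800, seed=6)
        res = fit_one_factor(sites, inds, cfg)
        perm = np.arange(12)[::-1]
        inds_p = [IndicatorData(i.name, "binomial", i.y[perm], i.n[perm]) for i in inds]
        res_p = fit_one_factor([sites[i] for i in perm], inds_p, cfg)
        a = res.posterior_R().set_index("site")["mean"]
        b = res_p.posterior_R().set_index("site")["mean"]
        assert np.abs(a - b.reindex(a.index)).max() < 0.25

    def test_mixed_families_fit_and_converge(self):
        rng = np.random.default_rng(7)
        S = 15
        R = rng.normal(0, 1, S)
        inds = [
            IndicatorData("p", "binomial", rng.binomial(100, expit(-1 + R)), np.full(S, 100)),
            IndicatorData("t", "normal", 2.0 + 0.5 * R + rng.normal(0, 0.2, S)),
            IndicatorData("d", "bernoulli", (rng.random(S) < expit(-1 + R)).astype(float)),
        ]
        res = fit_one_factor([f"S{i}" for i in range(S)], inds,
                             McmcConfig(chains=2, iterations=3000, warmup=1500, seed=8))
        assert np.corrcoef(res.posterior_R()["mean"], R)[0, 1] > 0.6
        assert max(res.rhat.values()) < 1.3  # loose: short desk-scale chains

    def test_single_chain_warns(self):
        _, sites, inds = _simulated_binomial_model(seed=9, n_sites=6, n=30)
        with pytest.warns(UserWarning, match="single-chain"):
            fit_one_factor(sites, inds, McmcConfig(chains=1, iterations=400, warmup=200, seed=1))


class TestCalibration:
    def test_simulation_based_calibration_rank_uniformity(self):
        """Reduced-scale SBC: the rank of the true R_1 among thinned
        posterior draws is uniform when data come from the prior
        predictive (2 binomial indicators, 10 sites)."""
        n_rep, n_rank = 60, 19
        ranks = []
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            S, n = 10, 25
            R = rng.normal(0, 1, S)
            inds = []
            for j in range(2):
                b0 = rng.normal(0, 5)
                load = abs(rng.normal(0, 1))
                sig = abs(stats.cauchy.rvs(0, 1, random_state=rng))
                eta = b0 + load * R + rng.normal(0, sig, S)
                inds.append(IndicatorData(f"k{j}", "binomial",
                                          rng.binomial(n, expit(eta)), np.full(S, n)))
            res = fit_one_factor(
                [f"S{i}" for i in range(S)], inds,
                McmcConfig(chains=1, iterations=1240, warmup=400, seed=rep),
            )
            draws = res.draws["R"][0, :, 0]
            thinned = draws[:: len(draws) // n_rank][:n_rank]
            ranks.append(int(np.sum(thinned < R[0])))
        counts = np.bincount(np.array(ranks) // 4, minlength=5)
        p = stats.chisquare(counts).pvalue
        assert p > 0.005


class TestBayesComposite:
    def test_centered_scores_are_zero(self):
        z = np.full((2, 4, 200), 3.0)
        res = bayes_composite(z, list("ABCD"), np.array([0.5, 0.5]),
                              trial_centers=np.array([3.0, 3.0]),
                              trial_scales=np.array([1.0, 1.0]))
        assert np.allclose(res.s_draws, 0.0)

    def test_single_indicator_identity(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 1, (1, 3, 300))
        res = bayes_composite(z, list("ABC"), np.array([1.0]),
                              trial_centers=np.array([0.0]),
                              trial_scales=np.array([1.0]))
        np.testing.assert_allclose(res.s_draws, z[0])

    def test_doubling_scale_halves_contribution(self):
        rng = np.random.default_rng(1)
        z = rng.normal(0, 1, (1, 3, 300))
        a = bayes_composite(z, list("ABC"), np.array([1.0]),
                            trial_centers=np.array([0.0]), trial_scales=np.array([1.0]))
        b = bayes_composite(z, list("ABC"), np.array([1.0]),
                            trial_centers=np.array([0.0]), trial_scales=np.array([2.0]))
        np.testing.assert_allclose(b.s_draws, a.s_draws / 2.0)

    def test_default_robust_centers(self):
        rng = np.random.default_rng(2)
        z = rng.normal(0, 1, (2, 8, 150))
        res = bayes_composite(z, [f"S{i}" for i in range(8)], np.array([0.5, 0.5]),
                              cfg=CompositeConfig(tau=0.0))
        assert np.isfinite(res.mean).all()
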