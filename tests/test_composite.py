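"""Robust standardization, weights and the three composite forms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbmscore.composite import (
    CompositeConfig,
    WeightVector,
    compose,
    entropy_weights,
    fit_standardization,
    sample_weights,
    standardize_draws,
    summarize,
)
from rbmscore.stage1 import IndicatorDrawMatrix


def _anchor_frame(**cols):
    return pd.DataFrame(cols)


class TestStandardization:
    def test_median_and_mad_scale(self):
        params = fit_standardization(_anchor_frame(a=[1.0, 2, 3, 4, 5]))
        assert params.center["a"] == 3.0
        assert params.scale["a"] == pytest.approx(1.4826)

    def test_constant_anchors_unit_fallback(self):
        with pytest.warns(UserWarning, match="constant"):
            params = fit_standardization(_anchor_frame(a=[2.0, 2.0, 2.0]))
        assert params.scale["a"] == 1.0

    def test_sd_fallback_when_mad_zero(self):
        params = fit_standardization(_anchor_frame(a=[0.0, 0, 0, 100]))
        assert params.center["a"] == 0.0
        assert params.scale["a"] == pytest.approx(50.0)

    def test_single_site_rejected(self):
        with pytest.raises(ValueError, match="2 sites"):
            fit_standardization(_anchor_frame(a=[1.0]))

    def test_standardize_affine(self):
        params = fit_standardization(_anchor_frame(a=[0.0, 0.0, 4.0, -4.0]))
        mat = IndicatorDrawMatrix(["s1", "s2"], [[0.0], [3.0]], "a", "logit")
        out = standardize_draws(mat, params)
        assert out.draws[0, 0] == 0.0
        assert out.draws[1, 0] == pytest.approx(3.0 / params.scale["a"])

    def test_missing_indicator_rejected(self):
        params = fit_standardization(_anchor_frame(a=[1.0, 2.0]))
        mat = IndicatorDrawMatrix(["s1"], [[0.0]], "other", "logit")
        with pytest.raises(KeyError, match="other"):
            standardize_draws(mat, params)

    def test_standardized_anchors_have_median_zero(self):
        rng = np.random.default_rng(8)
        anchors = _anchor_frame(a=rng.normal(2, 3, 15), b=rng.exponential(1, 15))
        params = fit_standardization(anchors)
        std = (anchors - params.center) / params.scale
        assert np.allclose(std.median(), 0.0, atol=1e-12)


class TestCompose:
    z = np.array([1.0, 0.0, 2.0, -1.0]).reshape(4, 1, 1)
    w = np.full(4, 0.25)

    def test_linear_worked_example(self):
        s = compose(self.z, self.w, CompositeConfig("linear"))
        assert s[0, 0] == pytest.approx(0.50)

    def test_softmax_large_lambda_approaches_max(self):
        s = compose(self.z, self.w, CompositeConfig("softmax", lam=400.0))
        assert s[0, 0] == pytest.approx(0.50, abs=1e-2)

    def test_geomean_hand_computed(self):
        s = compose(self.z, self.w, CompositeConfig("geomean", shift=2.0))
        assert s[0, 0] == pytest.approx(24.0 ** 0.25 - 2.0)

    def test_geomean_identity_on_equal_scores(self):
        z = np.full((3, 2, 4), 0.7)
        s = compose(z, np.array([0.2, 0.3, 0.5]), CompositeConfig("geomean", shift=2.0))
        assert np.allclose(s, 0.7)

    def test_geomean_shift_violation_raises(self):
        z = np.array([-5.0]).reshape(1, 1, 1)
        with pytest.raises(ValueError, match="shift"):
            compose(z, np.array([1.0]), CompositeConfig("geomean", shift=2.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_softmax_bounds_largest_weighted_term(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(0, 2, (5, 3, 7))
        w = rng.dirichlet(np.ones(5))
        soft = compose(z, w, CompositeConfig("softmax", lam=2.0))
        assert np.all(soft >= (w[:, None, None] * z).max(axis=0) - 1e-12)

    def test_softmax_nonincreasing_in_lambda(self):
        # (1/lam) * logsumexp(lam * x) is the lam-softmax norm: it
        # decreases toward max_k x_k as lam grows
        rng = np.random.default_rng(3)
        z = rng.normal(0, 1, (4, 5, 10))
        w = np.full(4, 0.25)
        prev = compose(z, w, CompositeConfig("softmax", lam=0.5))
        for lam in (1.0, 2.0, 5.0, 20.0):
            cur = compose(z, w, CompositeConfig("softmax", lam=lam))
            assert np.all(cur <= prev + 1e-10)
            prev = cur

    def test_zero_weight_indicator_is_ignored(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(3, 4, 6))
        base = compose(z, np.array([0.6, 0.4, 0.0]), CompositeConfig("linear"))
        reduced = compose(z[:2], np.array([0.6, 0.4]), CompositeConfig("linear"))
        np.testing.assert_allclose(base, reduced)

    def test_indicator_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(4, 3, 5))
        w = np.array([0.1, 0.2, 0.3, 0.4])
        perm = [2, 0, 3, 1]
        a = compose(z, w, CompositeConfig("linear"))
        b = compose(z[perm], w[perm], CompositeConfig("linear"))
        np.testing.assert_allclose(a, b)

    def test_per_draw_weight_pairing(self):
        z = np.ones((2, 1, 3))
        w_draws = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        z[1] = 2.0
        s = compose(z, w_draws, CompositeConfig("linear"))
        np.testing.assert_allclose(s[0], [1.0, 2.0, 1.5])


class TestWeights:
    def test_weight_vector_normalization(self):
        w = WeightVector.from_raw(["a", "b"], [2.0, 2.0])
        np.testing.assert_allclose(w.values, [0.5, 0.5])

    def test_invalid_weight_sum_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            WeightVector(["a", "b"], [0.5, 0.6])

    def test_dirichlet_simplex_and_mean(self):
        w = sample_weights(np.array([4.0, 2.0, 1.0]), 10_000, 0)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(w.mean(axis=0), [4 / 7, 2 / 7, 1 / 7], atol=0.02)

    def test_symmetric_dirichlet_mean(self):
        w = sample_weights(np.ones(3), 10_000, 1)
        np.testing.assert_allclose(w.mean(axis=0), [1 / 3] * 3, atol=0.02)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            sample_weights(np.array([1.0, 0.0]), 100, 0)

    def test_entropy_weights_proportional_to_dispersion(self):
        anchors = _anchor_frame(a=[0.0, 1, 2, 3], b=[0.0, 3, 6, 9])
        w = entropy_weights(anchors)
        np.testing.assert_allclose(w.values, [0.25, 0.75])

    def test_entropy_weights_constant_indicator_gets_zero(self):
        anchors = _anchor_frame(a=[1.0, 1, 1], b=[0.0, 2, 4])
        w = entropy_weights(anchors)
        assert w.as_series()["a"] == 0.0

    def test_entropy_weights_all_constant_uniform(self):
        anchors = _anchor_frame(a=[1.0, 1.0], b=[2.0, 2.0])
        with pytest.warns(UserWarning, match="uniform"):
            w = entropy_weights(anchors)
        np.testing.assert_allclose(w.values, [0.5, 0.5])


class TestSummarize:
    def test_exceedance_fraction(self):
        s = np.tile([0.0, 1.0, 2.0, 3.0] * 25, (2, 1))
        res = summarize(s, ["A", "B"], CompositeConfig(tau=1.5))
        assert res.pr_exceed["A"] == pytest.approx(0.5)

    def test_dominant_site_top1(self):
        rng = np.random.default_rng(0)
        s = rng.normal(0, 1, (4, 200))
        s[2] += 50.0
        res = summarize(s, list("ABCD"), CompositeConfig(tau=0.0, top_k=1))
        assert res.pr_topk["C"] == 1.0
        assert res.pr_topk.drop("C").max() == 0.0

    def test_degenerate_draws_collapse_cri(self):
        s = np.full((2, 150), 2.0)
        res = summarize(s, ["A", "B"], CompositeConfig(tau=1.5))
        assert res.cri_lo["A"] == res.cri_hi["A"] == 2.0

    def test_ranks_are_permutations_and_topk_sums(self):
        rng = np.random.default_rng(1)
        s = rng.normal(0, 1, (9, 400))
        res = summarize(s, [f"S{i}" for i in range(9)], CompositeConfig(tau=0.0, top_k=3))
        expected = np.arange(1, 10)
        for m in range(0, 400, 37):
            assert sorted(res.rank_draws[:, m]) == list(expected)
        assert res.pr_topk.sum() == pytest.approx(3.0, abs=1e-10)

    def test_rank_ties_broken_by_site_order(self):
        s = np.zeros((3, 120))
        res = summarize(s, ["C", "A", "B"], CompositeConfig(tau=0.5))
        assert list(res.rank_draws[:, 0]) == [1, 2, 3]

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            summarize(np.zeros((2, 50)), ["A", "B"], CompositeConfig())
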