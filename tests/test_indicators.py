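"""Indicator computations against hand-computed and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rbmscore.indicators import (
    BIIConfig,
    DistanceConfig,
    IndicatorSpec,
    compute_bii,
    compute_cmg,
    compute_duration_stat,
    compute_edd,
    compute_fail_rate,
    compute_window_risk,
    detect_sfps,
    energy_distance,
    ks_statistic,
)


class TestBII:
    def test_direct_count(self):
        out = compute_bii({"A": [61, 75, 90, 62]}, BIIConfig(60, 5))
        assert tuple(out.loc[0, ["y_bii", "n_bii"]]) == (2, 4)

    def test_all_far_above_band(self):
        out = compute_bii({"A": [72, 75, 90]}, BIIConfig(60, 5))
        assert tuple(out.loc[0, ["y_bii", "n_bii"]]) == (0, 3)

    def test_band_is_closed_at_both_ends(self):
        out = compute_bii({"A": [65.0, 55.0]}, BIIConfig(60, 5))
        assert out.loc[0, "y_bii"] == 2

    def test_empty_site_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="no enrolled"):
            out = compute_bii({"A": [], "B": [60.0]}, BIIConfig(60, 5))
        assert list(out["site"]) == ["B"]

    def test_default_delta_is_five_percent_of_threshold(self):
        assert BIIConfig(60).half_width == pytest.approx(3.0)

    @given(st.lists(st.floats(40, 80), min_size=1, max_size=20))
    @settings(max_examples=25, deadline=None)
    def test_order_invariance(self, values):
        cfg = BIIConfig(60, 5)
        a = compute_bii({"A": values}, cfg)
        b = compute_bii({"A": list(np.random.default_rng(1).permutation(values))}, cfg)
        assert a.loc[0, "y_bii"] == b.loc[0, "y_bii"]

    @given(st.lists(st.floats(40, 80), min_size=1, max_size=20),
           st.floats(0.5, 5), st.floats(0.1, 5))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_delta(self, values, delta, widen):
        narrow = compute_bii({"A": values}, BIIConfig(60, delta)).loc[0, "y_bii"]
        wide = compute_bii({"A": values}, BIIConfig(60, delta + widen)).loc[0, "y_bii"]
        assert wide >= narrow


def test_fail_rate_passes_counts_through(toy_agg):
    out = compute_fail_rate(toy_agg)
    assert tuple(out.loc[0, ["y_fail", "n_screen"]]) == (5, 20)
    assert out.loc[0, "y_fail"] / out.loc[0, "n_screen"] == pytest.approx(0.25)


def test_window_risk_counts_violations(toy_agg):
    out = compute_window_risk(toy_agg)
    assert tuple(out.loc[0, ["y_window", "n_enrolled"]]) == (2, 15)
    assert out.loc[2, "y_window"] == 0  # perfect adherence -> zero risk


class TestDuration:
    def test_median_of_log_times(self):
        out = compute_duration_stat({"A": np.exp([1.0, 2.0, 3.0])})
        assert out.loc[0, "log_median"] == pytest.approx(2.0)

    def test_single_time(self):
        out = compute_duration_stat({"A": [np.exp(5.0)]})
        assert out.loc[0, "log_median"] == pytest.approx(5.0)

    def test_unit_times_give_zero(self):
        out = compute_duration_stat({"A": [1.0, 1.0, 1.0, 1.0]})
        assert out.loc[0, "log_median"] == pytest.approx(0.0)

    def test_even_count_midpoint(self):
        out = compute_duration_stat({"A": np.exp([1.0, 3.0])})
        assert out.loc[0, "log_median"] == pytest.approx(2.0)


def _brute_ks(x, y):
    grid = np.concatenate([x, y])
    return max(
        abs(np.mean(np.asarray(x) <= g) - np.mean(np.asarray(y) <= g)) for g in grid
    )


def _brute_energy(x, y):
    cross = np.mean([abs(a - b) for a in x for b in y])
    self_x = np.mean([abs(a - b) for a in x for b in x])
    self_y = np.mean([abs(a - b) for a in y for b in y])
    return 2 * cross - self_x - self_y


class TestDistances:
    def test_identical_samples_ks_zero(self):
        assert compute_edd([1, 2, 3], [1, 2, 3]) == 0.0

    def test_interleaved_ks_half(self):
        # ECDF steps at x in {1,2,3,4} give max gap 0.5
        assert compute_edd([1, 3], [2, 4]) == pytest.approx(0.5)

    def test_singleton_energy(self):
        assert compute_edd([0.0], [1.0], DistanceConfig("energy")) == pytest.approx(2.0)

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError, match="single-site"):
            compute_edd([1.0], [])

    def test_exhaustive_small_sample_oracles(self):
        """KS and energy match brute force on every sample pair of size
        <= 4 drawn from a 3-point support (spot-check of all shapes)."""
        support = [0.0, 1.0, 2.0]
        samples = [
            list(c)
            for size in (1, 2, 3, 4)
            for c in itertools.combinations_with_replacement(support, size)
        ]
        for x in samples:
            for y in samples:
                assert ks_statistic(x, y) == pytest.approx(_brute_ks(x, y), abs=1e-12)
                assert energy_distance(x, y) == pytest.approx(_brute_energy(x, y), abs=1e-12)

    def test_ks_agrees_with_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 30))
            y = rng.normal(0.5, 1.3, size=rng.integers(2, 30))
            assert ks_statistic(x, y) == pytest.approx(
                stats.ks_2samp(x, y).statistic, abs=1e-12
            )

    def test_fully_separated_samples_ks_one(self):
        assert ks_statistic([1, 2], [10, 11, 12]) == 1.0

    # values rounded to 1e-3 so exp() cannot collapse distinct floats
    @given(st.lists(st.floats(-3, 3).map(lambda v: round(v, 3)), min_size=2, max_size=15),
           st.lists(st.floats(-3, 3).map(lambda v: round(v, 3)), min_size=2, max_size=15))
    @settings(max_examples=30, deadline=None)
    def test_ks_invariant_to_joint_monotone_transform(self, x, y):
        d1 = ks_statistic(x, y)
        d2 = ks_statistic(np.exp(x), np.exp(y))
        assert d1 == pytest.approx(d2, abs=1e-12)

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=12),
           st.lists(st.floats(-5, 5), min_size=1, max_size=12))
    @settings(max_examples=30, deadline=None)
    def test_energy_nonnegative_zero_iff_identical(self, x, y):
        d = energy_distance(x, y)
        assert d >= 0
        assert energy_distance(x, x) == pytest.approx(0.0, abs=1e-9)


class TestSFPS:
    def test_identical_composition_no_shift(self):
        counts = np.array([[10, 5], [10, 5]])
        assert detect_sfps(counts) == 0

    def test_complete_reversal_detected(self):
        # 2x2 chi-square of [[20,0],[0,20]] is 40 > 3.84
        counts = np.array([[20, 0], [0, 20]])
        assert detect_sfps(counts) == 1
        stat = stats.chi2_contingency(counts, correction=False)[0]
        assert stat == pytest.approx(40.0)

    def test_single_reason_degenerate(self):
        counts = np.array([[12, 0], [9, 0]])
        with pytest.warns(UserWarning, match="reasons"):
            assert detect_sfps(counts) == 0

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 15, size=(4, 3))
        perm = counts[:, [2, 0, 1]]
        assert detect_sfps(counts) == detect_sfps(perm)

    def test_needs_two_periods(self):
        with pytest.raises(ValueError):
            detect_sfps(np.array([[1, 2]]))


class TestCMG:
    def test_pass_through(self):
        assert compute_cmg(10, 20, 0.5) == (10, 20, 0.5)

    def test_count_bounds(self):
        with pytest.raises(ValueError):
            compute_cmg(21, 20, 0.5)

    def test_benchmark_bounds(self):
        with pytest.raises(ValueError):
            compute_cmg(1, 2, 1.5)


def test_indicator_spec_rejects_inconsistent_transform():
    with pytest.raises(ValueError, match="logit"):
        IndicatorSpec("bad", "binomial", +1, "log")
    with pytest.raises(ValueError, match="direction"):
        IndicatorSpec("bad", "binomial", 2, "logit")
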