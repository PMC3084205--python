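"""Selection-coefficient estimation, pooling, normalisation and ANCOVA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evoscape.competition_fitness import (
    CompetitionTimeSeries,
    ancova_slope_test,
    estimate_selection,
    normalize_selection,
    pool_replicates,
    relative_fitness,
    select_linear_phase,
)

from conftest import linear_series, make_estimate


class TestEstimateSelection:
    def test_noise_free_series_recovers_slope_exactly(self):
        est = estimate_selection(linear_series(0.05, intercept=-0.5))
        assert est.s == pytest.approx(0.05, abs=1e-12)
        assert est.se == pytest.approx(0.0, abs=1e-9)
        assert not est.normalized

    def test_constant_proportion_gives_zero_slope(self):
        est = estimate_selection(linear_series(0.0))
        assert est.s == pytest.approx(0.0, abs=1e-12)

    def test_ci_contains_estimate_and_uses_t_quantile(self):
        est = estimate_selection(linear_series(0.1, noise_sd=0.05))
        lo, hi = est.ci95
        assert lo < est.s < hi
        # half-width equals t_{0.975, n-2} * se
        import scipy.stats

        half = scipy.stats.t.ppf(0.975, est.n_points - 2) * est.se
        assert hi - est.s == pytest.approx(half, rel=1e-9)

    def test_zero_count_raises_with_pseudocount_advice(self):
        g = np.arange(4.0)
        ser = CompetitionTimeSeries("r", g, np.array([5.0, 3, 1, 0]), np.full(4, 10.0))
        with pytest.raises(ValueError, match="pseudocount"):
            estimate_selection(ser)
        est = estimate_selection(ser, pseudocount=0.5)
        assert np.isfinite(est.s)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            estimate_selection(linear_series(0.1, n=2))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        slope=st.floats(-0.5, 0.5),
        intercept=st.floats(-2, 2),
        noise=st.floats(0, 0.2),
        seed=st.integers(0, 10_000),
    )
    def test_ols_slope_matches_closed_form(self, slope, intercept, noise, seed):
        """Slope always equals sum((x-xbar)(y-ybar)) / sum((x-xbar)^2)."""
        rng = np.random.default_rng(seed)
        ser = linear_series(slope, n=10, intercept=intercept, noise_sd=noise, rng=rng)
        est = estimate_selection(ser)
        x, y = ser.generations, ser.log_ratio()
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert est.s == pytest.approx(expected, rel=1e-9, abs=1e-12)


class TestSelectLinearPhase:
    def test_perfectly_linear_series_returned_whole(self):
        ser = linear_series(0.08, n=10)
        out = select_linear_phase(ser)
        assert len(out) == 10
        assert out.linear_window == (0.0, 9.0)

    def test_saturating_tail_excluded(self):
        # linear for the first 8 samples, then the log ratio flattens (saturation)
        g = np.arange(12.0)
        y = np.where(g <= 7, 0.3 * g, 0.3 * 7)
        ser = CompetitionTimeSeries("r", g, 1e4 * np.exp(y), np.full(12, 1e4))
        out = select_linear_phase(ser, min_points=4, max_dropped_fraction=0.5)

        # brute-force oracle over all admissible contiguous windows
        import scipy.stats

        best = None
        for i in range(12):
            for j in range(i + 4, 13):
                if 12 - (j - i) > 6:
                    continue
                r = scipy.stats.linregress(g[i:j], y[i:j])
                key = (round(r.rvalue**2, 12), j - i, -i)
                best = max(best, key) if best else key
        assert out.linear_window[1] <= 7.0
        got = scipy.stats.linregress(out.generations, np.log(out.count_mutant / out.count_reference))
        assert round(got.rvalue**2, 12) == best[0]

    def test_infeasible_min_points_raises(self):
        with pytest.raises(ValueError, match="min_points"):
            select_linear_phase(linear_series(0.1, n=5), min_points=6)

    def test_zero_count_samples_never_in_window(self):
        g = np.arange(8.0)
        m = np.array([10.0, 20, 40, 80, 160, 320, 640, 1280])
        r = np.array([100.0, 100, 100, 100, 100, 100, 0, 0])
        ser = CompetitionTimeSeries("r", g, m, r)
        out = select_linear_phase(ser, min_points=4)
        assert np.all(out.count_reference > 0)


class TestPoolAndNormalize:
    def test_identical_replicates_have_zero_sem(self):
        e = make_estimate(0.1, 0.01, normalized=False)
        pooled = pool_replicates([e, e, e])
        assert pooled.s == pytest.approx(0.1)
        assert pooled.se == pytest.approx(0.0, abs=1e-15)
        assert pooled.n_replicates == 3

    def test_hand_computed_sem(self):
        ests = [make_estimate(s, 0.0, normalized=False) for s in (0.10, 0.12, 0.14)]
        pooled = pool_replicates(ests)
        assert pooled.s == pytest.approx(0.12)
        assert pooled.se == pytest.approx(0.02 / np.sqrt(3))

    def test_single_replicate_passthrough(self):
        e = make_estimate(0.07, 0.015, normalized=False)
        assert pool_replicates([e]) is e

    def test_mixed_normalized_flags_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            pool_replicates([make_estimate(0.1, normalized=True),
                             make_estimate(0.1, normalized=False)])

    def test_normalization_arithmetic_and_error_propagation(self):
        mut = make_estimate(0.12, 0.01, normalized=False)
        wt = make_estimate(0.02, 0.01, normalized=False)
        norm = normalize_selection(mut, wt)
        assert norm.s == pytest.approx(0.10)
        assert norm.se == pytest.approx(np.sqrt(2) * 0.01)
        assert norm.normalized

    def test_identity_control_changes_only_flag(self):
        mut = make_estimate(0.12, 0.01, normalized=False)
        norm = normalize_selection(mut, make_estimate(0.0, 0.0, normalized=False))
        assert norm.s == mut.s and norm.se == mut.se and norm.normalized

    def test_self_normalization_is_zero(self):
        wt = make_estimate(0.03, 0.005, normalized=False)
        assert normalize_selection(wt, wt).s == pytest.approx(0.0)

    def test_double_normalization_refused(self):
        norm = make_estimate(0.1, normalized=True)
        with pytest.raises(ValueError, match="double normalization"):
            normalize_selection(norm, make_estimate(0.0, normalized=False))


class TestRelativeFitness:
    @pytest.mark.parametrize("s,w", [(0.0, 1.0), (0.2, 1.2), (-0.15, 0.85)])
    def test_w_is_one_plus_s(self, s, w):
        rf = relative_fitness(make_estimate(s, 0.01))
        assert rf.w == pytest.approx(w)
        assert rf.ci95[0] == pytest.approx(1 + s - 1.96 * 0.01)
        assert rf.convention == "w = 1 + s"

    def test_requires_normalized_input(self):
        with pytest.raises(ValueError, match="normalized"):
            relative_fitness(make_estimate(0.1, normalized=False))


class TestAncova:
    def test_identical_series_give_no_slope_difference(self):
        ser = linear_series(0.05, noise_sd=0.01, rng=np.random.default_rng(1))
        f, p = ancova_slope_test(ser, ser)
        assert abs(f) < 1e-6
        assert p > 0.99

    def test_clearly_different_slopes_highly_significant(self):
        rng = np.random.default_rng(2)
        mut = linear_series(0.05, noise_sd=0.01, rng=rng)
        wt = linear_series(0.00, noise_sd=0.01, rng=rng, replicate="wt")
        f, p = ancova_slope_test(mut, wt)
        assert p < 1e-6

    def test_symmetric_under_label_exchange(self):
        rng = np.random.default_rng(3)
        a = linear_series(0.08, noise_sd=0.02, rng=rng)
        b = linear_series(0.02, noise_sd=0.02, rng=rng, replicate="b")
        assert ancova_slope_test(a, b) == pytest.approx(ancova_slope_test(b, a))
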