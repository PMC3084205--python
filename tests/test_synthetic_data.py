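"""Synthetic-data generators: closed-form expectations, determinism, truth labels."""

import numpy as np
import pytest

from evoscape.competition_fitness import estimate_selection
from evoscape.synthetic_data import (
    LandscapeScenario,
    SCENARIO_DEFAULTS,
    SimulationConfig,
    gen_clone_genotypes,
    gen_competition_series,
    gen_coverage_profiles,
    gen_landscape_scenario,
    gen_variant_tables,
)
from evoscape.variant_filters import apply_filters


class TestSimulationConfig:
    def test_generations_from_wall_time(self):
        cfg = SimulationConfig()
        # 6 h at 0.2 h^-1 -> 1.2 volume turnovers -> 1.2 / ln 2 generations
        assert cfg.generations_per_sample == pytest.approx(1.2 / np.log(2))
        g = cfg.sample_generations()
        assert g[0] == 0.0 and g[-1] <= cfg.total_generations

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(events_per_sample=0)
        with pytest.raises(ValueError):
            SimulationConfig(total_generations=0)


class TestCompetitionSeries:
    def test_neutral_noise_free_is_constant(self):
        for ser in gen_competition_series(0.0, SimulationConfig(seed=1), noise=False):
            p = ser.count_mutant / (ser.count_mutant + ser.count_reference)
            assert np.allclose(p, p[0])

    def test_noise_free_log_ratio_exactly_linear(self):
        ser = gen_competition_series(
            0.05, SimulationConfig(seed=1), initial_log_ratio=-0.5, noise=False
        )[0]
        assert np.allclose(ser.log_ratio(), -0.5 + 0.05 * ser.generations)

    def test_replicates_independent_but_seed_deterministic(self):
        a = gen_competition_series(0.1, SimulationConfig(seed=7))
        b = gen_competition_series(0.1, SimulationConfig(seed=7))
        for x, y in zip(a, b):
            assert np.array_equal(x.count_mutant, y.count_mutant)
        assert not np.array_equal(a[0].count_mutant, a[1].count_mutant)

    def test_estimator_recovers_true_coefficient(self):
        hits = 0
        for seed in range(100):
            ser = gen_competition_series(0.2, SimulationConfig(seed=seed, n_replicates=1))[0]
            lo, hi = estimate_selection(ser).ci95
            hits += lo <= 0.2 <= hi
        assert hits >= 90

    def test_saturation_truncates_instead_of_dividing_by_zero(self):
        # enormous slope drives the proportion to 1.0 in floating point
        series = gen_competition_series(
            5.0, SimulationConfig(seed=3, total_generations=40), noise=False
        )
        assert all(s.truncated for s in series)
        for s in series:
            s.log_ratio()  # finite everywhere

    def test_degenerate_initial_proportion_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            gen_competition_series(0.1, SimulationConfig(seed=1), initial_log_ratio=1e9)


class TestLandscapeScenarios:
    def test_reciprocal_sign_defaults_match_study_pattern(self):
        sc = LandscapeScenario("reciprocal_sign")
        assert sc.wx > sc.w0 and sc.wy > sc.w0
        assert sc.wxy < sc.w0 and sc.wxy < min(sc.wx, sc.wy)

    def test_additive_by_construction(self):
        sc = LandscapeScenario("additive", wx=1.1, wy=1.1, wxy=1.2)
        assert sc.wxy - sc.w0 == pytest.approx((sc.wx - sc.w0) + (sc.wy - sc.w0))

    def test_negative_defaults_bracketed(self):
        sc = LandscapeScenario("negative")
        assert max(sc.wx, sc.wy) < sc.wxy < sc.w0 + (sc.wx - sc.w0) + (sc.wy - sc.w0)

    def test_inconsistent_ordering_rejected_naming_inequality(self):
        with pytest.raises(ValueError, match="wxy < w0"):
            LandscapeScenario("reciprocal_sign", wxy=1.5)
        with pytest.raises(ValueError, match="wxy < wx \\+ wy - w0"):
            LandscapeScenario("negative", wxy=2.0)
        with pytest.raises(ValueError, match="flip"):
            LandscapeScenario("sign", wx=1.1, wy=1.2, wxy=1.5)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            LandscapeScenario("magnitude")

    def test_table_has_four_genotypes(self):
        df = gen_landscape_scenario(LandscapeScenario("sign"))
        assert list(df["genotype"]) == ["00", "10", "01", "11"]
        assert (df["fitness"] > 0).all()


class TestVariantTables:
    def test_truth_partitions_under_filters_noise_free(self):
        anc, evo, truth = gen_variant_tables(120, true_snps=5, true_indels=3, seed=2)
        survivors, _ = apply_filters(anc, evo)
        assert set(survivors["pos"]) == set(truth[truth["expected_pass"]]["pos"])

    def test_truth_partitions_under_filters_with_noise(self):
        anc, evo, truth = gen_variant_tables(
            250, true_snps=6, true_indels=2, error_rate=0.02, seed=8
        )
        survivors, _ = apply_filters(anc, evo)
        assert set(survivors["pos"]) == set(truth[truth["expected_pass"]]["pos"])

    def test_empty_input(self):
        anc, evo, truth = gen_variant_tables(0)
        assert anc == [] and evo == [] and truth.empty

    def test_same_seed_identical_tables(self):
        a = gen_variant_tables(50, true_snps=3, seed=4)
        b = gen_variant_tables(50, true_snps=3, seed=4)
        assert a[0] == b[0] and a[1] == b[1] and a[2].equals(b[2])

    def test_too_many_variants_rejected(self):
        with pytest.raises(ValueError, match="more true variants"):
            gen_variant_tables(3, true_snps=2, true_indels=2)


class TestCoverageProfiles:
    def test_no_amplification_identical_expectations(self):
        anc, clone = gen_coverage_profiles(100, 30, 1, 10, amp_copies=1, noise=False)
        assert np.array_equal(anc.depth, clone.depth)

    def test_tenfold_segment_noise_free(self):
        anc, clone = gen_coverage_profiles(1000, 30, 401, 500, amp_copies=10, noise=False)
        assert np.allclose(clone.depth[400:500] / anc.depth[400:500], 10.0)
        assert np.allclose(clone.depth[:400], anc.depth[:400])

    def test_poisson_noise_reproducible(self):
        a = gen_coverage_profiles(500, 30, 100, 200, 5, seed=6)
        b = gen_coverage_profiles(500, 30, 100, 200, 5, seed=6)
        assert np.array_equal(a[1].depth, b[1].depth)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="amp_copies"):
            gen_coverage_profiles(100, 30, 1, 10, amp_copies=0)
        with pytest.raises(ValueError, match="segment"):
            gen_coverage_profiles(100, 30, 50, 40)


class TestCloneGenotypes:
    def test_exclusive_sampling_never_produces_doubles(self):
        table = gen_clone_genotypes(22, 0.4, 0.5, allow_double=False, seed=1)
        assert ((table["mth1"] == 1) & (table["hxt_amp"] == 1)).sum() == 0
        assert len(table) == 22

    def test_degenerate_frequencies_all_double(self):
        table = gen_clone_genotypes(10, 1.0, 1.0, allow_double=True, seed=1)
        assert table["mth1"].sum() == 10 and table["hxt_amp"].sum() == 10

    def test_independent_sampling_matches_binomial_expectation(self):
        doubles = [
            (
                (lambda t: ((t["mth1"] == 1) & (t["hxt_amp"] == 1)).sum())(
                    gen_clone_genotypes(200, 0.5, 0.4, allow_double=True, seed=s)
                )
            )
            for s in range(40)
        ]
        assert np.mean(doubles) == pytest.approx(200 * 0.5 * 0.4, rel=0.1)

    def test_infeasible_exclusivity_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            gen_clone_genotypes(10, 0.7, 0.6, allow_double=False)

    def test_bad_frequency_rejected(self):
        with pytest.raises(ValueError, match="frequencies"):
            gen_clone_genotypes(10, 1.5, 0.1)
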