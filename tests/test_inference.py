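"""Randomization tests, Edgington combination and Tau-U against oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from scedkit import (
    DesignSpace,
    GeneratorConfig,
    PhaseDesign,
    edgington_combine,
    enumerate_designs,
    mean_diff_stat,
    randomization_test,
    render_p,
    run_inference,
    simulate_cohort,
    simulate_series,
    tau_u,
)
from tests.conftest import make_series


class TestMeanDiffStat:
    def test_constant_phases(self, design_756, series_factory):
        vals = [10.0] * 7 + [4.0] * 89
        s = series_factory(vals, design_756)
        assert mean_diff_stat(s) == pytest.approx(6.0)

    def test_no_effect_constant_series_is_zero(self, design_756, series_factory):
        s = series_factory([5.0] * 96, design_756)
        assert mean_diff_stat(s) == 0.0

    def test_matches_brute_force_means(self, small_space, series_factory):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 28, size=12).astype(float)
        vals[[2, 7]] = np.nan
        for d in enumerate_designs(small_space):
            s = series_factory(vals, d)
            a = [v for v in vals[:d.baseline_days] if not math.isnan(v)]
            bc = [v for v in vals[d.baseline_days:] if not math.isnan(v)]
            assert mean_diff_stat(s) == pytest.approx(
                sum(a) / len(a) - sum(bc) / len(bc))


def strict_max_series(design_756):
    """96-day series whose statistic is strictly largest under baseline 7."""
    rng = np.random.default_rng(5)
    vals = np.concatenate([20 + rng.integers(0, 8, size=7),
                           rng.integers(0, 4, size=89)]).astype(float)
    return make_series(vals, design_756)


class TestRandomizationTest:
    def test_unique_maximum_gives_p_of_one_twentieth(self, space, design_756):
        s = strict_max_series(design_756)
        res = randomization_test(s, space)
        assert res.n_scenarios == 20
        assert res.p_value == 0.05
        assert res.observed_stat == max(res.null_stats.values())

    def test_constant_series_all_ties_p_is_one(self, space, design_756):
        s = make_series([5.0] * 96, design_756)
        res = randomization_test(s, space)
        assert all(v == 0 for v in res.null_stats.values())
        assert res.p_value == 1.0

    def test_attainable_p_values_are_k_over_20(self, space, design_756):
        for seed in range(15):
            cfg = GeneratorConfig(effect_size=0, onset_delay_days=0, ramp_days=0)
            s = simulate_series(cfg, design_756, seed=seed, participant_id="n")
            p = randomization_test(s, space).p_value
            assert p in {k / 20 for k in range(1, 21)}

    def test_matches_independent_enumeration_oracle(self, small_space):
        rng = np.random.default_rng(7)
        for trial in range(40):
            vals = rng.integers(0, 10, size=12).astype(float)
            vals[rng.random(12) < 0.1] = np.nan
            obs_b = int(rng.integers(3, 7))
            design = small_space.design_for_baseline(obs_b)
            s = make_series(vals, design)
            # oracle: enumerate partitions by hand
            stats_by_b = {}
            for b in range(3, 7):
                a = vals[:b][~np.isnan(vals[:b])]
                bc = vals[b:][~np.isnan(vals[b:])]
                if len(a) and len(bc):
                    stats_by_b[b] = a.mean() - bc.mean()
            if obs_b not in stats_by_b:
                continue
            obs = stats_by_b[obs_b]
            expected_p = (sum(1 for v in stats_by_b.values() if v >= obs - 1e-12)
                          / len(stats_by_b))
            res = randomization_test(s, small_space, design)
            assert res.p_value == pytest.approx(expected_p)
            assert res.null_stats == pytest.approx(stats_by_b)

    def test_two_sided_counts_absolute_extremes(self, small_space):
        vals = np.array([0, 0, 0, 9, 9, 9, 9, 9, 9, 9, 9, 9], dtype=float)
        design = small_space.design_for_baseline(3)
        res = randomization_test(make_series(vals, design), small_space,
                                 direction="two_sided")
        # observed stat is the most negative; |obs| is the unique largest
        assert res.p_value == 0.25

    def test_scenarios_with_empty_observed_side_are_excluded(self, small_space):
        vals = np.array([np.nan, np.nan, np.nan, 5, 6, 7, 8, 9, 1, 2, 3, 4],
                        dtype=float)
        design = small_space.design_for_baseline(5)
        res = randomization_test(make_series(vals, design), small_space)
        assert res.excluded_baselines == (3,)
        assert res.n_scenarios == 3

    def test_stratum_restricted_null(self, small_space):
        vals = np.arange(12, dtype=float)
        design = small_space.design_for_baseline(5)
        res = randomization_test(make_series(vals, design), small_space,
                                 scenario_set="stratum")
        assert set(res.null_stats) == {5, 6}

    def test_effect_shifts_p_toward_attainable_minimum(self, space):
        # simulated immediate strong effect vs null: the effect cohort hits
        # the minimum attainable p more often
        effect_cfg = GeneratorConfig(effect_size=10, onset_delay_days=0,
                                     ramp_days=7, noise_sd=2)
        null_cfg = GeneratorConfig(effect_size=0, onset_delay_days=0,
                                   ramp_days=0, noise_sd=2)
        design = PhaseDesign(12, 56, 28)
        n_min_effect = n_min_null = 0
        for seed in range(150):
            pe = randomization_test(
                simulate_series(effect_cfg, design, seed=seed), space).p_value
            pn = randomization_test(
                simulate_series(null_cfg, design, seed=10_000 + seed), space).p_value
            n_min_effect += pe == 0.05
            n_min_null += pn == 0.05
        assert n_min_effect > n_min_null


class TestEdgington:
    def test_reported_four_case_combination(self):
        res = edgington_combine([0.45, 0.99, 0.35, 0.50])
        assert round(res.combined_p, 2) == 0.69
        # the two-decimal result is insensitive to the bounded entry
        assert round(edgington_combine([0.45, 1.0, 0.35, 0.50]).combined_p, 2) == 0.69

    def test_single_p_is_identity(self):
        assert edgington_combine([0.05]).combined_p == pytest.approx(0.05)

    def test_two_halves_combine_to_half(self):
        # P(U1 + U2 <= 1) = 1/2 for independent uniforms
        assert edgington_combine([0.5, 0.5]).combined_p == pytest.approx(0.5)

    def test_matches_irwin_hall_cdf(self):
        rng = np.random.default_rng(1)
        for n in (2, 3, 4, 6):
            ps = rng.uniform(0.01, 1.0, size=n)
            expected = stats.irwinhall.cdf(ps.sum(), n)
            assert edgington_combine(ps).combined_p == pytest.approx(expected)

    def test_matches_monte_carlo_sum_of_uniforms(self):
        rng = np.random.default_rng(2)
        ps = [0.31, 0.72, 0.55, 0.18]
        s = sum(ps)
        draws = rng.uniform(size=(100_000, 4)).sum(axis=1)
        mc = np.mean(draws <= s)
        se = np.sqrt(mc * (1 - mc) / 100_000)
        assert abs(edgington_combine(ps).combined_p - mc) < 3 * se

    @given(ps=st.lists(st.floats(0.01, 0.99), min_size=2, max_size=5),
           idx=st.integers(0, 4), bump=st.floats(0.001, 0.2))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_each_component(self, ps, idx, bump):
        base = edgington_combine(ps).combined_p
        bumped = list(ps)
        i = idx % len(ps)
        bumped[i] = min(1.0, bumped[i] + bump)
        assert edgington_combine(bumped).combined_p >= base - 1e-12

    @pytest.mark.parametrize("bad", [[], [0.0, 0.5], [0.5, 1.2]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            edgington_combine(bad)


def tau_oracle(a, bc, corrected):
    s_cross = sum(np.sign(y - x) for x in a for y in bc)
    s_trend = sum(np.sign(a[j] - a[i])
                  for i in range(len(a)) for j in range(i + 1, len(a)))
    if corrected:
        return (s_cross - s_trend) / (len(a) * len(bc) + len(a) * (len(a) - 1) / 2)
    return s_cross / (len(a) * len(bc))


class TestTauU:
    def test_complete_dominance_flat_baseline(self, small_space):
        design = small_space.design_for_baseline(4)
        vals = [9.0] * 4 + [2, 1, 2, 1, 0, 1, 2, 0]
        s = make_series(vals, design)
        uncorrected = tau_u(s, correct_baseline_trend=False)
        assert uncorrected.tau_u == pytest.approx(-1.0)
        corrected = tau_u(s)
        n_a, n_bc = 4, 8
        assert corrected.tau_u == pytest.approx(
            -n_a * n_bc / (n_a * n_bc + n_a * 3 / 2))

    def test_all_ties_give_zero(self, small_space):
        design = small_space.design_for_baseline(4)
        s = make_series([5.0] * 12, design)
        assert tau_u(s).tau_u == 0.0

    @pytest.mark.parametrize("corrected", [True, False])
    def test_matches_exhaustive_pair_oracle(self, small_space, corrected):
        rng = np.random.default_rng(12)
        for _ in range(50):
            vals = rng.integers(0, 10, size=12).astype(float)
            vals[rng.random(12) < 0.15] = np.nan
            design = small_space.design_for_baseline(int(rng.integers(3, 7)))
            s = make_series(vals, design)
            a = vals[:design.baseline_days]
            a = a[~np.isnan(a)]
            bc = vals[design.baseline_days:]
            bc = bc[~np.isnan(bc)]
            res = tau_u(s, correct_baseline_trend=corrected)
            if len(a) < 2 or len(bc) < 1:
                assert math.isnan(res.tau_u) or not corrected
                continue
            assert res.tau_u == pytest.approx(tau_oracle(a, bc, corrected))
            assert abs(res.tau_u) <= 1

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_value_negation(self, seed):
        # negating values (reflecting the 0-27 scale) negates the pair counts
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 28, size=12).astype(float)
        design = DesignSpace(total_days=12, treatment_days=5, baseline_min=3,
                             baseline_max=6,
                             strata=((3, 4), (5, 6))).design_for_baseline(4)
        res = tau_u(make_series(vals, design))
        flipped = tau_u(make_series(27 - vals, design))
        assert flipped.s_cross == -res.s_cross
        assert flipped.s_trend_a == -res.s_trend_a

    def test_insufficient_baseline_reports_explicitly(self, small_space):
        design = small_space.design_for_baseline(3)
        vals = [np.nan, np.nan, 5] + [3.0] * 9
        res = tau_u(make_series(vals, design))
        assert res.insufficient
        assert res.n_a == 1


class TestRunInference:
    def test_cohort_report_has_participant_rows_and_combined(self):
        cohort = simulate_cohort(4, master_seed=3)
        table, combined = run_inference(cohort)
        assert len(table) == 5
        assert table.iloc[-1].participant_id == "All combined"
        assert table.iloc[-1].p_value == pytest.approx(combined.combined_p)
        per_p = table.p_value.iloc[:4].tolist()
        assert combined.combined_p == pytest.approx(
            edgington_combine(per_p).combined_p)

    def test_single_participant_combined_equals_own_p(self):
        cohort = simulate_cohort(1, master_seed=4)
        table, combined = run_inference(cohort)
        assert combined.combined_p == pytest.approx(table.iloc[0].p_value)

    def test_constant_cohort_renders_p_at_least_99(self, space, design_756):
        items = [("P1", make_series([5.0] * 96, design_756), design_756)]
        table, _ = run_inference(items, space)
        assert table.iloc[0].p_value == 1.0
        assert table.iloc[0].p_display == "≥.99"

    @pytest.mark.parametrize("p,expected", [
        (0.45, ".45"), (0.05, ".05"), (0.994, ".99"), (0.995, "≥.99"),
        (1.0, "≥.99"), (math.nan, "NA"),
    ])
    def test_p_rendering(self, p, expected):
        assert render_p(p) == expected
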