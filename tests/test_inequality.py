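"""Fractional ranks, concentration/Erreygers indices, stages, bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import healthineq as hq
from healthineq.exceptions import ParameterError, UndefinedIndexError
from healthineq.inequality import QUINTILE_LABELS, STAGES


def brute_ci_summation(health, income):
    """Summation-form oracle: CI = 2/(n*mean) * sum h_i I_i - 1, untied ranks."""
    order = np.argsort(income, kind="stable")
    n = len(health)
    ranks = np.empty(n)
    ranks[order] = (np.arange(1, n + 1) - 0.5) / n
    return 2.0 / (n * np.mean(health)) * np.sum(health * ranks) - 1.0


class TestFractionalRank:
    def test_three_values(self):
        fr = hq.fractional_rank(np.array([10.0, 20.0, 30.0]))
        assert np.allclose(fr.rank, [1 / 6, 3 / 6, 5 / 6])

    def test_tie_averaging(self):
        fr = hq.fractional_rank(np.array([5.0, 5.0]))
        assert np.allclose(fr.rank, [0.5, 0.5])

    def test_mean_is_half_exactly(self, rng):
        vals = rng.integers(0, 5, 200).astype(float)   # heavy ties
        assert hq.fractional_rank(vals).rank.mean() == pytest.approx(0.5, abs=1e-12)

    def test_permutation_invariance_exhaustive(self):
        base = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        ref = dict(zip(base, hq.fractional_rank(base).rank))
        for perm in itertools.permutations(base):
            perm = np.array(perm)
            r = hq.fractional_rank(perm).rank
            assert all(ref[v] == ri for v, ri in zip(perm, r))


class TestConcentrationIndex:
    def test_constant_health_zero(self):
        fr = hq.fractional_rank(np.arange(10.0))
        assert hq.concentration_index(np.full(10, 0.4), fr).index_value == pytest.approx(0.0)

    def test_sign_and_antisymmetry(self):
        income = np.arange(1.0, 101.0)
        health = income / 100.0
        ci_up = hq.concentration_index(health, hq.fractional_rank(income)).index_value
        ci_down = hq.concentration_index(health, hq.fractional_rank(-income)).index_value
        assert ci_up > 0
        assert ci_down == pytest.approx(-ci_up, abs=1e-12)

    @given(st.integers(0, 500))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_covariance_form_equals_summation_form(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 9)
        health = rng.uniform(0.1, 1.0, n)
        income = rng.permutation(np.arange(n, dtype=float))   # untied
        ci = hq.concentration_index(health, hq.fractional_rank(income)).index_value
        assert ci == pytest.approx(brute_ci_summation(health, income), abs=1e-12)

    def test_scale_invariance_in_health(self, rng):
        health = rng.uniform(0.1, 1.0, 50)
        fr = hq.fractional_rank(rng.normal(size=50))
        a = hq.concentration_index(health, fr).index_value
        b = hq.concentration_index(7.3 * health, fr).index_value
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_mean_health_undefined(self):
        fr = hq.fractional_rank(np.arange(4.0))
        with pytest.raises(UndefinedIndexError):
            hq.concentration_index(np.zeros(4), fr)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            h = rng.uniform(0, 1, 30)
            v = hq.concentration_index(h + 1e-9, hq.fractional_rank(rng.normal(size=30)))
            assert -1.0 <= v.index_value <= 1.0


class TestErreygersIndex:
    def test_constant_health_zero(self):
        fr = hq.fractional_rank(np.arange(9.0))
        ei = hq.erreygers_index(np.full(9, 0.3), fr, 0.0, 1.0)
        assert ei.index_value == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 500))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_identity_ei_equals_4_mean_ci_on_unit_bounds(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 50))
        health = rng.uniform(0.05, 1.0, n)
        income = rng.permutation(np.arange(n, dtype=float))
        fr = hq.fractional_rank(income)
        ci = hq.concentration_index(health, fr)
        ei = hq.erreygers_index(health, fr, 0.0, 1.0)
        assert ei.index_value == pytest.approx(
            4.0 * ci.mean_health * ci.index_value, abs=1e-12
        )

    def test_health_equal_to_rank_closed_form(self):
        """h_i = R_i on [0,1]: EI = 4(2E[R^2] - E[R]) -> 2/3 as n grows."""
        n = 1000
        r = (np.arange(1, n + 1) - 0.5) / n
        ei = hq.erreygers_index(r, hq.fractional_rank(r), 0.0, 1.0).index_value
        expected = 4 * (2 * np.mean(r**2) - np.mean(r))
        assert ei == pytest.approx(expected, abs=1e-12)
        assert ei == pytest.approx(2.0 / 3.0, abs=1e-3)

    def test_out_of_bounds_health_rejected(self):
        fr = hq.fractional_rank(np.arange(3.0))
        with pytest.raises(ParameterError):
            hq.erreygers_index(np.array([0.2, 0.5, 1.4]), fr, 0.0, 1.0)


class TestStageIncomes:
    def test_arithmetic_example(self):
        cohort = pd.DataFrame(
            {
                "income_initial": [100.0],
                "premium": [10.0],
                "oop_spend": [30.0],
                "reimbursement": [20.0],
            }
        )
        si = hq.build_stage_incomes(cohort)
        assert (si.initial[0], si.contribution[0], si.treatment[0], si.reimbursement[0]) == (
            100.0, 90.0, 60.0, 80.0,
        )

    def test_no_flow_identity(self):
        cohort = pd.DataFrame(
            {
                "income_initial": [50.0, 70.0],
                "premium": [0.0, 0.0],
                "oop_spend": [0.0, 0.0],
                "reimbursement": [0.0, 0.0],
            }
        )
        si = hq.build_stage_incomes(cohort)
        for s in STAGES[1:]:
            assert np.array_equal(si.stage(s), si.initial)

    def test_elementwise_monotonicity_on_generated_cohort(self, default_cohort):
        si = hq.build_stage_incomes(default_cohort)
        assert (si.contribution <= si.initial).all()
        assert (si.treatment <= si.contribution).all()
        assert (si.reimbursement >= si.treatment).all()

    def test_reimbursement_above_spending_rejected(self):
        cohort = pd.DataFrame(
            {
                "income_initial": [100.0],
                "premium": [0.0],
                "oop_spend": [10.0],
                "reimbursement": [11.0],
            }
        )
        with pytest.raises(ParameterError):
            hq.build_stage_incomes(cohort)


class TestQuintileAssign:
    def test_balanced_cut(self):
        labels = hq.quintile_assign(np.arange(1.0, 11.0))
        counts = pd.Series(labels).value_counts()
        assert all(counts[q] == 2 for q in QUINTILE_LABELS)

    def test_all_equal_incomes_lowest_group(self):
        labels = hq.quintile_assign(np.full(10, 5.0))
        assert all(l == "low" for l in labels)

    def test_boundary_ties_go_to_lower_group(self):
        vals = np.array([1.0, 2.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        boundary = np.quantile(vals, 0.2)
        labels = hq.quintile_assign(vals)
        assert all(l == "low" for l in labels[vals == boundary]) or boundary not in vals

    @given(st.integers(0, 300))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_group_sizes_off_by_at_most_tie_mass(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 20, 100).astype(float)   # plenty of ties
        labels = hq.quintile_assign(vals)
        counts = pd.Series(labels).value_counts().reindex(list(QUINTILE_LABELS)).fillna(0)
        max_tie = pd.Series(vals).value_counts().max()
        assert (abs(counts - 20) <= max_tie).all()


class TestBootstrap:
    def test_se_of_mean_matches_closed_form(self, rng):
        x = pd.DataFrame({"v": rng.normal(0.0, 2.0, 1000)})
        boot = hq.bootstrap_se(lambda df: df["v"].mean(), x, B=500, seed=4)
        closed = 2.0 / np.sqrt(1000)
        assert abs(boot.se - closed) / closed < 0.2

    def test_minimum_b_flagged_low_precision(self, rng):
        x = pd.DataFrame({"v": rng.normal(size=50)})
        boot = hq.bootstrap_se(lambda df: df["v"].mean(), x, B=2, seed=0)
        assert boot.low_precision and boot.B == 2

    def test_same_seed_identical_se(self, rng):
        x = pd.DataFrame({"v": rng.normal(size=100)})
        a = hq.bootstrap_se(lambda df: df["v"].mean(), x, B=50, seed=9)
        b = hq.bootstrap_se(lambda df: df["v"].mean(), x, B=50, seed=9)
        assert a.se == b.se and a.p_value == b.p_value

    def test_b_below_two_rejected(self, rng):
        x = pd.DataFrame({"v": rng.normal(size=10)})
        with pytest.raises(ParameterError):
            hq.bootstrap_se(lambda df: df["v"].mean(), x, B=1, seed=0)


class TestSegmentPipeline:
    def test_zero_flows_fixed_mode_identical_cis(self):
        cohort, _ = hq.generate_cohort(hq.CohortConfig(n_individuals=2_000, seed=5))
        cohort = cohort.copy()
        cohort[["premium", "oop_spend", "reimbursement"]] = 0.0
        results, deltas = hq.segment_pipeline(cohort, mode="fixed")
        cis = [r.index_value for r in results if r.index_kind == "standard"]
        assert np.allclose(cis, cis[0])
        assert deltas.delta_total == pytest.approx(0.0, abs=1e-15)

    def test_delta_telescoping(self, small_cohort):
        _, deltas = hq.segment_pipeline(small_cohort, mode="fixed")
        total = (
            deltas.delta_contribution + deltas.delta_treatment + deltas.delta_reimbursement
        )
        assert deltas.delta_total == pytest.approx(total, abs=1e-12)

    def test_reimbursement_transfer_to_poorest_narrows_inequality(self):
        """Full reimbursement concentrated on the poorest decile re-ranks
        them upward, so the post-reimbursement CI falls: delta_total > 0."""
        cohort, _ = hq.generate_cohort(hq.CohortConfig(n_individuals=5_000, seed=11))
        cohort = cohort.copy()
        cohort["premium"] = 0.0
        cohort["oop_spend"] = 0.6 * cohort["income_initial"]
        poorest = cohort["income_initial"] <= cohort["income_initial"].quantile(0.1)
        cohort["reimbursement"] = np.where(poorest, cohort["oop_spend"], 0.0)
        _, deltas = hq.segment_pipeline(cohort, mode="fixed")
        assert deltas.delta_total > 0


class TestSubgroupCI:
    def test_within_quintile_ranks_have_mean_half(self, small_cohort):
        si = hq.build_stage_incomes(small_cohort)
        labels = hq.quintile_assign(si.initial)
        for q in QUINTILE_LABELS:
            r = hq.fractional_rank(si.initial[labels == q]).rank
            assert r.mean() == pytest.approx(0.5, abs=1e-12)

    def test_exchangeable_subgroups_match_total_ci(self):
        """Education is independent of income and (with zero covariate
        effects) of health, so subgroup CIs sit near the total CI."""
        cohort, _ = hq.generate_cohort(
            hq.CohortConfig(n_individuals=20_000, seed=9, covariate_effects={})
        )
        health = cohort["srh"].to_numpy(float)
        total = hq.concentration_index(
            health, hq.fractional_rank(cohort["income_initial"].to_numpy())
        ).index_value
        for res in hq.subgroup_ci(cohort, "education_group", health=health):
            assert abs(res.index_value - total) < 0.02, res.group

    def test_larger_female_slope_gives_larger_female_ci(self):
        """Directional recovery: with a larger income-health slope for
        women, the female CI exceeds the male CI in >= 95 of 100 seeds."""
        wins = 0
        for seed in range(100):
            cohort, _ = hq.generate_cohort(
                hq.CohortConfig(
                    n_individuals=5_000, seed=seed, female_income_slope_extra=0.5
                )
            )
            res = hq.subgroup_ci(
                cohort, "gender", stage="initial", health=cohort["srh"].to_numpy(float)
            )
            vals = {r.group: r.index_value for r in res}
            wins += vals["female"] > vals["male"]
        assert wins >= 95

    def test_unknown_grouping_rejected(self, small_cohort):
        with pytest.raises(ParameterError):
            hq.subgroup_ci(small_cohort, "hair_color")
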