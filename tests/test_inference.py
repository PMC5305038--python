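import dataclasses
import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from lickstat.inference import BayesFactorResult
from lickstat.inference import TestResult as TResult
from lickstat.inference import (
    bonferroni_family,
    coefficient_of_variation,
    jzs_bayes_factor,
    mann_whitney_u,
    one_way_anova,
    p_from_f,
    p_from_t,
    pearson_r,
    pooled_t_test,
    run_battery,
)


class TestPFromT:
    def test_printed_consumption_contrast(self):
        # frozen against the published t/p pair for df = 50
        assert p_from_t(3.179, 50) == pytest.approx(0.0025, abs=5e-5)

    def test_t_zero(self):
        assert p_from_t(0.0, 5) == pytest.approx(1.0)
        assert p_from_t(0.0, 500) == pytest.approx(1.0)

    def test_against_density_integration_oracle(self):
        # oracle: integrate the t density tail directly
        t, df = 2.0, 10
        tail, _ = integrate.quad(lambda x: stats.t.pdf(x, df), t, np.inf)
        assert p_from_t(t, df) == pytest.approx(2 * tail, rel=1e-8)
        assert p_from_t(t, df) == pytest.approx(0.073, abs=5e-4)

    def test_sign_symmetric(self):
        assert p_from_t(-2.5, 12) == p_from_t(2.5, 12)

    def test_df_below_one_rejected(self):
        with pytest.raises(ValueError):
            p_from_t(1.0, 0)

    @given(
        t1=st.floats(min_value=0.0, max_value=10.0),
        t2=st.floats(min_value=0.0, max_value=10.0),
        df=st.integers(min_value=1, max_value=200),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_abs_t(self, t1, t2, df):
        lo, hi = sorted([t1, t2])
        if hi - lo > 1e-6:
            assert p_from_t(hi, df) < p_from_t(lo, df)

    @given(
        f1=st.floats(min_value=0.0, max_value=50.0),
        f2=st.floats(min_value=0.0, max_value=50.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_p_from_f_decreasing(self, f1, f2):
        lo, hi = sorted([f1, f2])
        if hi - lo > 1e-6:
            assert p_from_f(hi, 2, 49) < p_from_f(lo, 2, 49)


class TestPooledT:
    def test_df_matches_study_design(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=22)
        assert pooled_t_test(a, b).df == 50

    def test_identical_means(self):
        res = pooled_t_test([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # means 2 and 3, pooled SD 1 -> t = -1/sqrt(2/3)
        res = pooled_t_test([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.p_two_tailed == pytest.approx(0.288, abs=1e-3)

    def test_zero_pooled_variance(self):
        with pytest.raises(ValueError):
            pooled_t_test([1.0, 1.0], [2.0, 2.0])

    def test_matches_scipy(self, rng):
        a, b = rng.normal(size=12), rng.normal(1.0, 2.0, size=9)
        res = pooled_t_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_two_tailed == pytest.approx(ref.pvalue)


def permutation_mw_p(a, b):
    """Brute-force oracle: full enumeration over all rank assignments."""
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)
    n1n2 = na * (n - na)

    def u_of(indices):
        sel = pooled[list(indices)]
        rest = np.delete(pooled, list(indices))
        return (sel[:, None] > rest[None, :]).sum() + 0.5 * (
            sel[:, None] == rest[None, :]
        ).sum()

    u_obs = min(u_of(range(na)), n1n2 - u_of(range(na)))
    us = [u_of(c) for c in combinations(range(n), na)]
    extreme = sum(
        1 for u in us if u <= u_obs + 1e-9 or u >= n1n2 - u_obs - 1e-9
    )
    return min(1.0, extreme / len(us))


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_two_tailed == pytest.approx(1 / 3)

    def test_identical_multisets(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)  # n1*n2/2

    def test_u_sum_identity(self, rng):
        for _ in range(20):
            a = rng.integers(0, 10, size=rng.integers(1, 8)).astype(float)
            b = rng.integers(0, 10, size=rng.integers(1, 8)).astype(float)
            from lickstat.inference import _u_statistic

            assert _u_statistic(a, b) + _u_statistic(b, a) == len(a) * len(b)

    def test_exact_matches_permutation_oracle(self, rng):
        for _ in range(15):
            a = rng.normal(size=rng.integers(2, 6))
            b = rng.normal(size=rng.integers(2, 6))
            res = mann_whitney_u(a, b)
            assert res.p_two_tailed == pytest.approx(permutation_mw_p(a, b))

    def test_exact_with_ties_matches_oracle(self, rng):
        for _ in range(10):
            a = rng.integers(0, 4, size=4).astype(float)
            b = rng.integers(0, 4, size=4).astype(float)
            res = mann_whitney_u(a, b)
            assert res.p_two_tailed == pytest.approx(permutation_mw_p(a, b))

    def test_exact_matches_scipy_no_ties(self, rng):
        a, b = rng.normal(size=7), rng.normal(size=6)
        res = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, method="exact", alternative="two-sided")
        assert res.p_two_tailed == pytest.approx(ref.pvalue)

    def test_large_sample_normal_approximation(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(0.8, 1.0, size=22)
        res = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, method="asymptotic", alternative="two-sided")
        assert res.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestOneWayAnova:
    def test_df_matches_study_design(self, rng):
        groups = [rng.normal(size=n) for n in (30, 13, 9)]
        main, _ = one_way_anova(groups)
        assert main.df == (2.0, 49.0)

    def test_two_group_f_equals_t_squared(self, rng):
        a, b = rng.normal(size=10), rng.normal(0.5, 1.0, size=10)
        main, _ = one_way_anova([a, b])
        t = pooled_t_test(a, b).statistic
        assert main.statistic == pytest.approx(t**2, abs=1e-10)
        assert main.p_two_tailed == pytest.approx(pooled_t_test(a, b).p_two_tailed)

    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        main, _ = one_way_anova([g, g, g])
        assert main.statistic == pytest.approx(0.0)
        assert main.p_two_tailed == pytest.approx(1.0)

    def test_zero_variance_everywhere_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 1.0], [2.0, 2.0]])

    def test_posthoc_pairs(self, rng):
        groups = [rng.normal(loc, 1.0, size=8) for loc in (0, 0, 3)]
        main, posthoc = one_way_anova(groups, group_names=["a", "b", "c"])
        assert len(posthoc) == 3
        names = {p.measure_name for p in posthoc}
        assert names == {"a_vs_b", "a_vs_c", "b_vs_c"}
        # Bonferroni over pairs: adjusted p >= raw p
        raw = pooled_t_test(groups[0], groups[1]).p_two_tailed
        adj = next(p for p in posthoc if p.measure_name == "a_vs_b").p_two_tailed
        assert adj == pytest.approx(min(1.0, raw * 3))


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson_r(x, -x).statistic == pytest.approx(-1.0)

    def test_hand_computed(self):
        # cov 5.5/3, ssx 5, ssy 8.75 -> r = 5.5 / sqrt(5 * 8.75)
        res = pearson_r([1, 2, 3, 4], [1, 3, 2, 5])
        assert res.statistic == pytest.approx(5.5 / math.sqrt(5 * 8.75), abs=1e-9)
        assert res.statistic == pytest.approx(0.83, abs=0.01)

    def test_p_via_t_transform(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = pearson_r(x, y)
        r = res.statistic
        t = r * math.sqrt((20 - 2) / (1 - r * r))
        assert res.p_two_tailed == pytest.approx(p_from_t(t, 18), rel=1e-6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _result(p, name="m"):
    return TResult(
        measure_name=name, test_name="t", statistic=1.0, df=50.0, p_two_tailed=p
    )


class TestBonferroni:
    def test_printed_verdicts(self):
        out = bonferroni_family([_result(0.0025), _result(0.02)], alpha=0.05, m=7)
        assert out[0].significant
        assert not out[1].significant

    def test_m_one_is_uncorrected(self):
        out = bonferroni_family([_result(0.03)], alpha=0.05, m=1)
        assert out[0].bonferroni_alpha == 0.05
        assert out[0].significant

    def test_family_too_small_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_family([_result(0.01), _result(0.01)], alpha=0.05, m=1)

    @given(
        ps=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=7),
        m=st.integers(min_value=2, max_value=10),
    )
    @settings(max_examples=50, deadline=None)
    def test_corrected_subset_of_uncorrected(self, ps, m):
        if m < len(ps):
            m = len(ps)
        results = [_result(p, name=str(i)) for i, p in enumerate(ps)]
        corrected = bonferroni_family(results, alpha=0.05, m=m)
        uncorrected = bonferroni_family(results, alpha=0.05, m=1) if len(ps) == 1 else [
            dataclasses.replace(r, bonferroni_alpha=0.05) for r in results
        ]
        sig_corr = {r.measure_name for r in corrected if r.significant}
        sig_unc = {r.measure_name for r in uncorrected if r.significant}
        assert sig_corr <= sig_unc


def mc_jzs_bf10(t, n1, n2, rscale, n_draws=400_000, seed=99):
    """Monte-Carlo oracle: BF10 as the prior-averaged likelihood ratio
    over Cauchy effect-size draws."""
    rng = np.random.default_rng(seed)
    delta = stats.cauchy.rvs(scale=rscale, size=n_draws, random_state=rng)
    n_eff = n1 * n2 / (n1 + n2)
    nu = n1 + n2 - 2
    alt = stats.nct.pdf(t, nu, delta * math.sqrt(n_eff))
    return alt.mean() / stats.t.pdf(t, nu)


class TestJZSBayesFactor:
    def test_t_zero_favours_null(self):
        assert jzs_bayes_factor(0.0, 30, 22).bf10 < 1.0

    def test_matches_monte_carlo_oracle(self):
        bf = jzs_bayes_factor(2.0, 20, 20).bf10
        assert bf == pytest.approx(mc_jzs_bf10(2.0, 20, 20, 1.0), rel=0.01)

    def test_symmetric_in_sign(self):
        assert jzs_bayes_factor(-2.5, 12, 15).bf10 == pytest.approx(
            jzs_bayes_factor(2.5, 12, 15).bf10, rel=1e-9
        )

    def test_monotone_in_abs_t(self):
        ts = [0.0, 0.5, 1.0, 2.0, 3.0, 5.0]
        bfs = [jzs_bayes_factor(t, 30, 22).bf10 for t in ts]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_bf01_inverse(self):
        res = jzs_bayes_factor(1.7, 10, 12)
        assert res.bf01 * res.bf10 == pytest.approx(1.0)

    def test_direction_reporting(self):
        assert jzs_bayes_factor(4.0, 30, 22).direction_reported == "supports_alternative"
        null = jzs_bayes_factor(0.1, 30, 22)
        assert null.direction_reported == "supports_null"
        assert null.k == pytest.approx(null.bf01)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            jzs_bayes_factor(1.0, 1, 10)
        with pytest.raises(ValueError):
            jzs_bayes_factor(1.0, 10, 10, rscale=0.0)


class TestCoefficientOfVariation:
    def test_constant_values(self):
        assert coefficient_of_variation([3.0, 3.0, 3.0]) == pytest.approx(0.0)

    def test_simple_example(self):
        assert coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(50.0)

    def test_scale_invariance(self, rng):
        x = rng.lognormal(size=25)
        assert coefficient_of_variation(7.3 * x) == pytest.approx(
            coefficient_of_variation(x)
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


class TestFamilywiseErrorOnNullCohorts:
    def test_type_i_error_controlled(self, small_params):
        """Identical group parameters: the Bonferroni battery flags any
        measure in at most ~alpha of replicate cohorts.

        Scaled down from the design-size cohorts to stay fast: 8 vs 8
        subjects, 1 session, 250 replicates.
        """
        import lickstat.simulate as sim
        from lickstat.microstructure import summarize_cohort

        n_rep = 250
        hits = 0
        for rep in range(n_rep):
            cfg = sim.CohortConfig(
                n_control=8,
                n_mcao=8,
                sessions_per_subject=1,
                control_params=small_params,
                mcao_params=small_params,
                master_seed=50_000 + rep,
            )
            table = summarize_cohort(sim.simulate_cohort(cfg))
            battery = run_battery(table, family=7, alpha=0.05)
            if any(e["test"].significant for e in battery):
                hits += 1
        fwer = hits / n_rep
        # 0.05 plus ~2.5 binomial SEs
        assert fwer <= 0.05 + 2.5 * math.sqrt(0.05 * 0.95 / n_rep)
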