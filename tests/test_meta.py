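import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import grid_reml
from varmeta.meta import (
    RandomEffectsMeta, WaldComparison, bh_fdr, compare_subgroups,
    dersimonian_laird_tau2, i_squared, meta_regress, pool_random_effects,
    reml_tau2,
)


class TestREML:
    def test_no_heterogeneity(self):
        assert reml_tau2([0.2, 0.2], [0.03, 0.03]) == pytest.approx(0.0, abs=1e-10)

    def test_toy_set_matches_grid_search(self, toy_effects):
        y, v = toy_effects
        assert reml_tau2(y, v) == pytest.approx(grid_reml(y, v), abs=1e-4)

    def test_toy_set_matches_metafor(self, toy_effects):
        # frozen output of metafor 4.8-0 rma(method="REML") on this fixture
        y, v = toy_effects
        res = RandomEffectsMeta(y, v).fit()
        assert res.tau2 == pytest.approx(0.0204166667, abs=1e-9)
        assert res.params[0] == pytest.approx(0.1583333333, abs=1e-9)
        assert res.bse[0] == pytest.approx(0.1003466215, abs=1e-9)
        assert res.i2 == pytest.approx(33.793103, abs=1e-5)

    def test_matches_grid_on_random_small_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            k = int(rng.integers(3, 9))
            v = rng.uniform(0.005, 0.08, k)
            y = rng.normal(0, 0.25, k)
            assert reml_tau2(y, v) == pytest.approx(grid_reml(y, v), abs=1e-4)

    def test_tau_recovery_simulation(self):
        # true tau = 0.2 (tau2 = 0.04), k = 200, v = 0.01
        rng = np.random.default_rng(11)
        est = [reml_tau2(rng.normal(0, math.sqrt(0.04 + 0.01), 200),
                         np.full(200, 0.01)) for _ in range(200)]
        assert np.median(est) == pytest.approx(0.04, rel=0.20)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            reml_tau2([0.1], [0.02])
        with pytest.raises(ValueError):
            reml_tau2([0.1, 0.2], [0.02, -0.01])


class TestPooling:
    def test_identical_pair_equal_weight(self):
        pr = pool_random_effects(
            __import__("pandas").DataFrame(
                {"estimate": [0.3, 0.3], "variance": [0.04, 0.04],
                 "cohort_id": ["a", "b"]}))
        assert pr.estimate == pytest.approx(0.3, abs=1e-12)
        assert pr.se == pytest.approx(math.sqrt(0.02), abs=1e-10)
        assert pr.tau2 == pytest.approx(0.0, abs=1e-10)

    def test_tau2_zero_reduces_to_fixed_effect(self):
        y = np.array([0.10, 0.12, 0.11, 0.09])
        v = np.array([0.02, 0.03, 0.025, 0.04])
        res = RandomEffectsMeta(y, v).fit()
        assert res.tau2 == pytest.approx(0.0, abs=1e-8)
        w = 1 / v
        assert res.params[0] == pytest.approx(np.sum(w * y) / np.sum(w), abs=1e-8)
        assert res.bse[0] == pytest.approx(np.sum(w) ** -0.5, abs=1e-8)

    def test_toy_set_against_independent_arithmetic(self, toy_effects):
        # brute-force re-implementation of the pooling formulas
        y, v = toy_effects
        tau2 = grid_reml(y, v)
        w = 1 / (v + tau2)
        est = np.sum(w * y) / np.sum(w)
        se = np.sum(w) ** -0.5
        pr = pool_random_effects(
            __import__("pandas").DataFrame(
                {"estimate": y, "variance": v,
                 "cohort_id": list("abcdef")}))
        assert pr.estimate == pytest.approx(est, abs=1e-4)
        assert pr.se == pytest.approx(se, abs=1e-4)
        assert pr.ci_low == pytest.approx(pr.estimate - 1.959964 * pr.se, abs=1e-10)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            pool_random_effects(
                __import__("pandas").DataFrame(
                    {"estimate": [0.1], "variance": [0.02], "cohort_id": ["a"]}))

    def test_null_calibration(self):
        # two-sided z test under tau=0, mu=0: rejection rate 0.05 +/- 0.02
        rng = np.random.default_rng(1)
        rej = 0
        reps = 4000
        for _ in range(reps):
            v = rng.uniform(0.01, 0.05, 20)
            y = rng.normal(0, np.sqrt(v))
            rej += RandomEffectsMeta(y, v).fit().pvalues[0] < 0.05
        assert 0.03 <= rej / reps <= 0.07


class TestMetaRegression:
    def test_orthogonal_moderator_zero_slope(self):
        # construct effects exactly orthogonal to the centred moderator under
        # equal weights: slope must vanish to machine precision
        m = np.array([1.0, 2, 3, 4, 5])
        y = np.array([0.3, 0.3, 0.3, 0.3, 0.3])
        import pandas as pd
        mr = meta_regress(pd.DataFrame({"estimate": y, "variance": [0.04] * 5,
                                        "cohort_id": list("abcde")}), m)
        assert mr.slope == pytest.approx(0.0, abs=1e-12)

    def test_affine_shift_changes_only_intercept(self, toy_effects):
        y, v = toy_effects
        m = np.array([20.0, 35, 28, 50, 41, 33])
        r1 = RandomEffectsMeta(y, v, exog=m).fit()
        r2 = RandomEffectsMeta(y, v, exog=m + 17.0).fit()
        assert r2.params[1] == pytest.approx(r1.params[1], abs=1e-9)
        assert r2.params[0] != pytest.approx(r1.params[0], abs=1e-6)

    def test_matches_metafor_regression(self, toy_effects):
        # frozen output of metafor 4.8-0 rma(mods=~m, method="REML")
        y, v = toy_effects
        m = np.array([20.0, 35, 28, 50, 41, 33])
        res = RandomEffectsMeta(y, v, exog=m).fit()
        assert res.tau2 == pytest.approx(0.0102228682, abs=1e-9)
        assert res.params[1] == pytest.approx(0.0137209302, abs=1e-9)
        assert res.bse[1] == pytest.approx(0.0096663279, abs=1e-9)

    def test_slope_recovery_coverage(self):
        # beta = -0.03 per year, k = 60, tau = 0.05: true slope inside the
        # 95% CI in >= 90% of 200 replicates
        rng = np.random.default_rng(5)
        import pandas as pd
        hits = 0
        for _ in range(200):
            age = rng.normal(31, 6, 60)
            v = rng.uniform(0.01, 0.05, 60)
            y = 0.1 - 0.03 * (age - 31) + rng.normal(0, 0.05, 60) + \
                rng.normal(0, np.sqrt(v))
            mr = meta_regress(pd.DataFrame(
                {"estimate": y, "variance": v,
                 "cohort_id": [str(i) for i in range(60)]}), age)
            hits += abs(mr.slope - (-0.03)) <= 1.959964 * mr.se
        assert hits / 200 >= 0.90

    def test_constant_moderator_and_min_k(self):
        import pandas as pd
        df = pd.DataFrame({"estimate": [0.1] * 6, "variance": [0.02] * 6,
                           "cohort_id": list("abcdef")})
        with pytest.raises(ValueError, match="constant"):
            meta_regress(df, np.ones(6))
        with pytest.raises(ValueError, match="below minimum"):
            meta_regress(df.iloc[:3], [1.0, 2, 3])


class TestWald:
    def test_identical_estimates(self):
        w = WaldComparison(0.2, 0.1, 0.2, 0.1)
        assert w.z_stat == 0.0 and w.p_value == pytest.approx(1.0)

    def test_boundary_at_196(self):
        se = math.sqrt(0.1 ** 2 + 0.1 ** 2)
        w = WaldComparison(1.96 * se, 0.1, 0.0, 0.1)
        assert w.p_value == pytest.approx(0.05, abs=1e-3)

    def test_toy_values(self):
        w = WaldComparison(0.3, 0.1, 0.0, 0.1)
        assert w.z_stat == pytest.approx(0.3 / math.sqrt(0.02), abs=1e-3)
        assert w.z_stat == pytest.approx(2.121, abs=1e-3)
        assert w.p_value == pytest.approx(0.0339, abs=5e-4)

    def test_overlapping_subsets_rejected(self):
        import pandas as pd
        df = pd.DataFrame({"estimate": [0.1, 0.2, 0.3],
                           "variance": [0.02] * 3,
                           "cohort_id": ["a", "b", "c"]})
        a = pool_random_effects(df.iloc[:2])
        b = pool_random_effects(df.iloc[1:])
        with pytest.raises(ValueError, match="overlap"):
            compare_subgroups(a, b)


class TestBHFDR:
    def test_step_up_by_hand(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05, 0.2]
        assert list(bh_fdr(p, q=0.1)) == [True] * 5 + [False]

    def test_all_ones(self):
        assert not bh_fdr([1.0, 1.0, 1.0], q=0.1).any()

    def test_single_p(self):
        assert bh_fdr([0.05], q=0.1)[0]

    def test_empty(self):
        assert bh_fdr([], q=0.1).size == 0

    def test_order_and_ties_preserved(self):
        p = [0.2, 0.01, 0.01, 0.9]
        flags = bh_fdr(p, q=0.1)
        assert flags[1] == flags[2]
        assert not flags[3]

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20),
           st.floats(0.01, 0.2), st.floats(0.01, 0.2))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_q(self, p, q1, q2):
        lo, hi = min(q1, q2), max(q1, q2)
        r_lo, r_hi = bh_fdr(p, lo), bh_fdr(p, hi)
        assert np.all(r_hi | ~r_lo)  # rejections at lo are subset of those at hi


class TestI2:
    def test_scale_invariance(self):
        v = np.array([0.01, 0.02, 0.05, 0.03])
        for c in (0.1, 1.0, 7.3):
            assert i_squared(0.02 * c, v * c) == pytest.approx(
                i_squared(0.02, v), abs=1e-10)

    def test_bounds(self):
        v = np.array([0.01, 0.02, 0.05])
        assert i_squared(0.0, v) == 0.0
        assert 0 < i_squared(0.5, v) < 100


def test_summary_contains_key_quantities(toy_effects):
    y, v = toy_effects
    s = RandomEffectsMeta(y, v).fit().summary()
    assert "tau2" in s and "I2" in s and "intercept" in s
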