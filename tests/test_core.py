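"""Unit and property tests for rules and evaluation metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multiarm_itr.core import (FixedRule, Rule, TrialDataset,
                               UndefinedITREffectError, assignment_proportions,
                               deferral_target_transform, fixed_rule, ipw_value,
                               itr_effect, misclassification, utility)

from conftest import random_trial


def brute_force_ipw(data: TrialDataset, rule: Rule) -> float:
    """Independent loop oracle for the IPW value estimator (exact summation)."""
    import math

    arms = rule.decide(data.X)
    terms = []
    for i in range(data.n):
        if data.A[i] == arms[i]:
            terms.append(data.Y[i] / data.propensity[i, data.A[i] - 1])
    return math.fsum(terms) / data.n


class TestIPWValue:
    def test_toy_hand_computation(self, toy_trial):
        # rule == arm 2 matches subjects with Y = 3, 4: (1/6) * 3 * (3 + 4)
        assert ipw_value(toy_trial, fixed_rule(2)) == pytest.approx(3.5)

    def test_rule_matching_nobody_gives_zero(self, toy_trial):
        rule = Rule(decide_fn=lambda X: np.array([2, 3, 1, 3, 1, 2]), K=3)
        assert ipw_value(toy_trial, rule) == 0.0

    def test_constant_outcome_expectation(self):
        data = random_trial(999, seed=5)
        data.Y = np.ones(data.n)
        n1 = (data.A == 1).sum()
        assert ipw_value(data, fixed_rule(1)) == pytest.approx(3 * n1 / data.n)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_bitwise(self, seed):
        data = random_trial(50, seed=seed)
        rng = np.random.default_rng(seed)
        rule = Rule(decide_fn=lambda X: rng.integers(1, 4, len(X)), K=3)
        arms = rule.decide(data.X)
        frozen = Rule(decide_fn=lambda X: arms, K=3)
        assert ipw_value(data, frozen) == brute_force_ipw(data, frozen)

    def test_hajek_variant_normalizes(self, toy_trial):
        v = ipw_value(toy_trial, fixed_rule(2), normalized=True)
        assert v == pytest.approx((3 + 4) / 2)

    def test_zero_propensity_rejected(self):
        data = random_trial(30, seed=1)
        data.propensity[0] = [0.0, 0.5, 0.5]
        with pytest.raises(ValueError, match="positivity"):
            ipw_value(data, fixed_rule(1))


class TestMisclassification:
    @pytest.mark.parametrize("pred,truth,expected", [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 1, 1], [2, 2, 2], 1.0),
        ([1, 2, 3, 1], [1, 2, 1, 1], 0.25),
    ])
    def test_counts(self, pred, truth, expected):
        assert misclassification(pred, truth) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            misclassification([1, 2], [1, 2, 3])


class TestITREffect:
    def test_toy_hand_computation(self):
        X = pd.DataFrame({"x": [0.0, 1, 2, 3]})
        data = TrialDataset(X=X, A=np.array([1, 1, 2, 2]),
                            Y=np.array([4.0, 2, 1, 1]), K=2)
        assert itr_effect(data, fixed_rule(1, K=2)) == pytest.approx(2.0)

    def test_fixed_rule_identity(self):
        # delta of the constant-arm-a rule equals mean(Y|A=a) - mean(Y|A!=a)
        data = random_trial(200, seed=7)
        for a in (1, 2, 3):
            expected = data.Y[data.A == a].mean() - data.Y[data.A != a].mean()
            assert itr_effect(data, fixed_rule(a)) == pytest.approx(expected)

    def test_null_rule_effect_near_zero(self):
        data = random_trial(20_000, seed=11)
        rng = np.random.default_rng(0)
        rule = Rule(decide_fn=lambda X: rng.integers(1, 4, len(X)), K=3)
        arms = rule.decide(data.X)
        frozen = Rule(decide_fn=lambda X: arms, K=3)
        assert abs(itr_effect(data, frozen)) < 0.05

    def test_empty_group_is_distinct_signal(self):
        X = pd.DataFrame({"x": [0.0, 1]})
        data = TrialDataset(X=X, A=np.array([1, 2]), Y=np.array([1.0, 2.0]), K=2)
        all_match = Rule(decide_fn=lambda X: np.array([1, 2]), K=2)
        with pytest.raises(UndefinedITREffectError):
            itr_effect(data, all_match)


class TestUtilityAndTransform:
    @pytest.mark.parametrize("G,Rt,b,expected", [
        (10.0, 1.0, 2.0, 8.0),
        (5.0, 0.0, 7.0, 5.0),
        (5.0, 3.0, 0.0, 5.0),
    ])
    def test_utility(self, G, Rt, b, expected):
        assert utility(G, Rt, b) == expected

    @pytest.mark.parametrize("R,expected", [
        (0.0, np.pi / 2),
        (1.0, 0.0),
        (0.75, np.pi / 6),
    ])
    def test_transform_closed_forms(self, R, expected):
        assert deferral_target_transform(R) == pytest.approx(expected)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_transform_monotone_decreasing(self, r1, r2):
        lo, hi = sorted((r1, r2))
        if hi - lo > 1e-9:
            assert deferral_target_transform(lo) > deferral_target_transform(hi)

    def test_transform_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            deferral_target_transform(1.5)


class TestRulesAndProportions:
    def test_fixed_rule_constant(self, toy_trial):
        assert (fixed_rule(1).decide(toy_trial.X) == 1).all()
        np.testing.assert_allclose(
            assignment_proportions(fixed_rule(1), toy_trial.X), [1, 0, 0])

    def test_proportions_count_and_permutation_invariance(self):
        X = pd.DataFrame({"x": range(4)})
        arms = np.array([1, 1, 2, 3])
        rule = Rule(decide_fn=lambda Xn: arms[: len(Xn)], K=3)
        np.testing.assert_allclose(assignment_proportions(rule, X),
                                   [0.5, 0.25, 0.25])
        perm = np.array([3, 1, 2, 0])
        rule2 = Rule(decide_fn=lambda Xn: arms[perm], K=3)
        np.testing.assert_allclose(assignment_proportions(rule2, X),
                                   [0.5, 0.25, 0.25])

    def test_fixed_rule_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fixed_rule(4, K=3)

    def test_misclassification_of_rule_vs_itself_zero(self, toy_trial):
        arms = FixedRule(2).decide(toy_trial.X)
        assert misclassification(arms, arms) == 0.0


class TestTrialDatasetValidation:
    def test_rejects_missing_arm(self):
        X = pd.DataFrame({"x": [0.0, 1, 2]})
        with pytest.raises(ValueError, match="every arm"):
            TrialDataset(X=X, A=np.array([1, 1, 2]), Y=np.zeros(3), K=3)

    def test_rejects_nan(self):
        X = pd.DataFrame({"x": [0.0, np.nan, 2]})
        with pytest.raises(ValueError, match="missing"):
            TrialDataset(X=X, A=np.array([1, 2, 3]), Y=np.zeros(3), K=3)
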