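"""Adaptive contrast weighted learning: AIPW pseudo-estimates, contrasts, trees."""

import numpy as np
import pandas as pd
import pytest

from multiarm_itr.acwl import (build_contrasts, fit_acwl, fit_arm_means,
                               fit_weighted_tree_rule)
from multiarm_itr.core import TrialDataset

from conftest import random_trial


class TestAIPW:
    def test_toy_hand_computation(self):
        # 10 subjects, linear regressor so mu_tilde is reproducible
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x": rng.normal(size=10)})
        A = np.array([1, 2, 3, 1, 2, 3, 1, 2, 3, 1])
        Y = rng.normal(size=10)
        data = TrialDataset(X=X, A=A, Y=Y, K=3)
        model = fit_arm_means(data, regressor_spec="linear")
        # brute-force loop oracle for the augmentation
        for i in range(10):
            for a in (1, 2, 3):
                expected = model.mu_tilde[i, a - 1]
                if A[i] == a:
                    expected += (Y[i] - model.mu_tilde[i, a - 1]) / (1 / 3)
                assert model.mu_hat[i, a - 1] == pytest.approx(expected)

    def test_no_augmentation_for_other_arms(self):
        data = random_trial(60, seed=0)
        model = fit_arm_means(data, regressor_spec="linear")
        off = data.A != 2
        np.testing.assert_allclose(model.mu_hat[off, 1], model.mu_tilde[off, 1])

    def test_zero_residual_means_no_augmentation(self):
        # when the regression is exact, mu_hat == mu_tilde everywhere
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"x": rng.normal(size=90)})
        A = np.tile([1, 2, 3], 30)
        Y = 2.0 * X["x"].to_numpy() + A  # exactly linear per arm
        data = TrialDataset(X=X, A=A, Y=Y, K=3)
        model = fit_arm_means(data, regressor_spec="linear")
        np.testing.assert_allclose(model.mu_hat, model.mu_tilde, atol=1e-8)


class TestContrasts:
    def test_sorting_example(self):
        cs = build_contrasts(np.array([[1.0, 2.0, 0.5]]))
        np.testing.assert_array_equal(cs.ordering[0], [3, 1, 2])
        assert cs.l_K[0] == 2
        assert cs.C1[0] == pytest.approx(1.0)
        assert cs.C2[0] == pytest.approx(1.5)

    def test_all_equal_means(self):
        cs = build_contrasts(np.array([[2.0, 2.0, 2.0]]))
        assert cs.C1[0] == 0 and cs.C2[0] == 0

    def test_k2_contrasts_coincide(self):
        cs = build_contrasts(np.array([[0.3, 0.9]]))
        assert cs.C1[0] == cs.C2[0] == pytest.approx(0.6)
        assert cs.l_K[0] == 2

    def test_invariants_on_random_data(self):
        rng = np.random.default_rng(11)
        cs = build_contrasts(rng.normal(size=(500, 3)))
        assert (cs.C1 >= 0).all()
        assert (cs.C2 >= cs.C1).all()
        assert all(sorted(row) == [1, 2, 3] for row in cs.ordering)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="subject"):
            build_contrasts(np.array([[1.0, np.nan, 0.0]]))


class TestWeightedTree:
    def _X(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})

    def test_uniform_labels_give_constant_rule(self):
        X = self._X(100)
        rule = fit_weighted_tree_rule(X, np.full(100, 2), np.ones(100), K=3)
        assert (rule.decide(X) == 2).all()

    def test_perfect_binary_split_recovered(self):
        X = self._X(400, seed=2)
        labels = np.where(X["x1"] > 0, 1, 3)
        rule = fit_weighted_tree_rule(X, labels, np.ones(400), K=3, seed=0)
        assert np.mean(rule.decide(X) == labels) == 1.0

    def test_zero_weights_fall_back_to_majority(self):
        X = self._X(50)
        labels = np.array([1] * 30 + [2] * 20)
        with pytest.warns(UserWarning, match="zero"):
            rule = fit_weighted_tree_rule(X, labels, np.zeros(50), K=3)
        assert (rule.decide(X) == 1).all()

    def test_weight_scale_invariance(self):
        X = self._X(300, seed=7)
        rng = np.random.default_rng(7)
        labels = rng.integers(1, 4, 300)
        w = rng.uniform(0.1, 2.0, 300)
        r1 = fit_weighted_tree_rule(X, labels, w, K=3, seed=1)
        r2 = fit_weighted_tree_rule(X, labels, 2.0 * w, K=3, seed=1)
        np.testing.assert_array_equal(r1.decide(X), r2.decide(X))


class TestEndToEnd:
    def test_k2_reduces_to_single_weighted_classification(self):
        # with two arms the ACWL objective is one weighted classification with
        # weight |mu_hat_2 - mu_hat_1| and label argmax
        rng = np.random.default_rng(13)
        X = pd.DataFrame({"x": rng.normal(size=200)})
        A = np.tile([1, 2], 100)
        Y = np.where(A == 2, 1.0, -1.0) * X["x"].to_numpy() + 0.1 * rng.normal(size=200)
        data = TrialDataset(X=X, A=A, Y=Y, K=2)
        model = fit_arm_means(data, regressor_spec="linear")
        cs = build_contrasts(model.mu_hat)
        np.testing.assert_allclose(cs.C2, np.abs(model.mu_hat[:, 1] - model.mu_hat[:, 0]))
        np.testing.assert_array_equal(cs.l_K, np.argmax(model.mu_hat, axis=1) + 1)
        rule_pipeline, _ = fit_acwl(data, regressor_spec="linear", seed=0)
        rule_direct = fit_weighted_tree_rule(data.X, cs.l_K, cs.C2, K=2, seed=0)
        assert np.mean(rule_pipeline.decide(X) == rule_direct.decide(X)) == 1.0

    def test_invalid_contrast_name(self):
        data = random_trial(60, seed=0)
        with pytest.raises(ValueError):
            fit_acwl(data, contrast="C3")
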