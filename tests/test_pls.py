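"""Penalized least squares: group lasso and strong-hierarchy variants."""

import numpy as np
import pandas as pd
import pytest

from multiarm_itr.design import build_design
from multiarm_itr.pls import (fit_penalized, fit_pls, rule_from_fit,
                              selection_frequency)
from multiarm_itr.simdata import gen_setting


@pytest.fixture(scope="module")
def small_linear_trial():
    data, truth = gen_setting(2, 2000, seed=3)
    return data, truth


def _design(data):
    return build_design(data.X, data.A, data.K)


class TestPenaltyLimits:
    def test_huge_lambda_zeroes_all_groups(self, small_linear_trial):
        data, _ = small_linear_trial
        d = _design(data)
        fit = fit_penalized(d, data.Y, variant="GL", lam_grid=np.array([1e6]),
                            cv_folds=2, seed=0)
        assert not any(fit.selected_groups.values())
        # rule collapses to a marginal-best constant rule
        arms = rule_from_fit(fit).decide(data.X.head(50))
        assert len(np.unique(arms)) == 1

    def test_zero_lambda_matches_ols(self, small_linear_trial):
        data, _ = small_linear_trial
        d = _design(data)
        fit = fit_penalized(d, data.Y, variant="GL",
                            lam_grid=np.array([1e-4, 0.0]), cv_folds=2, seed=0,
                            tol=1e-14, max_iter=50000)
        ols, *_ = np.linalg.lstsq(d.matrix, data.Y, rcond=None)
        np.testing.assert_allclose(fit.beta, ols, atol=1e-6)


class TestGroupStructure:
    def test_gl_within_group_all_or_none(self, small_linear_trial):
        data, _ = small_linear_trial
        fit = fit_pls(data, variant="GL", seed=0, n_lambdas=20)[1]
        for g in fit.design.groups:
            if g.kind == "intercept":
                continue
            beta_g = fit.beta[list(g.cols)]
            if fit.selected_groups[g.name]:
                assert np.linalg.norm(beta_g) > 0
            else:
                assert (beta_g == 0).all()  # dropped groups are exactly zero

    def test_hgl_strong_hierarchy_holds_on_fits(self):
        for seed in range(3):
            data, _ = gen_setting(2, 1500, seed=seed)
            fit = fit_pls(data, variant="HGL", seed=seed, n_lambdas=20)[1]
            assert fit.satisfies_strong_hierarchy()

    def test_true_interaction_group_recovered(self):
        # setting 2's Delta involves X1, X2, X3, X4, X5 through arms 1 and 2;
        # X3 carries the strongest interaction (coefficient 5)
        hits = 0
        for seed in range(5):
            data, _ = gen_setting(2, 4000, seed=seed)
            fit = fit_pls(data, variant="GL", seed=seed, n_lambdas=25)[1]
            hits += fit.selected_interactions()["X3"]
        assert hits == 5


class TestRuleBehaviour:
    def test_reference_arm_invariance(self, small_linear_trial):
        data, _ = small_linear_trial
        d1 = build_design(data.X, data.A, data.K, arm_reference=1)
        d2 = build_design(data.X, data.A, data.K, arm_reference=3)
        lam = np.logspace(-1, -3, 10)
        f1 = fit_penalized(d1, data.Y, lam_grid=lam, cv_folds=3, seed=0)
        f2 = fit_penalized(d2, data.Y, lam_grid=lam, cv_folds=3, seed=0)
        a1 = rule_from_fit(f1).decide(data.X.head(300))
        a2 = rule_from_fit(f2).decide(data.X.head(300))
        assert np.mean(a1 == a2) > 0.97

    def test_misclassification_decreases_with_n(self):
        from multiarm_itr.core import misclassification
        from multiarm_itr.simdata import fixed_test_set
        test, truth = fixed_test_set(2, 2000, seed=0)
        rates = []
        for n in (500, 2000, 8000):
            per_rep = [
                misclassification(
                    fit_pls(gen_setting(2, n, seed=r)[0], variant="GL",
                            seed=r, n_lambdas=20)[0].decide(test.X), truth)
                for r in range(3)
            ]
            rates.append(np.mean(per_rep))
        assert rates[0] > rates[1] > rates[2]


class TestSelectionFrequency:
    def test_percentage_counting(self, small_linear_trial):
        data, _ = small_linear_trial
        fits = [fit_pls(data, variant="GL", seed=s, n_lambdas=15)[1]
                for s in range(2)]
        freq = selection_frequency(fits)
        assert set(freq.index) == set(data.X.columns)
        assert ((freq == 0) | (freq == 50) | (freq == 100)).all()

    def test_needs_two_fits(self, small_linear_trial):
        data, _ = small_linear_trial
        fit = fit_pls(data, variant="GL", seed=0, n_lambdas=10)[1]
        with pytest.raises(ValueError):
            selection_frequency([fit])
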