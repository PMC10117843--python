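"""Conditional-likelihood fits: closed forms, brute-force oracles, flags."""

import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar

import occohort.rrmodels as rm
from occohort.rrmodels import (conditional_loglik, fit_conditional,
                               fit_log_linear_quadratic, rr_trend_test)

from conftest import make_risk_set


class TestMatchedPairs:
    def test_closed_form_log_n10_over_n01(self):
        sets = ([make_risk_set(i, 1, [0]) for i in range(8)]
                + [make_risk_set(50 + i, 0, [1]) for i in range(2)]
                + [make_risk_set(80 + i, 1, [1]) for i in range(5)])
        est = fit_conditional(sets, exposure="exposed", covariates=())["exposed"]
        assert est.beta == pytest.approx(np.log(8 / 2), abs=1e-8)
        assert est.rr == pytest.approx(4.0, abs=1e-7)


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_one_parameter_grid_maximisation(self, seed):
        rng = np.random.default_rng(seed)
        sets = [make_risk_set(i, float(rng.integers(0, 4)),
                              rng.integers(0, 4, size=rng.integers(1, 4)).tolist())
                for i in range(int(rng.integers(3, 7)))]
        fit = fit_conditional(sets, exposure="cumulative", covariates=())
        est = fit["cumulative"]
        if not est.identifiable or est.separated:
            return
        X, starts, case_rows = rm._assemble(sets, "cumulative", ())[:3]
        res = minimize_scalar(lambda b: -conditional_loglik(np.array([b]), X, starts, case_rows),
                              bounds=(-8, 8), method="bounded",
                              options={"xatol": 1e-10})
        assert est.beta == pytest.approx(res.x, abs=1e-3)

    def test_optimum_beats_random_draws(self):
        rng = np.random.default_rng(99)
        sets = [make_risk_set(i, float(rng.integers(0, 3)),
                              rng.integers(0, 3, size=3).tolist()) for i in range(5)]
        fit = fit_conditional(sets, exposure="cumulative", covariates=())
        X, starts, case_rows = rm._assemble(sets, "cumulative", ())[:3]
        best = conditional_loglik(np.array([fit["cumulative"].beta]), X, starts, case_rows)
        for b in rng.normal(0, 2, size=1000):
            assert best >= conditional_loglik(np.array([b]), X, starts, case_rows) - 1e-9

    def test_two_parameter_numeric_maximisation(self):
        rng = np.random.default_rng(4)
        sets = [make_risk_set(i, (int(rng.integers(0, 3)), float(rng.uniform(0, 5))),
                              [(int(rng.integers(0, 3)), float(rng.uniform(0, 5)))
                               for _ in range(3)]) for i in range(6)]
        fit = fit_conditional(sets, exposure="linquad", covariates=())
        X, starts, case_rows = rm._assemble(sets, "linquad", ())[:3]
        res = minimize(lambda b: -conditional_loglik(b, X, starts, case_rows),
                       x0=np.zeros(2), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        got = np.array([fit["linear"].beta, fit["quadratic"].beta])
        assert np.allclose(got, res.x, atol=1e-3)


class TestFlags:
    def test_no_within_set_contrast_is_non_identifiable(self):
        sets = [make_risk_set(i, 1, [1, 1]) for i in range(4)]
        est = fit_conditional(sets, exposure="exposed", covariates=())["exposed"]
        assert not est.identifiable

    def test_complete_separation_flagged_with_infinite_bound(self):
        sets = [make_risk_set(i, 1, [0, 0]) for i in range(6)]
        est = fit_conditional(sets, exposure="exposed", covariates=())["exposed"]
        assert est.separated
        assert est.ci_high == float("inf")

    def test_empty_sets_dropped_and_counted(self):
        sets = [make_risk_set(0, 1, [0]), make_risk_set(1, 1, [])]
        sets[1].excluded = True
        fit = fit_conditional(sets, exposure="exposed", covariates=())
        assert fit.n_sets_used == 1 and fit.n_sets_dropped == 1


class TestLikelihoodProperties:
    def test_within_set_constant_shift_leaves_fit_unchanged(self):
        rng = np.random.default_rng(12)
        sets, shifted = [], []
        for i in range(10):
            case = float(rng.uniform(0, 5))
            ctls = [float(rng.uniform(0, 5)) for _ in range(3)]
            shift = float(rng.uniform(-2, 2))
            sets.append(make_risk_set(i, (0, case), [(0, c) for c in ctls]))
            shifted.append(make_risk_set(i, (0, case + shift),
                                         [(0, c + shift) for c in ctls]))
        a = fit_conditional(sets, exposure="cumulative", covariates=())["cumulative"]
        b = fit_conditional(shifted, exposure="cumulative", covariates=())["cumulative"]
        assert a.beta == pytest.approx(b.beta, abs=1e-6)

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        sets = [make_risk_set(i, float(rng.integers(0, 3)),
                              rng.integers(0, 3, size=3).tolist()) for i in range(12)]
        a = fit_conditional(sets, exposure="cumulative", covariates=())["cumulative"]
        b = fit_conditional(sets[::-1], exposure="cumulative", covariates=())["cumulative"]
        assert a.beta == pytest.approx(b.beta, abs=1e-9)


class TestDoseResponse:
    def test_null_exposure_is_flagged_identity(self):
        sets = [make_risk_set(i, (0, 0.0), [(0, 0.0)] * 3) for i in range(5)]
        model = fit_log_linear_quadratic(sets, covariates=())
        assert not model.identifiable
        assert model.rr(3.7) == 1.0

    def test_rr_at_zero_is_exactly_one(self):
        rng = np.random.default_rng(3)
        sets = [make_risk_set(i, (0, float(rng.uniform(0, 5))),
                              [(0, float(rng.uniform(0, 5))) for _ in range(3)])
                for i in range(20)]
        model = fit_log_linear_quadratic(sets, covariates=())
        assert model.rr(0.0) == 1.0

    def test_parameter_recovery_from_softmax_simulation(self):
        """Cases drawn with true beta1=0.02, beta2=0 are recovered within 2 SE."""
        rng = np.random.default_rng(17)
        b_true = 0.02
        sets = []
        for i in range(500):
            x = rng.uniform(0, 40, size=8)
            w = np.exp(b_true * x)
            case = rng.choice(8, p=w / w.sum())
            members = [(0, float(v)) for v in x]
            sets.append(make_risk_set(i, members[case],
                                      [m for j, m in enumerate(members) if j != case]))
        model = fit_log_linear_quadratic(sets, covariates=())
        se1 = np.sqrt(model.covariance[0, 0])
        assert abs(model.beta1 - b_true) < 2 * se1


class TestTrendTest:
    def test_single_category_errors(self):
        sets = [make_risk_set(i, (1, 1.0), [(1, 1.0)] * 2) for i in range(5)]
        with pytest.raises(ValueError):
            rr_trend_test(sets, covariates=())

    def test_strong_trend_detected(self):
        rng = np.random.default_rng(23)
        sets = []
        for i in range(80):
            cats = rng.integers(0, 5, size=4)
            w = np.exp(0.8 * cats)
            case = rng.choice(4, p=w / w.sum())
            members = [(int(c), float(c)) for c in cats]
            sets.append(make_risk_set(i, members[case],
                                      [m for j, m in enumerate(members) if j != case]))
        assert rr_trend_test(sets, covariates=()) < 0.01

    def test_custom_scores_accepted(self):
        rng = np.random.default_rng(31)
        sets = [make_risk_set(i, (int(rng.integers(0, 4)), 0.0),
                              [(int(rng.integers(0, 4)), 0.0) for _ in range(3)])
                for i in range(40)]
        p_rank = rr_trend_test(sets, covariates=())
        p_mid = rr_trend_test(sets, scores={0: 0.0, 1: 0.05, 2: 0.3, 3: 1.5},
                              covariates=())
        assert 0 <= p_rank <= 1 and 0 <= p_mid <= 1
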