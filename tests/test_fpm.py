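"""Flexible parametric model: MLE oracles, prediction identities, serialization."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

import crvalid as cv
from crvalid.fpm import build_design

from conftest import make_dataset


def exponential_data(rate: float, n: int, seed: int, n_causes: int = 1):
    rng = np.random.default_rng(seed)
    t = rng.exponential(1.0 / rate, size=n)
    return make_dataset(t, np.ones(n, dtype=int)) if n_causes == 1 else None


def weibull_mle(t: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    """Closed-form-profile Weibull MLE oracle: H(t) = rate * t**shape.

    For fixed shape a the rate MLE is sum(d)/sum(t**a); the profile score
    for a is solved by bracketed root finding.
    """
    ev = d == 1

    def score(a):
        w = t**a
        lam = d.sum() / w.sum()
        return d.sum() / a + np.log(t[ev]).sum() - lam * (w * np.log(t)).sum()

    a = brentq(score, 0.05, 20.0, xtol=1e-12)
    return d.sum() / (t**a).sum(), a


class TestBuildDesign:
    def test_terms(self):
        df = pd.DataFrame({"x1": [1.0, 2.0, 3.0, 4.0], "x4": [1, 2, 3, 4]})
        X, names, levels = build_design(df, ["x1", "x1**2", "C(x4)"], None)
        assert names == ["x1", "x1**2", "x4_2", "x4_3", "x4_4"]
        assert np.allclose(X[:, 1], [1.0, 4.0, 9.0, 16.0])
        assert np.allclose(X[:, 2], [0.0, 1.0, 0.0, 0.0])  # x4_2 dummy
        assert levels["C(x4)"] == [1, 2, 3, 4]

    def test_unknown_column_error(self):
        df = pd.DataFrame({"x1": [1.0]})
        with pytest.raises((KeyError, ValueError)):
            build_design(df, ["nope"], None)


class TestFitOracles:
    def test_weibull_mle_recovery_df1(self):
        # df = 1 model *is* a Weibull: its MLE must match the direct Weibull MLE
        rng = np.random.default_rng(21)
        n = 3000
        t = rng.weibull(1.4, size=n) * 2.0
        d = (t < 3.0).astype(int)
        t = np.minimum(t, 3.0)
        data = make_dataset(t, d)
        m = cv.fit_cause_specific(data, 1, [], df=1)
        rate_hat = np.exp(m.gamma[0])
        shape_hat = m.gamma[1]
        rate_mle, shape_mle = weibull_mle(t, d)
        assert rate_hat == pytest.approx(rate_mle, rel=1e-5)
        assert shape_hat == pytest.approx(shape_mle, rel=1e-5)

    def test_exponential_recovery(self):
        lam, n = 0.7, 5000
        data = exponential_data(lam, n, seed=22)
        m = cv.fit_cause_specific(data, 1, [], df=1)
        # gamma slope ~ 1 (shape), exp(intercept) ~ rate, within ~3 SE
        assert abs(m.gamma[1] - 1.0) < 3.5 / np.sqrt(n) * 1.2
        assert abs(np.exp(m.gamma[0]) - lam) / lam < 0.06
        # fitted survival tracks e^{-lam t}
        grid = np.array([0.5, 1.0, 2.0])
        S = cv.predict_survival(m, pd.DataFrame({"x": [0.0]}), grid)
        assert np.allclose(S[0], np.exp(-lam * grid), atol=0.02)

    def test_ph_effect_recovery(self):
        # binary covariate with true log hazard ratio ln 2 on cause 1
        rng = np.random.default_rng(23)
        n = 20_000
        x = rng.integers(0, 2, size=n).astype(float)
        lam = 0.3 * 2.0**x
        t = rng.exponential(1.0 / lam)
        d = (t < 8.0).astype(int)
        data = make_dataset(np.minimum(t, 8.0), d, x=x)
        m = cv.fit_cause_specific(data, 1, ["x"], df=2)
        se_approx = 2.0 / np.sqrt(n)
        assert abs(m.beta[0] - np.log(2.0)) < 3 * se_approx

    def test_zero_events_error(self):
        data = make_dataset([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="no events of cause 2"):
            cv.fit_cause_specific(data, 2, [], df=1)

    def test_nested_df_loglik_nondecreasing(self, small_sim):
        _, data, _ = small_sim
        lls = [
            cv.fit_cause_specific(data, 1, ["x1", "x2"], df=df).loglik
            for df in (1, 2, 3)
        ]
        assert lls[0] <= lls[1] + 1e-6 and lls[1] <= lls[2] + 1e-6

    def test_parameter_recovery_on_simulator(self, derivation_models, scenarios):
        # bias of beta-hat < 2% of truth (or < 0.01 absolute for small effects)
        eff = scenarios["derivation"].effects[0]
        truth = {"x1": eff.x1, "x1**2": eff.x1_sq, "x2": eff.x2, "x3": eff.x3,
                 "x4_2": eff.x4[0], "x4_3": eff.x4[1], "x4_4": eff.x4[2]}
        m = derivation_models[1]
        for name, b in zip(m.beta_names, m.beta):
            tol = max(0.02 * abs(truth[name]), 0.015)
            assert abs(b - truth[name]) < tol, (name, b, truth[name])


@pytest.fixture(scope="module")
def expo_model():
    data = exponential_data(0.5, 4000, seed=24)
    return cv.fit_cause_specific(data, 1, [], df=1)


class TestPredictions:
    def test_survival_limits_and_monotone(self, expo_model):
        cov = pd.DataFrame({"x": [0.0]})
        grid = np.linspace(0.01, 6.0, 60)
        S = cv.predict_survival(expo_model, cov, grid)[0]
        assert np.all(np.diff(S) <= 1e-12)
        assert cv.predict_survival(expo_model, cov, 1e-9)[0] == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_time_error(self, expo_model):
        with pytest.raises(ValueError):
            cv.predict_survival(expo_model, pd.DataFrame({"x": [0.0]}), 0.0)
        with pytest.raises(ValueError):
            cv.predict_hazard(expo_model, pd.DataFrame({"x": [0.0]}), -1.0)

    def test_cs_failure_complement_exact(self, expo_model):
        cov = pd.DataFrame({"x": [0.0]})
        S = cv.predict_survival(expo_model, cov, 2.0)
        F = cv.predict_cs_failure(expo_model, cov, 2.0)
        assert S + F == pytest.approx(1.0, abs=0)  # exact complement

    def test_hazard_constant_for_exponential(self, expo_model):
        cov = pd.DataFrame({"x": [0.0]})
        h = cv.predict_hazard(expo_model, cov, np.array([0.5, 1.0, 2.0, 4.0]))[0]
        # fitted shape ~ 1 but not exactly: hazard is near-constant
        assert np.allclose(h, h[0], rtol=0.02)
        assert h[0] == pytest.approx(0.5, rel=0.06)

    def test_hazard_ratio_constant_over_time(self, small_sim):
        _, _, models = small_sim
        m = models[1]
        cov = pd.DataFrame(
            {"x1": [0.0, 1.0], "x2": [0.0, -1.0], "x3": [0.0, 0.5], "x4": [1, 3]}
        )
        grid = np.array([0.5, 2.0, 5.0, 9.0])
        h = cv.predict_hazard(m, cov, grid)
        ratio = h[1] / h[0]
        assert np.allclose(ratio, ratio[0], rtol=1e-10)

    def test_hazard_integrates_to_cumhaz(self, small_sim):
        _, _, models = small_sim
        m = models[1]
        cov = pd.DataFrame({"x1": [0.3], "x2": [-0.2], "x3": [0.1], "x4": [2]})
        t_end = 6.0
        H_num, _ = quad(
            lambda u: float(cv.predict_hazard(m, cov, u)[0]), 1e-12, t_end, limit=200
        )
        H_model = -np.log(float(cv.predict_survival(m, cov, t_end)[0]))
        assert H_num == pytest.approx(H_model, abs=1e-6)


def _hand_exponential_modelset(lam1: float, lam2: float) -> cv.ModelSet:
    """Exact exponential models built directly from coefficients.

    With one log-time basis column, gamma = (log lam, 1) gives
    H(t) = lam * t exactly.
    """
    def make(cause, lam):
        return cv.CauseSpecificModel(
            cause=cause,
            knots=cv.KnotVector((-3.0, 3.0)),
            gamma=np.array([np.log(lam), 1.0]),
            beta=np.array([]),
            terms=[],
            beta_names=[],
            levels={},
            loglik=0.0,
            n=1,
            n_events=1,
            converged=True,
        )

    return cv.ModelSet({1: make(1, lam1), 2: make(2, lam2)})


class TestCIF:
    def test_constant_hazard_closed_form(self):
        models = _hand_exponential_modelset(1.0, 1.0)
        cov = pd.DataFrame(index=range(1))
        cif = cv.predict_cif(models, cov, 1.0)
        assert cif[0, 0] == pytest.approx(0.432332, abs=1e-6)
        truth = 0.5 * (1.0 - np.exp(-2.0))
        assert cif[0, 0] == pytest.approx(truth, abs=1e-7)

    def test_asymmetric_closed_form(self):
        lam1, lam2, t = 0.7, 0.2, 2.5
        models = _hand_exponential_modelset(lam1, lam2)
        cif = cv.predict_cif(models, pd.DataFrame(index=range(1)), t)
        tot = lam1 + lam2
        assert cif[0, 0] == pytest.approx(lam1 / tot * (1 - np.exp(-tot * t)), abs=1e-7)
        assert cif[0, 1] == pytest.approx(lam2 / tot * (1 - np.exp(-tot * t)), abs=1e-7)

    def test_symmetric_causes_equal(self):
        models = _hand_exponential_modelset(0.4, 0.4)
        cif = cv.predict_cif(models, pd.DataFrame(index=range(1)), 3.0)
        assert cif[0, 0] == pytest.approx(cif[0, 1], abs=1e-12)

    def test_conservation_fitted_models(self, small_sim):
        _, data, models = small_sim
        cov = data.covariates().head(50)
        for t in (0.5, 3.0, 10.0):
            cif = cv.predict_cif(models, cov, t)
            S = 1.0 - cv.predict_all_cause(models, cov, t)
            assert np.max(np.abs(S + cif.sum(axis=1) - 1.0)) < 1e-6

    def test_all_cause_equals_sum_of_cifs(self, small_sim):
        _, data, models = small_sim
        cov = data.covariates().head(50)
        cif = cv.predict_cif(models, cov, 7.0)
        allc = cv.predict_all_cause(models, cov, 7.0)
        assert np.max(np.abs(allc - cif.sum(axis=1))) < 1e-6

    def test_monotone_in_t(self, small_sim):
        _, data, models = small_sim
        cov = data.covariates().head(20)
        prev = np.zeros((20, 2))
        for t in (0.5, 1.0, 2.0, 4.0, 8.0):
            cur = cv.predict_cif(models, cov, t)
            assert np.all(cur >= prev - 1e-9)
            prev = cur

    def test_nonpositive_time_error(self):
        models = _hand_exponential_modelset(1.0, 1.0)
        with pytest.raises(ValueError):
            cv.predict_cif(models, pd.DataFrame(index=range(1)), 0.0)


class TestSerialization:
    def test_round_trip_bit_faithful(self, small_sim):
        _, data, models = small_sim
        blob = json.dumps(models.to_dict())
        back = cv.ModelSet.from_dict(json.loads(blob))
        for k in (1, 2):
            assert np.array_equal(back[k].gamma, models[k].gamma)
            assert np.array_equal(back[k].beta, models[k].beta)
            assert back[k].knots.knots == models[k].knots.knots
        cov = data.covariates().head(25)
        assert np.array_equal(
            cv.predict_cif(back, cov, 5.0), cv.predict_cif(models, cov, 5.0)
        )

    def test_prediction_design_mismatch_error(self, small_sim):
        _, _, models = small_sim
        bad = pd.DataFrame({"x1": [0.0], "x2": [0.0], "x3": [0.0], "x4": [9]})
        with pytest.raises(ValueError):
            models[1].linear_predictor(bad)
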