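"""IPCW Brier scores, censoring/competing-event weights, null models, IPA."""

import dataclasses

import numpy as np
import pytest

import crvalid as cv
from crvalid.performance import fit_censoring_fpm
from crvalid.simulator import default_config, simulate_dataset

from conftest import make_dataset, random_dataset


def no_censoring_data():
    # n = 4, no censoring: two cause-1 events by t*=5, two cause-2 events after
    return make_dataset([1.0, 2.0, 6.0, 7.0], [1, 1, 2, 2])


class TestCensoringWeights:
    def test_administrative_only_all_ones(self):
        data = make_dataset([1.0, 2.0, 10.0, 10.0], [1, 2, 0, 0])
        w = cv.censoring_weights(data, 5.0)
        assert np.all(w.g_event == 1.0)
        assert np.all(w.g_tstar == 1.0)

    def test_hand_half_censored(self):
        # G(1.5) = 0.5 -> weight 2 for later events
        data = make_dataset([1.0, 1.0, 2.0, 2.0], [0, 0, 1, 2])
        w = cv.censoring_weights(data, 3.0)
        assert w.g_event[2] == pytest.approx(0.5)  # 1/G = 2

    def test_event_weights_use_left_limit(self):
        # subject with event at the censoring time gets G just before it
        data = make_dataset([1.0, 1.0, 3.0], [0, 1, 1])
        w = cv.censoring_weights(data, 2.0)
        assert w.g_event[1] == pytest.approx(1.0)  # G(1-) = 1

    def test_nonincreasing_in_time(self):
        data = random_dataset(39, n=250)
        w = cv.censoring_weights(data, 2.0)
        order = np.argsort(data.time)
        assert np.all(np.diff(w.g_event[order]) <= 1e-15)

    def test_fpm_method_close_to_reverse_km(self):
        cfg = dataclasses.replace(default_config(n=3000, seed=31),
                                  censoring_rate=0.05)
        data = simulate_dataset(cfg)
        a = cv.censoring_weights(data, 8.0, method="reverse_km")
        b = cv.censoring_weights(data, 8.0, method="fpm")
        assert np.median(np.abs(a.g_event - b.g_event)) < 0.02

    def test_unknown_method_error(self):
        with pytest.raises(ValueError):
            cv.censoring_weights(no_censoring_data(), 5.0, method="nope")


class TestCompetingEventWeights:
    def test_no_competing_events_all_ones(self):
        data = make_dataset([1.0, 2.0, 3.0, 8.0], [1, 1, 1, 0],
                            x=[0.1, -0.2, 0.3, 0.0])
        base = cv.censoring_weights(data, 5.0)
        w = cv.competing_event_weights(data, 1, [], base, 5.0)
        assert np.all(w.gk_event == 1.0)
        assert np.all(w.gk_tstar == 1.0)

    def test_exponential_competing_oracle(self):
        # covariate-free competing hazard lam2: G_k(t) ~ e^{-lam2 t}
        rng = np.random.default_rng(32)
        n, lam1, lam2 = 8000, 0.25, 0.15
        t = rng.exponential(1.0 / (lam1 + lam2), size=n)
        cause = 1 + (rng.uniform(size=n) < lam2 / (lam1 + lam2)).astype(int)
        t_cl = np.minimum(t, 10.0)
        status = np.where(t > 10.0, 0, cause)
        data = make_dataset(t_cl, status)
        base = cv.censoring_weights(data, 8.0)
        w = cv.competing_event_weights(data, 1, [], base, 8.0, df=2, td_df=0)
        grid_idx = data.time < 8.0
        expect = np.exp(-lam2 * data.time[grid_idx])
        assert np.median(np.abs(w.gk_event[grid_idx] - expect)) < 0.01

    def test_td_effects_nest_proportional(self, small_sim):
        _, data, _ = small_sim
        mask = data.status == 2
        m0 = fit_censoring_fpm(data, mask, ["x1", "x2"], df=2, td_df=0)
        m2 = fit_censoring_fpm(data, mask, ["x1", "x2"], df=2, td_df=2)
        assert m2.loglik >= m0.loglik - 1e-6


class TestBrierOracles:
    def test_perfect_predictions_zero(self):
        data = no_censoring_data()
        w = cv.censoring_weights(data, 5.0)
        pred = np.array([1.0, 1.0, 0.0, 0.0])  # exactly the indicators
        assert cv.brier_cif(data, pred, w, 5.0, 1) == 0.0

    def test_half_events_constant_half_prediction(self):
        # no censoring, F = 0.5, half cause-k events by t* -> 0.25 exactly
        data = no_censoring_data()
        w = cv.censoring_weights(data, 5.0)
        assert cv.brier_cif(data, 0.5, w, 5.0, 1) == pytest.approx(0.25, abs=0)

    def test_hand_quarter_prediction(self):
        # F = 0.25: (2*0.5625 + 2*0.0625)/4 = 0.3125
        data = no_censoring_data()
        w = cv.censoring_weights(data, 5.0)
        assert cv.brier_cif(data, 0.25, w, 5.0, 1) == pytest.approx(0.3125, abs=0)

    def test_no_censoring_equals_plain_mse(self):
        data = random_dataset(33, n=300)
        frame = data.frame.copy()
        frame.loc[frame["status"] == 0, "status"] = 1
        data = cv.SurvivalDataset(frame)
        t_star = float(np.median(data.time))
        rng = np.random.default_rng(34)
        pred = rng.uniform(size=data.n)
        w = cv.censoring_weights(data, t_star)
        ind = ((data.time <= t_star) & (data.status == 1)).astype(float)
        assert cv.brier_cif(data, pred, w, t_star, 1) == pytest.approx(
            np.mean((ind - pred) ** 2), abs=1e-14
        )

    def test_cs_failure_equals_cif_single_cause(self):
        # one cause only: identical indicators, G_k = 1
        rng = np.random.default_rng(35)
        t = rng.exponential(2.0, size=400)
        status = (t < 4.0).astype(int)
        data = make_dataset(np.minimum(t, 4.0), status)
        w = cv.censoring_weights(data, 3.0)
        pred = rng.uniform(size=400)
        assert cv.brier_cs_failure(data, pred, w, 3.0, 1) == pytest.approx(
            cv.brier_cif(data, pred, w, 3.0, 1), abs=1e-14
        )

    def test_order_and_duplication_invariance(self):
        data = random_dataset(36, n=200)
        t_star = 2.0
        rng = np.random.default_rng(37)
        pred = rng.uniform(size=data.n)
        w = cv.censoring_weights(data, t_star)
        b = cv.brier_cif(data, pred, w, t_star, 1)
        # permutation
        perm = rng.permutation(data.n)
        pdata = cv.SurvivalDataset(data.frame.iloc[perm].reset_index(drop=True))
        pw = cv.censoring_weights(pdata, t_star)
        assert cv.brier_cif(pdata, pred[perm], pw, t_star, 1) == pytest.approx(b, abs=1e-14)
        # duplication (weights recomputed on the doubled data)
        ddata = cv.SurvivalDataset(
            data.frame.iloc[np.r_[0:data.n, 0:data.n]].reset_index(drop=True)
        )
        dw = cv.censoring_weights(ddata, t_star)
        dpred = np.r_[pred, pred]
        assert cv.brier_cif(ddata, dpred, dw, t_star, 1) == pytest.approx(b, abs=1e-12)

    def test_ipcw_unbiased_against_true_score(self):
        # random censoring: IPCW score ~ uncensored-score of the same DGM
        rng = np.random.default_rng(38)
        n, lam, p0 = 30_000, 0.4, None
        t = rng.exponential(1.0 / lam, size=n)
        c = rng.exponential(2.5, size=n)
        obs = np.minimum(t, c)
        status = (t <= c).astype(int)
        data = make_dataset(obs, status)
        t_star = 1.5
        p0 = 1.0 - np.exp(-lam * t_star)  # true risk, constant prediction
        w = cv.censoring_weights(data, t_star)
        b = cv.brier_cif(data, p0, w, t_star, 1)
        truth = p0 * (1 - p0)  # E[(Y - p0)^2] with Y ~ Bernoulli(p0)
        assert abs(b - truth) < 0.01

    def test_missing_predictions_error(self):
        data = no_censoring_data()
        w = cv.censoring_weights(data, 5.0)
        with pytest.raises(ValueError):
            cv.brier_cif(data, np.array([0.1, 0.2]), w, 5.0, 1)
        with pytest.raises(ValueError):
            cv.brier_cif(data, np.array([0.1, np.nan, 0.2, 0.3]), w, 5.0, 1)


class TestNullBrier:
    def test_no_censoring_variance_identity(self):
        data = no_censoring_data()
        w = cv.censoring_weights(data, 5.0)
        # event fraction p = 0.5 -> null Brier = p(1-p) = 0.25
        assert cv.null_brier(data, 5.0, 1, "cif", w) == pytest.approx(0.25, abs=0)

    def test_variance_identity_general_p(self):
        data = make_dataset([1.0, 6.0, 7.0, 8.0], [1, 2, 2, 1])
        w = cv.censoring_weights(data, 5.0)
        p = 0.25  # one of four events by t*
        assert cv.null_brier(data, 5.0, 1, "cif", w) == pytest.approx(p * (1 - p), abs=1e-14)

    def test_all_cause_target(self):
        data = no_censoring_data()
        w = cv.censoring_weights(data, 5.0)
        assert cv.null_brier(data, 5.0, 0, "all_cause", w) == pytest.approx(0.25)

    def test_unknown_target_error(self):
        data = no_censoring_data()
        w = cv.censoring_weights(data, 5.0)
        with pytest.raises(ValueError):
            cv.null_brier(data, 5.0, 1, "nope", w)


class TestIPA:
    def test_null_vs_null_zero(self):
        assert cv.ipa(0.2, 0.2) == 0.0

    def test_perfect_model_one(self):
        assert cv.ipa(0.0, 0.2) == 1.0

    def test_arithmetic(self):
        assert cv.ipa(0.1, 0.2) == pytest.approx(0.5)

    def test_negative_for_adversarial_predictions(self):
        data = no_censoring_data()
        w = cv.censoring_weights(data, 5.0)
        adversarial = np.array([0.0, 0.0, 1.0, 1.0])  # opposite of the truth
        b = cv.brier_cif(data, adversarial, w, 5.0, 1)
        bn = cv.null_brier(data, 5.0, 1, "cif", w)
        assert cv.ipa(b, bn) < 0

    def test_nonpositive_null_error(self):
        with pytest.raises(ValueError):
            cv.ipa(0.1, 0.0)
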