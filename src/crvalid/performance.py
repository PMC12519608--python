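"""IPCW Brier scores, null-model benchmarks and the Index of Prediction Accuracy.

The Brier score at a landmark t* compares event indicators with predicted
risks, reweighting observed contributions by the inverse probability of
remaining uncensored so that subjects lost to censoring are represented by
those still observed:

* cause-specific absolute risk target: indicator I(T <= t*, K = k) vs the
  predicted CIF, with ordinary censoring weights 1/G;
* cause-specific failure target 1 - S_k: the competing event acts as an
  additional (dependent) censoring process, handled by a second weight
  1/G_k from a flexible parametric model for the competing event with
  time-dependent covariate effects; competing-event subjects are treated as
  censored for cause k at their event time.

The Index of Prediction Accuracy rescales a model's Brier score against a
covariate-free null model (Aalen-Johansen for CIF targets, cause-specific
Kaplan-Meier for 1 - S_k): IPA = 1 - B / B_null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import SurvivalDataset
from .fpm import _maximize, build_design, fit_cause_specific, predict_survival
from .nonparam import aalen_johansen, kaplan_meier, reverse_km_censoring
from .splines import make_knots, rcs_basis, rcs_deriv_basis

__all__ = [
    "CensoringWeights",
    "PerformanceResult",
    "CensoringFPM",
    "censoring_weights",
    "competing_event_weights",
    "brier_cif",
    "brier_cs_failure",
    "brier_all_cause",
    "null_brier",
    "ipa",
]


@dataclass
class CensoringWeights:
    """Censoring-survival evaluations needed by the IPCW Brier score.

    ``g_event[i]`` is G(T_i-) (used when subject i has an event by t*) and
    ``g_tstar[i]`` is G(t*-) (used when subject i is still event-free at
    t*).  ``gk_*`` are the analogous competing-event survival terms for the
    1 - S_k target; they default to 1.
    """

    g_event: np.ndarray
    g_tstar: np.ndarray
    gk_event: np.ndarray | None = None
    gk_tstar: np.ndarray | None = None
    source: str = "reverse_km"


@dataclass(frozen=True)
class PerformanceResult:
    t_star: float
    cause: int
    target: str
    brier: float
    brier_null: float
    ipa: float


# ---------------------------------------------------------------------------
# censoring models
# ---------------------------------------------------------------------------

def censoring_weights(
    data: SurvivalDataset,
    t_star: float,
    method: str = "reverse_km",
    terms: list[str] | None = None,
    df: int = 3,
) -> CensoringWeights:
    """Ordinary censoring weights G(T_i-) / G(t*-).

    ``method="reverse_km"`` (default) uses the reverse Kaplan-Meier;
    ``method="fpm"`` fits a flexible parametric model to the censoring
    times with covariates ``terms``.
    """
    T = data.time
    if method == "reverse_km":
        G = reverse_km_censoring(data)
        g_event = np.asarray(G.left(T), dtype=float)
        g_tstar = np.full(data.n, float(G.left(t_star)))
    elif method == "fpm":
        cens = SurvivalDataset(
            data.frame.assign(status=(data.status == 0).astype(int)), n_causes=1
        )
        model = fit_cause_specific(cens, 1, terms or [], df=df)
        g_event = _rowwise_survival_plain(model, data.covariates(), T)
        g_tstar = predict_survival(model, data.covariates(), t_star)
    else:
        raise ValueError(f"unknown censoring-weight method {method!r}")
    _check_positive(data, t_star, g_event, g_tstar)
    return CensoringWeights(g_event, g_tstar, source=method)


def _rowwise_survival_plain(model, cov: pd.DataFrame, t: np.ndarray) -> np.ndarray:
    """S(t_i | x_i) for subject-specific times under a proportional model."""
    log_t = np.log(np.asarray(t, dtype=float))
    B = rcs_basis(log_t, model.knots)
    eta = model.gamma[0] + B @ model.gamma[1:] + model.linear_predictor(cov)
    return np.exp(-np.exp(eta))


def _event_free_at(data: SurvivalDataset, t_star: float) -> np.ndarray:
    """Event-free at t*: T > t*, or censored exactly at t* (administrative)."""
    return (data.time > t_star) | ((data.time == t_star) & (data.status == 0))


def _check_positive(data, t_star, g_event, g_tstar) -> None:
    ev = (data.time <= t_star) & (data.status > 0)
    atr = _event_free_at(data, t_star)
    if np.any(g_event[ev] <= 0) or np.any(np.atleast_1d(g_tstar)[atr] <= 0):
        raise ValueError("non-positive censoring weight at a needed evaluation time")


@dataclass
class CensoringFPM:
    """Flexible parametric competing-event model with time-dependent effects.

    Used to build the second IPCW weight G_k for the 1 - S_k Brier score:
    the "event" is failure from any cause other than k, and covariate
    effects may vary with log time through spline interactions (``delta``).
    ``None``-like degenerate case (no competing events) is represented by
    ``trivial=True`` and predicts survival 1 everywhere.
    """

    trivial: bool = False
    knots: object | None = None
    td_knots: object | None = None
    gamma: np.ndarray | None = None        # intercept + baseline spline coefs
    delta: np.ndarray | None = None        # (n_covariates, td_df) TD coefs
    beta: np.ndarray | None = None
    terms: list[str] | None = None
    beta_names: list[str] | None = None
    levels: dict | None = None
    loglik: float = 0.0

    def survival(self, cov: pd.DataFrame, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if t.ndim == 0:
            t = np.full(len(cov), float(t))
        if self.trivial:
            return np.ones(len(cov))
        log_t = np.log(t)
        B = rcs_basis(log_t, self.knots)
        X, names, _ = build_design(cov, self.terms, self.levels)
        if names != self.beta_names:
            raise ValueError("prediction design does not match the fitted design")
        eta = self.gamma[0] + B @ self.gamma[1:] + X @ self.beta
        if self.delta is not None and self.delta.size:
            Btd = rcs_basis(log_t, self.td_knots)
            eta = eta + np.einsum("nj,nt,jt->n", X, Btd, self.delta)
        return np.exp(-np.exp(eta))


def fit_censoring_fpm(
    data: SurvivalDataset,
    event_mask: np.ndarray,
    terms: list[str],
    df: int = 3,
    td_df: int = 2,
) -> CensoringFPM:
    """Fit the flexible parametric censoring model for an arbitrary event.

    ``event_mask`` marks the rows whose exit counts as the event; everyone
    else is censored at their time.  ``td_df`` spline columns interact with
    every covariate (0 = proportional effects).
    """
    d = np.asarray(event_mask, dtype=float)
    if d.sum() == 0:
        return CensoringFPM(trivial=True)
    t = data.time
    log_t = np.log(t)
    log_ev = log_t[d == 1]
    X, names, levels = build_design(data.covariates(), terms, None)
    knots = make_knots(log_ev, n_interior=df - 1, boundary_percentiles=(0.0, 100.0))
    B = rcs_basis(log_t, knots)
    B1 = rcs_deriv_basis(log_t, knots)
    q = X.shape[1]

    td_knots = None
    if td_df > 0 and q > 0:
        td_knots = make_knots(log_ev, n_interior=td_df - 1, boundary_percentiles=(0.0, 100.0))
        Btd = rcs_basis(log_t, td_knots)
        B1td = rcs_deriv_basis(log_t, td_knots)
        B_ext = np.hstack([B] + [X[:, [j]] * Btd for j in range(q)])
        B1_ext = np.hstack([B1] + [X[:, [j]] * B1td for j in range(q)])
    else:
        td_df = 0
        B_ext, B1_ext = B, B1

    # warm start: proportional model first, then free the TD coefficients
    theta0 = np.zeros(1 + B.shape[1] + q)
    theta0[0] = np.log(d.sum() / t.sum())
    theta0[1] = 1.0
    theta_ph, _, _, _ = _maximize(theta0, (B, B1, X, d, log_t), gtol=1e-6, max_newton=50)

    theta0 = np.zeros(1 + B_ext.shape[1] + q)
    theta0[: 1 + B.shape[1]] = theta_ph[: 1 + B.shape[1]]
    theta0[1 + B_ext.shape[1]:] = theta_ph[1 + B.shape[1]:]
    theta, f, gnorm, converged = _maximize(
        theta0, (B_ext, B1_ext, X, d, log_t), gtol=1e-6, max_newton=50
    )
    if not converged:
        raise RuntimeError(
            f"censoring model did not converge (max |gradient| = {gnorm:.3g})"
        )
    df_base = B.shape[1]
    delta = (
        theta[1 + df_base: 1 + df_base + q * td_df].reshape(q, td_df)
        if td_df > 0
        else np.empty((q, 0))
    )
    return CensoringFPM(
        trivial=False,
        knots=knots,
        td_knots=td_knots,
        gamma=theta[: 1 + df_base],
        delta=delta,
        beta=theta[1 + df_base + q * td_df:],
        terms=list(terms),
        beta_names=names,
        levels=levels,
        loglik=-f,
    )


def competing_event_weights(
    data: SurvivalDataset,
    cause: int,
    terms: list[str],
    weights: CensoringWeights,
    t_star: float,
    df: int = 3,
    td_df: int = 2,
) -> CensoringWeights:
    """Extend ``weights`` with competing-event survival terms G_k.

    Fits the flexible parametric model for the competing event (any cause
    other than ``cause``) with time-dependent effects and evaluates it at
    each subject's event time and at t*.
    """
    mask = (data.status > 0) & (data.status != cause)
    model = fit_censoring_fpm(data, mask, terms, df=df, td_df=td_df)
    cov = data.covariates()
    gk_event = model.survival(cov, data.time)
    gk_tstar = model.survival(cov, t_star)
    needed = np.concatenate(
        [gk_event[(data.time <= t_star) & (data.status == cause)],
         gk_tstar[_event_free_at(data, t_star)]]
    )
    if needed.size and np.min(needed) < 0.01:
        warnings.warn("competing-event censoring weight below 0.01", stacklevel=2)
    return CensoringWeights(
        g_event=weights.g_event,
        g_tstar=weights.g_tstar,
        gk_event=gk_event,
        gk_tstar=gk_tstar,
        source=weights.source + "+competing_fpm",
    )


# ---------------------------------------------------------------------------
# Brier scores
# ---------------------------------------------------------------------------

def _as_pred(predictions: np.ndarray, n: int) -> np.ndarray:
    p = np.asarray(predictions, dtype=float)
    if p.ndim == 0:
        p = np.full(n, float(p))
    if p.shape != (n,):
        raise ValueError("one prediction per subject is required")
    if np.any(~np.isfinite(p)):
        raise ValueError("missing or non-finite predictions")
    return p


def brier_cif(
    data: SurvivalDataset,
    predictions: np.ndarray,
    weights: CensoringWeights,
    t_star: float,
    cause: int,
) -> float:
    """IPCW Brier score for the cause-specific absolute risk at t*."""
    p = _as_pred(predictions, data.n)
    T, D = data.time, data.status
    ev = (T <= t_star) & (D > 0)
    evk = ((T <= t_star) & (D == cause)).astype(float)
    atr = _event_free_at(data, t_star)
    _check_positive(data, t_star, weights.g_event, weights.g_tstar)
    contrib = np.zeros(data.n)
    contrib[ev] = (evk[ev] - p[ev]) ** 2 / weights.g_event[ev]
    contrib[atr] = p[atr] ** 2 / np.atleast_1d(weights.g_tstar)[atr]
    return float(contrib.mean())


def brier_cs_failure(
    data: SurvivalDataset,
    predictions: np.ndarray,
    weights: CensoringWeights,
    t_star: float,
    cause: int,
) -> float:
    """IPCW Brier score for 1 - S_k at t* with dual censoring weights.

    Competing-event subjects are censored for cause k at their event time:
    they contribute to neither term and the double weights 1/(G G_k)
    redistribute their mass over the remaining subjects.
    """
    p = _as_pred(predictions, data.n)
    T, D = data.time, data.status
    evk = (T <= t_star) & (D == cause)
    atr = _event_free_at(data, t_star)
    gk_event = weights.gk_event if weights.gk_event is not None else np.ones(data.n)
    gk_tstar = weights.gk_tstar if weights.gk_tstar is not None else np.ones(data.n)
    ge = weights.g_event * gk_event
    gt = np.atleast_1d(weights.g_tstar) * np.atleast_1d(gk_tstar)
    if np.any(ge[evk] <= 0) or np.any(gt[atr] <= 0):
        raise ValueError("non-positive censoring weight at a needed evaluation time")
    contrib = np.zeros(data.n)
    contrib[evk] = (1.0 - p[evk]) ** 2 / ge[evk]
    contrib[atr] = p[atr] ** 2 / gt[atr]
    return float(contrib.mean())


def brier_all_cause(
    data: SurvivalDataset,
    predictions: np.ndarray,
    weights: CensoringWeights,
    t_star: float,
) -> float:
    """IPCW Brier score for the all-cause absolute risk at t*."""
    p = _as_pred(predictions, data.n)
    T, D = data.time, data.status
    ev = (T <= t_star) & (D > 0)
    atr = _event_free_at(data, t_star)
    _check_positive(data, t_star, weights.g_event, weights.g_tstar)
    contrib = np.zeros(data.n)
    contrib[ev] = (1.0 - p[ev]) ** 2 / weights.g_event[ev]
    contrib[atr] = p[atr] ** 2 / np.atleast_1d(weights.g_tstar)[atr]
    return float(contrib.mean())


def null_brier(
    data: SurvivalDataset,
    t_star: float,
    cause: int,
    target: str,
    weights: CensoringWeights,
) -> float:
    """Brier score of the covariate-free null model.

    CIF target: constant Aalen-Johansen estimate; 1 - S_k target: constant
    complement of the cause-specific KM, scored with the dual weights;
    all-cause target: constant complement of the all-cause KM.
    """
    if target == "cif":
        pred = aalen_johansen(data, cause)(t_star)
        return brier_cif(data, pred, weights, t_star, cause)
    if target == "cs_failure":
        pred = 1.0 - kaplan_meier(data, cause)(t_star)
        return brier_cs_failure(data, pred, weights, t_star, cause)
    if target == "all_cause":
        pred = 1.0 - kaplan_meier(data, "any")(t_star)
        return brier_all_cause(data, pred, weights, t_star)
    raise ValueError(f"unknown target {target!r}")


def ipa(brier: float, brier_null: float) -> float:
    """Index of Prediction Accuracy: 1 - B/B_null (1 perfect, 0 useless)."""
    if brier_null <= 0:
        raise ValueError("null-model Brier score must be positive")
    return 1.0 - brier / brier_null
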