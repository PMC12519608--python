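"""Calibration curves and statistics from pseudo-observations.

Observed risks (jackknife pseudo-values, which may fall outside [0, 1]) are
regressed on functions of the predicted risk with a logit link, solving the
quasi-likelihood estimating equations by iteratively reweighted least
squares; the canonical link makes the weights cancel from the score, so the
fit is plain logistic-regression IRLS that tolerates out-of-range responses.

Three regressions share this engine:

* the smoothed calibration curve — restricted cubic spline of
  logit(predicted risk), boundary knots at the 5th/95th percentiles;
* the calibration slope — coefficient of logit(predicted risk), ideal 1;
* calibration-in-the-large (CITL) — intercept with logit(predicted risk) as
  a fixed offset, ideal 0.

The observed/expected ratio mean(theta) / mean(predicted) completes the set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .pseudo import PseudoObservationSet, make_risk_groups
from .splines import make_knots, rcs_basis

__all__ = [
    "CalibrationResult",
    "calibration_curve",
    "calibration_slope_citl",
    "oe_ratio",
    "grouped_points",
    "calibrate",
]

_CLAMP = 1e-10


@dataclass
class CalibrationResult:
    """Smoothed curve, grouped points and summary statistics at a landmark."""

    t_star: float
    target: str
    cause: int
    grid: np.ndarray          # predicted-risk grid
    curve: np.ndarray         # fitted observed risk on the grid
    groups: pd.DataFrame      # mean predicted / mean observed / count per group
    slope: float
    citl: float
    oe: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray


def _irls_logit(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | float = 0.0,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> np.ndarray:
    """Solve sum_i x_i (y_i - expit(x_i'b + offset_i)) = 0 by damped IRLS."""
    beta = np.zeros(X.shape[1])
    ybar = float(np.clip(np.mean(y), 0.01, 0.99))
    if np.allclose(X[:, 0], 1.0):
        beta[0] = logit(ybar) - float(np.mean(np.atleast_1d(offset)))
    score_scale = max(1.0, y.size)
    for _ in range(max_iter):
        eta = X @ beta + offset
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("calibration regression is singular") from exc
        # dampen huge steps for stability far from the solution
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step *= 10.0 / norm
        beta = beta + step
        if np.max(np.abs(score)) / score_scale < tol and norm < 1e-8:
            return beta
    if np.max(np.abs(score)) / score_scale > 1e-6:
        raise RuntimeError("calibration regression did not converge")
    return beta


def _validated_logit_pred(predicted: np.ndarray) -> np.ndarray:
    predicted = np.asarray(predicted, dtype=float)
    if np.any((predicted <= 0) | (predicted >= 1)):
        warnings.warn(
            "predicted risks at 0 or 1 clamped away from the boundary",
            stacklevel=3,
        )
        predicted = np.clip(predicted, _CLAMP, 1.0 - _CLAMP)
    if np.unique(predicted).size == 1:
        raise ValueError("degenerate predictor: all predicted risks identical")
    return logit(predicted)


def calibration_curve(
    pseudo: PseudoObservationSet,
    predicted: np.ndarray,
    n_interior_knots: int = 3,
    boundary_percentiles: tuple[float, float] = (5.0, 95.0),
    grid_size: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Spline-smoothed calibration curve.

    Returns ``(grid, curve)``: an equally spaced grid of predicted risk
    between the boundary knots and the fitted observed risk on it (bounded
    in (0, 1) by the logit link).
    """
    theta = pseudo.theta
    z = _validated_logit_pred(predicted)
    if theta.shape != z.shape:
        raise ValueError("pseudo-values and predictions must align one-to-one")
    knots = make_knots(z, n_interior_knots, boundary_percentiles)
    X = np.column_stack([np.ones_like(z), rcs_basis(z, knots)])
    beta = _irls_logit(theta, X)
    z_lo, z_hi = knots.boundary
    grid = np.linspace(expit(z_lo), expit(z_hi), grid_size)
    Xg = np.column_stack([np.ones(grid_size), rcs_basis(logit(grid), knots)])
    return grid, expit(Xg @ beta)


def calibration_slope_citl(
    pseudo: PseudoObservationSet, predicted: np.ndarray
) -> tuple[float, float]:
    """Calibration slope (ideal 1) and calibration-in-the-large (ideal 0).

    Slope: coefficient of logit(predicted) in the logit-link pseudo-value
    regression.  CITL: intercept of the same regression refitted with
    logit(predicted) as a fixed offset.
    """
    theta = pseudo.theta
    z = _validated_logit_pred(predicted)
    X = np.column_stack([np.ones_like(z), z])
    beta = _irls_logit(theta, X)
    slope = float(beta[1])
    citl = float(_irls_logit(theta, np.ones((z.size, 1)), offset=z)[0])
    return slope, citl


def oe_ratio(pseudo: PseudoObservationSet, predicted: np.ndarray) -> float:
    """Observed/expected ratio mean(theta) / mean(predicted); ideal 1."""
    predicted = np.asarray(predicted, dtype=float)
    return float(pseudo.theta.mean() / predicted.mean())


def grouped_points(
    pseudo: PseudoObservationSet, predicted: np.ndarray, n_groups: int = 15
) -> pd.DataFrame:
    """Mean predicted vs mean pseudo-observed risk in equal-percentile groups."""
    predicted = np.asarray(predicted, dtype=float)
    grouping = make_risk_groups(predicted, n_groups)
    df = pd.DataFrame(
        {"group": grouping.labels, "predicted": predicted, "observed": pseudo.theta}
    )
    out = df.groupby("group").agg(
        predicted=("predicted", "mean"),
        observed=("observed", "mean"),
        count=("group", "size"),
    )
    return out.reset_index()


def calibrate(
    pseudo: PseudoObservationSet,
    predicted: np.ndarray,
    n_interior_knots: int = 3,
    boundary_percentiles: tuple[float, float] = (5.0, 95.0),
    n_groups: int = 15,
    n_hist_bins: int = 50,
) -> CalibrationResult:
    """All calibration outputs for one target at one landmark."""
    predicted = np.asarray(predicted, dtype=float)
    grid, curve = calibration_curve(
        pseudo, predicted, n_interior_knots, boundary_percentiles
    )
    slope, citl = calibration_slope_citl(pseudo, predicted)
    counts, edges = np.histogram(predicted, bins=n_hist_bins, range=(0.0, 1.0))
    return CalibrationResult(
        t_star=pseudo.t_star,
        target=pseudo.target,
        cause=pseudo.cause,
        grid=grid,
        curve=curve,
        groups=grouped_points(pseudo, predicted, n_groups),
        slope=slope,
        citl=citl,
        oe=oe_ratio(pseudo, predicted),
        hist_edges=edges,
        hist_counts=counts,
    )
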