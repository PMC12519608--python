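"""Jackknife pseudo-observations at a landmark time.

A pseudo-observation replaces subject i's incompletely observed outcome by

    theta_i = n * theta_hat - (n - 1) * theta_hat^(-i),

where theta_hat is a nonparametric estimator of the event probability at
the landmark and theta_hat^(-i) its leave-one-out recomputation.  Two
targets are supported: the Aalen-Johansen cumulative incidence (for
calibrating cause-specific absolute risks) and the complement of the
cause-specific Kaplan-Meier (for calibrating each cause-specific model),
the latter optionally stratified into prognostic-index risk groups so that
the within-group independent-censoring assumption is more plausible under
dependent censoring by the competing event.

Leave-one-out estimates are computed in O(n log n) from prefix sums over
the risk-set table: removing subject i lowers every at-risk count at times
up to its exit and (for events) one event count, so each leave-one-out
curve differs from the full-sample curve by a per-subject multiplicative
factor plus one boundary term.  A brute-force leave-one-out evaluator is
provided for cross-checking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import SurvivalDataset
from .nonparam import aalen_johansen, kaplan_meier, risk_set_table

__all__ = [
    "RiskGrouping",
    "PseudoObservationSet",
    "make_risk_groups",
    "pseudo_cif",
    "pseudo_cs_failure",
    "pseudo_all_cause",
    "brute_force_pseudo",
]


@dataclass(frozen=True)
class RiskGrouping:
    """Subject-to-risk-group assignment with group proportions."""

    labels: np.ndarray  # values in 1..R
    n_groups: int

    @property
    def proportions(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_groups + 1)[1:] / self.labels.size


@dataclass(frozen=True)
class PseudoObservationSet:
    """Per-subject pseudo-values theta_i for one target at one landmark."""

    t_star: float
    cause: int
    target: str  # "cif" | "cs_failure" | "all_cause"
    theta: np.ndarray
    grouping: RiskGrouping | None = None

    @property
    def mean(self) -> float:
        return float(self.theta.mean())


def make_risk_groups(predicted: np.ndarray, n_groups: int) -> RiskGrouping:
    """Split subjects into ``n_groups`` equal-percentile groups of ``predicted``.

    Group sizes differ by at most one; ties are broken by stable sort order.
    """
    predicted = np.asarray(predicted, dtype=float)
    n = predicted.size
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_groups > n:
        raise ValueError("more groups than subjects")
    if n_groups > 1 and np.unique(predicted).size == 1:
        raise ValueError("degenerate predictor; reduce the number of groups")
    order = np.argsort(predicted, kind="mergesort")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    labels = (ranks * n_groups) // n + 1
    return RiskGrouping(labels.astype(np.int64), n_groups)


# ---------------------------------------------------------------------------
# fast leave-one-out machinery
# ---------------------------------------------------------------------------

def _segment_sums(a: np.ndarray):
    """Prefix machinery for log-factor sums that may contain -inf.

    Returns ``seg(i, j)`` = sum of ``a`` over positions i..j-1, evaluating
    to -inf whenever the segment contains a -inf entry (so that differences
    of prefixes never produce inf - inf).
    """
    fin = np.concatenate([[0.0], np.cumsum(np.where(np.isneginf(a), 0.0, a))])
    ninf = np.concatenate([[0], np.cumsum(np.isneginf(a).astype(np.int64))])

    def seg(i, j):
        s = fin[j] - fin[i]
        return np.where(ninf[j] - ninf[i] > 0, -np.inf, s)

    return seg


def _log_factors(d: np.ndarray, n_r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """log(1 - d/n) for the full sample and with one at-risk subject removed."""
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.log1p(-d / n_r)
        b = np.where(
            n_r > 1,
            np.log1p(-np.minimum(d / np.maximum(n_r - 1, 1), 1.0)),
            -np.inf,
        )
    return a, b


def _loo_aj(data: SurvivalDataset, cause: int, t_star: float) -> tuple[float, np.ndarray]:
    """Full-sample AJ CIF at t_star and all n leave-one-out values."""
    tab = risk_set_table(data)
    d_any = tab.d_any
    keep = d_any > 0
    times = tab.times[keep]
    n_r = tab.n_at_risk[keep].astype(float)
    d = d_any[keep].astype(float)
    dk = tab.d[keep, cause - 1].astype(float)

    a, b = _log_factors(d, n_r)
    segA, segB = _segment_sums(a), _segment_sums(b)
    m = times.size
    pos = np.arange(m + 1)
    S_prev = np.exp(segA(np.zeros(m, dtype=int), pos[:-1]))   # full KM left limit
    SB_prev = np.exp(segB(np.zeros(m, dtype=int), pos[:-1]))  # leave-one-out left limit
    with np.errstate(divide="ignore", invalid="ignore"):
        jump_full = S_prev * dk / n_r
        jump_loo = np.where(n_r > 1, SB_prev * dk / (n_r - 1), 0.0)
    F = np.concatenate([[0.0], np.cumsum(jump_full)])   # F[j] = AJ after j-th time
    C = np.concatenate([[0.0], np.cumsum(jump_loo)])

    J = int(np.searchsorted(times, t_star, side="right"))
    theta_full = F[J]

    T, D = data.time, data.status
    q = np.searchsorted(times, T, side="left")     # number of grid times < T_i
    p = np.searchsorted(times, T, side="right") - 1
    at_grid = (p >= 0) & (times[np.maximum(p, 0)] == T)

    loo = np.empty(data.n)
    late = T > t_star
    loo[late] = C[J]

    idx = ~late & ~at_grid                          # censored off-grid, T <= t*
    if np.any(idx):
        qi = q[idx]
        with np.errstate(invalid="ignore", over="ignore"):
            w = np.exp(segB(0, qi) - segA(0, qi))
        diff = F[J] - F[qi]
        wd = np.zeros_like(diff)
        pos = diff > 0
        wd[pos] = w[pos] * diff[pos]
        loo[idx] = C[qi] + wd

    idx = ~late & at_grid                           # exits at an event time <= t*
    if np.any(idx):
        pi = p[idx]                                 # grid times < T_i are 0..pi-1
        e_any = (D[idx] > 0).astype(float)
        e_k = (D[idx] == cause).astype(float)
        denom = n_r[pi] - 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            own = np.where(denom > 0, np.exp(segB(0, pi)) * (dk[pi] - e_k) / denom, 0.0)
            log_fac = np.where(
                denom > 0,
                np.log1p(-np.minimum((d[pi] - e_any) / np.maximum(denom, 1.0), 1.0)),
                0.0,
            )
        diff = F[J] - F[pi + 1]
        with np.errstate(invalid="ignore", over="ignore"):
            w = np.exp(segB(0, pi) + log_fac - segA(0, pi + 1))
        wd = np.zeros_like(diff)
        pos = diff > 0
        wd[pos] = w[pos] * diff[pos]
        loo[idx] = C[pi] + own + wd

    return theta_full, loo


def _loo_km_failure(
    data: SurvivalDataset, event_def: int | str, t_star: float
) -> tuple[float, np.ndarray]:
    """Full-sample 1 - KM at t_star and all n leave-one-out values.

    ``event_def`` as in :func:`crvalid.nonparam.kaplan_meier`.
    """
    tab = risk_set_table(data)
    if event_def == "any":
        d_all = tab.d_any
        is_event = data.status > 0
    else:
        d_all = tab.d[:, int(event_def) - 1]
        is_event = data.status == int(event_def)
    keep = d_all > 0
    times = tab.times[keep]
    n_r = tab.n_at_risk[keep].astype(float)
    d = d_all[keep].astype(float)
    if times.size == 0:  # no qualifying events: KM = 1 everywhere, pseudo = 0
        return 0.0, np.zeros(data.n)

    a, b = _log_factors(d, n_r)
    segA, segB = _segment_sums(a), _segment_sums(b)

    J = int(np.searchsorted(times, t_star, side="right"))
    theta_full = 1.0 - np.exp(segA(0, J))

    T = data.time
    q = np.searchsorted(times, T, side="left")
    p = np.searchsorted(times, T, side="right") - 1
    at_grid = (p >= 0) & (times[np.maximum(p, 0)] == T)

    log_S = np.empty(data.n)
    late = T > t_star
    log_S[late] = segB(0, J)

    idx = ~late & ~at_grid
    if np.any(idx):
        qi = q[idx]
        log_S[idx] = segB(0, qi) + segA(qi, J)

    idx = ~late & at_grid
    if np.any(idx):
        pi = p[idx]
        e = is_event[idx].astype(float)
        denom = n_r[pi] - 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            log_fac = np.where(
                denom > 0,
                np.log1p(-np.minimum((d[pi] - e) / np.maximum(denom, 1.0), 1.0)),
                0.0,
            )
        log_S[idx] = segB(0, pi) + log_fac + segA(pi + 1, J)

    return theta_full, 1.0 - np.exp(log_S)


def _assemble(theta_full: float, loo: np.ndarray) -> np.ndarray:
    n = loo.size
    return n * theta_full - (n - 1) * loo


def _check_landmark(data: SurvivalDataset, t_star: float) -> None:
    if t_star <= 0:
        raise ValueError("landmark time must be positive")
    if t_star > data.time.max():
        warnings.warn(
            "landmark time lies beyond the observed follow-up; estimators are "
            "carried forward from the last observed time",
            stacklevel=3,
        )


def pseudo_cif(data: SurvivalDataset, cause: int, t_star: float) -> PseudoObservationSet:
    """Pseudo-observations of the Aalen-Johansen CIF for ``cause`` at ``t_star``."""
    _check_landmark(data, t_star)
    theta_full, loo = _loo_aj(data, cause, t_star)
    return PseudoObservationSet(t_star, cause, "cif", _assemble(theta_full, loo))


def pseudo_cs_failure(
    data: SurvivalDataset,
    cause: int,
    t_star: float,
    grouping: RiskGrouping | None = None,
) -> PseudoObservationSet:
    """Pseudo-observations of 1 - cause-specific KM, optionally stratified.

    With a grouping, the jackknife runs within each risk group separately
    (the mixture-KM construction): each group's subjects get pseudo-values
    of that group's own 1 - KM, weakening independent censoring to
    conditional independence given the group.
    """
    _check_landmark(data, t_star)
    if grouping is None:
        theta_full, loo = _loo_km_failure(data, cause, t_star)
        return PseudoObservationSet(t_star, cause, "cs_failure", _assemble(theta_full, loo))
    labels = np.asarray(grouping.labels)
    if labels.shape[0] != data.n:
        raise ValueError("grouping does not cover every subject")
    theta = np.empty(data.n)
    for r in range(1, grouping.n_groups + 1):
        mask = labels == r
        if not np.any(mask):
            raise ValueError("empty risk group")
        sub = SurvivalDataset(data.frame.loc[mask].reset_index(drop=True), data.n_causes)
        if sub.events(cause) == 0:
            warnings.warn(f"risk group {r} has no cause-{cause} events", stacklevel=2)
        theta_full, loo = _loo_km_failure(sub, cause, t_star)
        theta[mask] = _assemble(theta_full, loo)
    return PseudoObservationSet(t_star, cause, "cs_failure", theta, grouping)


def pseudo_all_cause(data: SurvivalDataset, t_star: float) -> PseudoObservationSet:
    """Pseudo-observations of the all-cause failure 1 - KM(any) at ``t_star``."""
    _check_landmark(data, t_star)
    theta_full, loo = _loo_km_failure(data, "any", t_star)
    return PseudoObservationSet(t_star, 0, "all_cause", _assemble(theta_full, loo))


def brute_force_pseudo(
    data: SurvivalDataset, cause: int, t_star: float, target: str = "cif"
) -> np.ndarray:
    """Direct leave-one-out pseudo-values (O(n^2); reference implementation)."""
    if target == "cif":
        full = aalen_johansen(data, cause)(t_star)
    elif target == "cs_failure":
        full = 1.0 - kaplan_meier(data, cause)(t_star)
    elif target == "all_cause":
        full = 1.0 - kaplan_meier(data, "any")(t_star)
    else:
        raise ValueError(f"unknown target {target!r}")
    n = data.n
    loo = np.empty(n)
    for i in range(n):
        sub = SurvivalDataset(data.frame.drop(data.frame.index[i]).reset_index(drop=True),
                              data.n_causes)
        if target == "cif":
            loo[i] = aalen_johansen(sub, cause)(t_star)
        elif target == "cs_failure":
            loo[i] = 1.0 - kaplan_meier(sub, cause)(t_star)
        else:
            loo[i] = 1.0 - kaplan_meier(sub, "any")(t_star)
    return n * float(full) - (n - 1) * loo
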