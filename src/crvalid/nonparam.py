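"""Nonparametric step-function estimators for competing-risks data.

Kaplan-Meier (all-cause or cause-specific), the Aalen-Johansen cumulative
incidence estimator, the reverse Kaplan-Meier estimate of the censoring
distribution, and the stratified "mixture" Kaplan-Meier (a group-proportion
weighted average of within-group cause-specific KMs, used to weaken the
independent-censoring assumption when jackknifing 1 - S_k).

Tie convention: at a tied time, events precede censorings, i.e. subjects
censored at t are still in the risk set at t.  Evaluation beyond the last
jump returns the last value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import SurvivalDataset

__all__ = [
    "StepFunction",
    "RiskSetTable",
    "risk_set_table",
    "kaplan_meier",
    "aalen_johansen",
    "reverse_km_censoring",
    "mixture_km",
]


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous step function with value ``init`` before the first jump."""

    times: np.ndarray
    values: np.ndarray
    init: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D and of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("jump times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def _eval(self, t, side: str):
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            out = np.full(t.shape, self.init)
        else:
            idx = np.searchsorted(self.times, t, side=side)
            out = np.where(idx == 0, self.init, self.values[np.maximum(idx - 1, 0)])
        return float(out) if out.ndim == 0 else out

    def __call__(self, t: float | np.ndarray) -> np.ndarray | float:
        """Right-continuous evaluation: value after any jump at ``t``."""
        return self._eval(t, "right")

    def left(self, t: float | np.ndarray) -> np.ndarray | float:
        """Left limit: value just before ``t`` (jumps at ``t`` excluded)."""
        return self._eval(t, "left")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "value": self.values})


@dataclass(frozen=True)
class RiskSetTable:
    """Counting-process summary at the distinct observed times.

    ``d`` has one column per cause (cause k in column k-1); ``censored``
    counts status-0 exits.  ``n_at_risk[j]`` counts subjects with
    ``T >= times[j]``.
    """

    times: np.ndarray
    n_at_risk: np.ndarray
    d: np.ndarray
    censored: np.ndarray

    @property
    def d_any(self) -> np.ndarray:
        return self.d.sum(axis=1)


def risk_set_table(data: SurvivalDataset) -> RiskSetTable:
    time, status = data.time, data.status
    times = np.unique(time)
    idx = np.searchsorted(times, time)
    K = data.n_causes
    d = np.zeros((times.size, K), dtype=np.int64)
    for k in range(1, K + 1):
        np.add.at(d[:, k - 1], idx[status == k], 1)
    censored = np.zeros(times.size, dtype=np.int64)
    np.add.at(censored, idx[status == 0], 1)
    exits = d.sum(axis=1) + censored
    # at risk at t_j: everyone who has not exited strictly before t_j
    n_at_risk = data.n - np.concatenate([[0], np.cumsum(exits)[:-1]])
    return RiskSetTable(times, n_at_risk, d, censored)


def _km_from_counts(times: np.ndarray, d: np.ndarray, n: np.ndarray) -> StepFunction:
    keep = d > 0
    with np.errstate(divide="ignore"):
        surv = np.cumprod(1.0 - d[keep] / n[keep])
    return StepFunction(times[keep], surv)


def kaplan_meier(data: SurvivalDataset, event_def: int | str = "any") -> StepFunction:
    """Kaplan-Meier estimator.

    ``event_def="any"`` gives the all-cause KM; an integer cause ``k``
    gives the cause-specific KM in which other-cause events are treated as
    censorings (the curve whose complement is the cause-specific failure
    function 1 - S_k).
    """
    tab = risk_set_table(data)
    if event_def == "any":
        d = tab.d_any
    else:
        k = int(event_def)
        if not 1 <= k <= data.n_causes:
            raise ValueError(f"cause {k} outside 1..{data.n_causes}")
        d = tab.d[:, k - 1]
    return _km_from_counts(tab.times, d, tab.n_at_risk)


def aalen_johansen(data: SurvivalDataset, cause: int) -> StepFunction:
    """Aalen-Johansen cumulative incidence for ``cause``.

    F_k(t) = sum over event times t_j <= t of S(t_j-) d_kj / n_j with S the
    all-cause KM left limit.
    """
    if not 1 <= cause <= data.n_causes:
        raise ValueError(f"cause {cause} outside 1..{data.n_causes}")
    tab = risk_set_table(data)
    d_any = tab.d_any
    keep = d_any > 0
    surv = np.cumprod(1.0 - d_any[keep] / tab.n_at_risk[keep])
    s_left = np.concatenate([[1.0], surv[:-1]])
    jumps = s_left * tab.d[keep, cause - 1] / tab.n_at_risk[keep]
    return StepFunction(tab.times[keep], np.cumsum(jumps), init=0.0)


def reverse_km_censoring(data: SurvivalDataset) -> StepFunction:
    """Reverse Kaplan-Meier estimate G(t) of P(censoring time > t).

    The censoring indicator plays the role of the event; all actual events
    act as censorings of the censoring process.
    """
    tab = risk_set_table(data)
    return _km_from_counts(tab.times, tab.censored, tab.n_at_risk)


def mixture_km(
    data: SurvivalDataset, groups: np.ndarray, cause: int
) -> StepFunction:
    """Mixture Kaplan-Meier: sum_r p_r * KM of cause ``cause`` within group r.

    ``groups`` assigns every subject a label; weights p_r are the group
    proportions.  Weakens the independent-censoring assumption to
    conditional independence within risk groups.
    """
    groups = np.asarray(groups)
    if groups.shape[0] != data.n:
        raise ValueError("group labels must cover every subject")
    labels, counts = np.unique(groups, return_counts=True)
    if np.any(counts == 0):
        raise ValueError("empty risk group")
    curves = []
    weights = counts / data.n
    for lab in labels:
        sub = SurvivalDataset(
            data.frame.loc[groups == lab].reset_index(drop=True), data.n_causes
        )
        curves.append(kaplan_meier(sub, cause))
    grid = np.unique(np.concatenate([c.times for c in curves] or [np.array([])]))
    if grid.size == 0:
        return StepFunction(np.array([]), np.array([]), init=1.0)
    vals = np.zeros(grid.size)
    for w, c in zip(weights, curves):
        vals += w * np.asarray(c(grid))
    return StepFunction(grid, vals)
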