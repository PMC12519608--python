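"""End-to-end validation workflow and calibration-plot rendering.

``validate`` runs every stage for a fitted model set on a dataset at a
landmark time: model predictions, pseudo-observations (risk-group
stratified for the per-model 1 - S_k targets), smoothed calibration curves
with slope/CITL/O-E, and IPCW Brier / null Brier / IPA — one result pair
per target: the cause-specific absolute risks (CIFs), each cause-specific
failure function, and the all-cause risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationResult, calibrate
from .dataset import SurvivalDataset
from .fpm import ModelSet, predict_all_cause, predict_cif, predict_cs_failure
from .performance import (
    PerformanceResult,
    brier_all_cause,
    brier_cif,
    brier_cs_failure,
    censoring_weights,
    competing_event_weights,
    ipa,
    null_brier,
)
from .pseudo import make_risk_groups, pseudo_all_cause, pseudo_cif, pseudo_cs_failure

__all__ = ["ValidationReport", "validate", "plot_calibration", "render_report"]


@dataclass
class ValidationReport:
    """Calibration + performance results per target, with provenance."""

    t_star: float
    results: dict[str, tuple[CalibrationResult, PerformanceResult]]
    provenance: dict = field(default_factory=dict)

    def stats_frame(self) -> pd.DataFrame:
        rows = []
        for name, (cal, perf) in self.results.items():
            rows.append(
                {
                    "target": name,
                    "cause": cal.cause,
                    "t": self.t_star,
                    "slope": cal.slope,
                    "citl": cal.citl,
                    "oe": cal.oe,
                    "brier": perf.brier,
                    "brier_null": perf.brier_null,
                    "ipa": perf.ipa,
                }
            )
        return pd.DataFrame(rows)


def validate(
    models: ModelSet,
    data: SurvivalDataset,
    t_star: float,
    n_risk_groups: int = 10,
    n_plot_groups: int = 15,
    n_interior_knots: int = 3,
    td_df: int = 2,
    include_cs_failure: bool = True,
    include_all_cause: bool = True,
) -> ValidationReport:
    """Validate ``models`` on ``data`` at landmark ``t_star``.

    ``n_risk_groups`` controls the prognostic-index stratification of the
    1 - S_k pseudo-observations (dependent-censoring control);
    ``n_plot_groups`` the grouped points overlaid on calibration plots.
    """
    if t_star <= 0:
        raise ValueError("landmark time must be positive")
    if t_star > data.time.max():
        raise ValueError("landmark time lies beyond the observed follow-up")
    if models.n_causes != data.n_causes:
        raise ValueError("model set and data disagree on the number of causes")

    cov = data.covariates()
    cif = predict_cif(models, cov, t_star)
    weights = censoring_weights(data, t_star)
    union_terms: list[str] = []
    for k in range(1, models.n_causes + 1):
        for term in models[k].terms:
            if term not in union_terms:
                union_terms.append(term)

    results: dict[str, tuple[CalibrationResult, PerformanceResult]] = {}

    for k in range(1, models.n_causes + 1):
        pred = cif[:, k - 1]
        ps = pseudo_cif(data, k, t_star)
        cal = calibrate(ps, pred, n_interior_knots, n_groups=n_plot_groups)
        b = brier_cif(data, pred, weights, t_star, k)
        bn = null_brier(data, t_star, k, "cif", weights)
        results[f"cif_cause{k}"] = (
            cal, PerformanceResult(t_star, k, "cif", b, bn, ipa(b, bn))
        )

    if include_cs_failure:
        for k in range(1, models.n_causes + 1):
            pred = predict_cs_failure(models[k], cov, t_star)
            grouping = make_risk_groups(models[k].linear_predictor(cov), n_risk_groups)
            ps = pseudo_cs_failure(data, k, t_star, grouping)
            cal = calibrate(ps, pred, n_interior_knots, n_groups=n_plot_groups)
            wk = competing_event_weights(data, k, union_terms, weights, t_star, td_df=td_df)
            b = brier_cs_failure(data, pred, wk, t_star, k)
            bn = null_brier(data, t_star, k, "cs_failure", wk)
            results[f"cs_failure_cause{k}"] = (
                cal, PerformanceResult(t_star, k, "cs_failure", b, bn, ipa(b, bn))
            )

    if include_all_cause:
        pred = predict_all_cause(models, cov, t_star)
        ps = pseudo_all_cause(data, t_star)
        cal = calibrate(ps, pred, n_interior_knots, n_groups=n_plot_groups)
        b = brier_all_cause(data, pred, weights, t_star)
        bn = null_brier(data, t_star, 0, "all_cause", weights)
        results["all_cause"] = (
            cal, PerformanceResult(t_star, 0, "all_cause", b, bn, ipa(b, bn))
        )

    return ValidationReport(t_star, results)


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_calibration(cal: CalibrationResult, perf: PerformanceResult, ax=None):
    """One calibration panel: diagonal, smoothed curve, grouped points,
    predicted-risk histogram strip and statistic annotations."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="perfect calibration")
    ax.plot(cal.grid, cal.curve, color="#d4418e", lw=2, label="smoothed curve")
    ax.plot(
        cal.groups["predicted"], cal.groups["observed"],
        "o", color="#f28e2b", ms=5, label="grouped risks",
    )
    top = cal.hist_counts / max(cal.hist_counts.max(), 1) * 0.08
    ax.bar(
        (cal.hist_edges[:-1] + cal.hist_edges[1:]) / 2,
        top, width=np.diff(cal.hist_edges), bottom=-0.1,
        color="0.6", align="center",
    )
    ax.annotate(
        f"slope = {cal.slope:.2f}\nCITL = {cal.citl:.2f}\n"
        f"O/E = {cal.oe:.2f}\nIPA = {perf.ipa:.3f}",
        xy=(0.03, 0.97), xycoords="axes fraction", va="top", fontsize=8,
        bbox=dict(boxstyle="round", fc="white", alpha=0.8),
    )
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.11, 1.02)
    ax.set_xlabel("predicted risk")
    ax.set_ylabel("observed risk (pseudo-observations)")
    ax.set_title(f"{cal.target} (cause {cal.cause}) at t = {cal.t_star:g}", fontsize=9)
    return ax


def render_report(report: ValidationReport, outdir, formats=("svg", "png")) -> list:
    """Write one calibration plot per target plus the stats CSV; returns paths."""
    import pathlib

    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, (cal, perf) in report.results.items():
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        plot_calibration(cal, perf, ax)
        for fmt in formats:
            path = outdir / f"calibration_{name}.{fmt}"
            fig.savefig(path, bbox_inches="tight", dpi=120)
            written.append(path)
        plt.close(fig)
    stats_path = outdir / "stats.csv"
    report.stats_frame().to_csv(stats_path, index=False)
    written.append(stats_path)
    return written
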