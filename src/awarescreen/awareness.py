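"""The awareness measure: slope of per-item ICC against item position.

If respondents tire (satisfice) through a long questionnaire, random
error grows with item position and the cluster-based per-item ICC drifts
downward; if engagement grows, it drifts upward.  The ordinary
least-squares slope of ICC on questionnaire position is therefore a
screening statistic for systematic change in reliability: negative means
reliability falls towards the end of the questionnaire, positive means
it rises, and values near zero are consistent with constant reliability.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .clustering import pam_two_cluster
from .data_io import AnalysisConfig, ResponseMatrix, ScaleSpec, apply_scale
from .errors import UnscreenableError
from .icc import IccSeries, _icc_vector, icc_series

logger = logging.getLogger("awarescreen")

__all__ = ["AwarenessResult", "slope_regression", "awareness_measure"]


@dataclass(frozen=True)
class AwarenessResult:
    """Fitted awareness measure for one scale.

    ``slope`` is in ICC units per questionnaire position;
    ``total_change`` rescales it to the full questionnaire
    (slope * questionnaire length), the scale on which the effect size
    is easiest to judge.
    """

    scale_name: str
    slope: float
    intercept: float
    n_items_used: int
    n_subjects: int
    icc_series: IccSeries
    total_change: float

    def to_dict(self) -> dict:
        return {
            "scale": self.scale_name,
            "slope": self.slope,
            "intercept": self.intercept,
            "n_items_used": self.n_items_used,
            "n_subjects": self.n_subjects,
            "total_change": self.total_change,
        }


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    if sxx <= 0:
        raise UnscreenableError("all item positions identical; slope undefined")
    slope = float(((x - xbar) * (y - ybar)).sum() / sxx)
    return slope, float(ybar - slope * xbar)


def slope_regression(series: IccSeries) -> tuple[float, float]:
    """OLS fit of ICC on questionnaire position over converged items.

    Requires at least 3 converged estimates; unweighted least squares
    (per-item ICC precision is not propagated — uncertainty is handled
    wholesale by the bootstrap).
    """
    if not series.screenable:
        raise UnscreenableError(
            f"scale {series.scale_name!r}: only {series.n_converged} converged "
            "items; at least 3 needed for the slope"
        )
    pos, icc = series.converged_arrays()
    return _ols_line(pos, icc)


def _slope_from_values(
    values: np.ndarray, positions: np.ndarray, estimator: str
) -> tuple[float, int]:
    """Fast pipeline core: PAM -> per-item ICC -> OLS slope.

    Operates on a complete-case value matrix and raises
    DegenerateDataError/UnscreenableError exactly like the public path;
    used inside bootstrap and simulation loops where constructing the
    full result objects would dominate the runtime.
    """
    assignment = pam_two_cluster(values)
    icc, _, _, converged = _icc_vector(values, assignment.labels, estimator)
    if int(converged.sum()) < 3:
        raise UnscreenableError("fewer than 3 items converged")
    slope, _ = _ols_line(positions[converged].astype(float), icc[converged])
    return slope, int(converged.sum())


def awareness_measure(
    rm: ResponseMatrix, spec: ScaleSpec, config: AnalysisConfig
) -> AwarenessResult:
    """Run the full screening pipeline for one scale.

    Steps: complete-case restriction to the scale's items, two-cluster
    PAM on those items, per-item one-way variance decomposition with the
    clusters as grouping factor, then OLS of ICC on item position.
    Deterministic given (rm, spec, config.seed).
    """
    scale_rm = apply_scale(rm, spec)
    assignment = pam_two_cluster(scale_rm.values, seed=config.seed)
    series = icc_series(scale_rm, spec, assignment, estimator=config.estimator)
    slope, intercept = slope_regression(series)
    length = config.questionnaire_length or int(spec.positions.max())
    return AwarenessResult(
        scale_name=spec.scale_name,
        slope=slope,
        intercept=intercept,
        n_items_used=series.n_converged,
        n_subjects=scale_rm.n_subjects,
        icc_series=series,
        total_change=slope * length,
    )


def write_result_json(result: AwarenessResult, path: str | Path) -> None:
    """Write one scale's result record as JSON (per-item table inline)."""
    record = result.to_dict()
    record["items"] = [
        {
            "position": e.position,
            "icc": e.icc,
            "sigma2_between": e.sigma2_between,
            "sigma2_within": e.sigma2_within,
            "converged": e.converged,
        }
        for e in result.icc_series.estimates
    ]
    Path(path).write_text(json.dumps(record, indent=2, allow_nan=True) + "\n")
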