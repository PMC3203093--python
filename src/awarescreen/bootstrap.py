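"""Subject-level bootstrap with BCa intervals for the awareness measure.

The resampling unit is the respondent (an entire response row): the
slope's sampling variation arises across respondents, and row resampling
is the only scheme that respects within-subject correlation.  Every
replicate re-runs the *full* pipeline, clustering included — the
estimator is the whole procedure, not the slope given a fixed partition.
Replicates on which the pipeline is degenerate or unscreenable are
dropped and counted, never retried (retrying would bias the bootstrap
distribution toward clusterable resamples).

Interval: bias-corrected and accelerated (BCa).  The bias-correction
constant is ``z0 = Phi^{-1}(#{theta*_b < theta_hat} / B)`` and the
acceleration ``a`` is the jackknife skewness
``sum(d_i^3) / (6 * (sum(d_i^2))^{3/2})`` with ``d_i = mean(theta_(-.))
- theta_(-i)`` over leave-one-subject-out estimates.  Endpoints are read
from the empirical replicate distribution by order statistics with
linear interpolation, so results are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .awareness import _slope_from_values, awareness_measure
from .data_io import AnalysisConfig, ResponseMatrix, ScaleSpec, apply_scale
from .errors import AwarescreenError, DegenerateDataError, UnscreenableError

logger = logging.getLogger("awarescreen")

__all__ = ["BootstrapResult", "bca_interval", "bootstrap_awareness", "bootstrap_slope_values"]


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap summary for one scale's awareness measure."""

    point_estimate: float
    replicates_requested: int
    replicates_used: int
    ci_low: float
    ci_high: float
    level: float
    significant: bool
    seed: int
    unreliable: bool = False

    def to_dict(self) -> dict:
        return {
            "slope": self.point_estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "replicates_used": self.replicates_used,
            "replicates_requested": self.replicates_requested,
            "significant": self.significant,
            "unreliable": self.unreliable,
        }


def bca_interval(
    replicate_values: np.ndarray,
    jackknife_values: np.ndarray,
    point_estimate: float,
    level: float = 0.95,
) -> tuple[float, float]:
    """BCa confidence interval endpoints from bootstrap + jackknife values."""
    theta = np.asarray(replicate_values, dtype=float)
    jack = np.asarray(jackknife_values, dtype=float)
    b = theta.size
    if b < 1:
        raise ValueError("no replicate values")
    if theta.max() == theta.min():
        logger.warning("all bootstrap replicates identical; degenerate interval")
        return float(theta[0]), float(theta[0])

    prop_below = np.sum(theta < point_estimate) / b
    if prop_below <= 0.0 or prop_below >= 1.0:
        # all replicates fell on one side of the point estimate
        clamp = norm.ppf(1.0 - 1.0 / b)
        z0 = -clamp if prop_below <= 0.0 else clamp
        logger.warning("bias-correction z0 infinite; clamped to %+.4f", z0)
    else:
        z0 = norm.ppf(prop_below)

    d = jack.mean() - jack
    denom = (d ** 2).sum() ** 1.5
    accel = (d ** 3).sum() / (6.0 * denom) if denom > 0 else 0.0

    alpha = (1.0 - level) / 2.0
    z_lo, z_hi = norm.ppf(alpha), norm.ppf(1.0 - alpha)
    a1 = norm.cdf(z0 + (z0 + z_lo) / (1.0 - accel * (z0 + z_lo)))
    a2 = norm.cdf(z0 + (z0 + z_hi) / (1.0 - accel * (z0 + z_hi)))
    lo, hi = np.quantile(theta, [a1, a2], method="linear")
    return float(lo), float(hi)


def bootstrap_slope_values(
    values: np.ndarray,
    positions: np.ndarray,
    config: AnalysisConfig,
) -> BootstrapResult:
    """Bootstrap the awareness slope on a complete-case value matrix.

    This is the computational core of :func:`bootstrap_awareness`,
    usable directly on simulated data.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions)
    n = values.shape[0]
    point, _ = _slope_from_values(values, positions, config.estimator)

    rng = np.random.default_rng(config.seed)
    b = config.bootstrap_replicates
    slopes = np.empty(b)
    failed = 0
    used = 0
    for _ in range(b):
        idx = rng.integers(0, n, n)
        try:
            slopes[used], _ = _slope_from_values(values[idx], positions, config.estimator)
            used += 1
        except (DegenerateDataError, UnscreenableError):
            failed += 1
    slopes = slopes[:used]
    if used == 0:
        raise UnscreenableError("every bootstrap replicate failed")

    jack = []
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            s, _ = _slope_from_values(values[mask], positions, config.estimator)
            jack.append(s)
        except (DegenerateDataError, UnscreenableError):
            pass
        mask[i] = True
    if len(jack) < 2:
        raise UnscreenableError("jackknife failed on nearly all subjects")

    lo, hi = bca_interval(slopes, np.asarray(jack), point, config.confidence_level)
    unreliable = failed > 0.10 * b
    if failed:
        logger.warning(
            "bootstrap: %d of %d replicates failed (%s)",
            failed, b, "flagged unreliable" if unreliable else "within tolerance",
        )
    return BootstrapResult(
        point_estimate=point,
        replicates_requested=b,
        replicates_used=used,
        ci_low=lo,
        ci_high=hi,
        level=config.confidence_level,
        significant=bool(lo > 0.0 or hi < 0.0),
        seed=config.seed,
        unreliable=unreliable,
    )


def bootstrap_awareness(
    rm: ResponseMatrix, spec: ScaleSpec, config: AnalysisConfig
) -> BootstrapResult:
    """Bootstrap CI and significance flag for one scale's awareness measure.

    The scale's complete-case matrix is fixed first; subjects are then
    resampled with replacement from it.  The significance rule is the
    screening convention: the slope differs from zero when zero lies
    outside the BCa interval.
    """
    scale_rm = apply_scale(rm, spec)
    return bootstrap_slope_values(scale_rm.values, spec.positions, config)
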