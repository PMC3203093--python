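"""Per-item intraclass correlation from a one-way variance decomposition.

For every item, responses are decomposed by the one-way random-intercept
model ``y_gi = mu + u_g + e_gi`` with the two clusters as the grouping
factor: ``u_g ~ N(0, sigma2_between)``, ``e_gi ~ N(0, sigma2_within)``.
The item's intraclass correlation is

    ICC = sigma2_between / (sigma2_between + sigma2_within),

the share of total response variance carried by the cluster split.  High
ICC means the two respondent subsets are well separated on that item
relative to the noise within each subset; as random error grows the ICC
shrinks.

Two estimators of the variance components are provided:

``reml``
    Restricted maximum likelihood.  The one-way model admits a profiled
    REML criterion in the single variance ratio ``lam =
    sigma2_between / sigma2_within``: with group sizes ``n_g``, group
    means ``m_g``, pooled within-group sum of squares ``SSW`` and
    weights ``w_g = n_g / (1 + lam * n_g)``,

        Q(lam)  = (sum_g w_g * (m_g - mu_hat)^2),   mu_hat = GLS mean
        s_hat   = (SSW + Q) / (N - 1)
        crit    = (N - 1) * log(s_hat) + sum_g log(1 + lam * n_g)
                  + log(sum_g w_g)

    minimised over ``lam >= 0`` (grid bracket then golden-section).  The
    between-component is constrained non-negative by construction.

``anova``
    Method of moments from the one-way ANOVA table with the
    unbalanced-design group-size correction
    ``n0 = (N - sum n_g^2 / N) / (G - 1)``; a negative between-component
    is truncated at zero.

With only two grouping levels a mixed-model fit sits at the edge of
common practice, so both estimators are first-class: for balanced groups
with an interior estimate they coincide exactly, which is exercised in
the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .clustering import ClusterAssignment
from .data_io import ResponseMatrix, ScaleSpec
logger = logging.getLogger("awarescreen")

__all__ = [
    "IccEstimate",
    "IccSeries",
    "variance_components_oneway",
    "icc_from_components",
    "icc_series",
]

_GOLD = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class IccEstimate:
    """Variance components and ICC for one item at one questionnaire position."""

    position: int
    sigma2_between: float
    sigma2_within: float
    icc: float
    converged: bool


@dataclass(frozen=True)
class IccSeries:
    """Per-item ICC estimates for one scale, ordered by questionnaire position."""

    scale_name: str
    estimates: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "estimates", tuple(self.estimates))
        positions = [e.position for e in self.estimates]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("estimate positions must be strictly increasing")

    @property
    def n_converged(self) -> int:
        return sum(e.converged for e in self.estimates)

    @property
    def screenable(self) -> bool:
        return self.n_converged >= 3

    def converged_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(positions, ICCs) over the converged items only."""
        pos = np.array([e.position for e in self.estimates if e.converged], dtype=float)
        icc = np.array([e.icc for e in self.estimates if e.converged], dtype=float)
        return pos, icc


# --------------------------------------------------------------------------
# vectorised internals: all items of a scale at once
# --------------------------------------------------------------------------

def _group_stats(values: np.ndarray, labels: np.ndarray):
    """Sufficient statistics per item: group sizes, mean difference, SSW."""
    g1 = labels == 0
    n1 = int(g1.sum())
    n2 = int(values.shape[0] - n1)
    v1, v2 = values[g1], values[~g1]
    m1 = v1.mean(axis=0)
    m2 = v2.mean(axis=0)
    ssw = ((v1 - m1) ** 2).sum(axis=0) + ((v2 - m2) ** 2).sum(axis=0)
    return n1, n2, m1, m2, ssw


def _reml_criterion(lam, n1, n2, ssw, d2, n_total):
    """Profiled -2 REML log-likelihood (up to a constant), vectorised in lam."""
    w1 = n1 / (1.0 + lam * n1)
    w2 = n2 / (1.0 + lam * n2)
    w = w1 + w2
    q = w1 * w2 / w * d2  # weighted between-group sum of squares (G = 2)
    s_hat = (ssw + q) / (n_total - 1)
    return (
        (n_total - 1) * np.log(s_hat)
        + np.log1p(lam * n1)
        + np.log1p(lam * n2)
        + np.log(w)
    )


def _reml_components(values: np.ndarray, labels: np.ndarray):
    """REML variance components for every item column. Returns (sb, sw)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return _reml_components_impl(values, labels)


def _reml_components_impl(values: np.ndarray, labels: np.ndarray):
    # degenerate columns produce NaN/inf here; the converged flag in
    # _icc_vector screens them out
    n, _ = values.shape
    n1, n2, m1, m2, ssw = _group_stats(values, labels)
    d2 = (m1 - m2) ** 2

    # coarse bracket on log(lam), then golden-section refinement per item
    log_lam = np.linspace(-14.0, 12.0, 53)
    crit = _reml_criterion(np.exp(log_lam)[:, None], n1, n2, ssw[None, :], d2[None, :], n)
    at_zero = _reml_criterion(0.0, n1, n2, ssw, d2, n)
    best = np.argmin(crit, axis=0)
    lo = log_lam[np.maximum(best - 1, 0)]
    hi = log_lam[np.minimum(best + 1, len(log_lam) - 1)]
    a, b = lo.copy(), hi.copy()
    for _ in range(20):  # bracket shrinks by the golden ratio per step
        c = b - _GOLD * (b - a)
        d = a + _GOLD * (b - a)
        f_cd = _reml_criterion(np.exp(np.stack([c, d])), n1, n2, ssw[None, :], d2[None, :], n)
        take_c = f_cd[0] < f_cd[1]
        b = np.where(take_c, d, b)
        a = np.where(take_c, a, c)
    # parabolic polish: near the optimum the criterion is locally
    # quadratic, so one vertex fit at a step well above evaluation
    # round-off reaches a precision the golden bracket alone would need
    # many more (tiny-array) evaluations for
    mid = (a + b) / 2.0
    h = 1e-4
    pts = np.stack([mid - h, mid, mid + h])
    f3 = _reml_criterion(np.exp(pts), n1, n2, ssw[None, :], d2[None, :], n)
    curv = f3[0] - 2.0 * f3[1] + f3[2]
    good = curv > 0
    shift = np.where(good, 0.5 * h * (f3[0] - f3[2]) / np.where(good, curv, 1.0), 0.0)
    lam = np.exp(mid + np.clip(shift, -h, h))
    f_lam = _reml_criterion(lam, n1, n2, ssw, d2, n)
    lam = np.where(at_zero <= f_lam, 0.0, lam)

    w1 = n1 / (1.0 + lam * n1)
    w2 = n2 / (1.0 + lam * n2)
    q = w1 * w2 / (w1 + w2) * d2
    sw = (ssw + q) / (n - 1)
    sb = lam * sw
    # zero within-group variance: the likelihood degenerates; fall back to
    # the method-of-moments decomposition (ICC = 1 when groups differ)
    zero_ssw = ssw <= 0.0
    if np.any(zero_ssw):
        sb_mom, sw_mom = _anova_components_from_stats(n1, n2, d2, ssw, n)
        sb = np.where(zero_ssw, sb_mom, sb)
        sw = np.where(zero_ssw, sw_mom, sw)
    return sb, sw


def _anova_components_from_stats(n1, n2, d2, ssw, n_total):
    g = 2
    ssb = n1 * n2 / n_total * d2  # two-group identity for sum n_g*(m_g - m)^2
    msb = ssb / (g - 1)
    msw = ssw / (n_total - g)
    n0 = (n_total - (n1 * n1 + n2 * n2) / n_total) / (g - 1)
    sb = np.maximum(0.0, (msb - msw) / n0)
    return sb, msw


def _anova_components(values: np.ndarray, labels: np.ndarray):
    n = values.shape[0]
    n1, n2, m1, m2, ssw = _group_stats(values, labels)
    return _anova_components_from_stats(n1, n2, (m1 - m2) ** 2, ssw, n)


def _icc_vector(values: np.ndarray, labels: np.ndarray, estimator: str):
    """ICCs for all item columns at once.

    Returns (icc, sigma2_between, sigma2_within, converged) arrays; a
    constant column or non-finite estimates mark the item non-converged.
    """
    values = np.asarray(values, dtype=float)
    if estimator == "reml":
        sb, sw = _reml_components(values, labels)
    elif estimator == "anova":
        sb, sw = _anova_components(values, labels)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    total = sb + sw
    converged = np.isfinite(total) & (total > 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(converged, sb / np.where(total > 0, total, 1.0), np.nan)
    return icc, sb, sw, converged


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def variance_components_oneway(
    values: np.ndarray, groups: np.ndarray, estimator: str = "reml"
) -> tuple[float, float, bool]:
    """Estimate (sigma2_between, sigma2_within, converged) for one item.

    ``groups`` is a 0/1 vector; both groups must be non-empty and there
    must be at least 4 observations.  A constant ``values`` vector
    yields ``converged=False`` (no variance to decompose).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.ndim != 1 or values.shape != groups.shape:
        raise ValueError("values and groups must be 1-D vectors of equal length")
    if values.size < 4:
        raise ValueError("need at least 4 observations")
    if not (np.any(groups == 0) and np.any(groups == 1)):
        raise ValueError("both groups must be non-empty")
    try:
        _, sb, sw, converged = _icc_vector(values[:, None], groups, estimator)
    except FloatingPointError:  # pragma: no cover - defensive
        return np.nan, np.nan, False
    return float(sb[0]), float(sw[0]), bool(converged[0])


def icc_from_components(sigma2_between: float, sigma2_within: float) -> float:
    """ICC = between / (between + within); both components must be >= 0."""
    if sigma2_between < 0 or sigma2_within < 0:
        raise ValueError("variance components must be non-negative")
    total = sigma2_between + sigma2_within
    if total <= 0:
        raise ValueError("total variance is zero; ICC undefined")
    return sigma2_between / total


def icc_series(
    rm: ResponseMatrix,
    spec: ScaleSpec,
    assignment: ClusterAssignment,
    estimator: str = "reml",
) -> IccSeries:
    """One ICC estimate per scale item, ordered by questionnaire position.

    Non-converged items (constant columns, degenerate fits) are flagged
    and logged, never silently dropped; the downstream regression uses
    the converged items only.  Fewer than 3 converged items makes the
    series unscreenable (``screenable`` property), which the caller
    turns into an error or a diagnostic.
    """
    if assignment.labels.shape[0] != rm.n_subjects:
        raise ValueError("cluster assignment does not match the response matrix")
    if tuple(rm.item_labels) != spec.labels:
        raise ValueError("response matrix columns must match the scale spec "
                         "(run apply_scale first)")
    icc, sb, sw, converged = _icc_vector(rm.values, assignment.labels, estimator)
    estimates = []
    for j, (label, pos) in enumerate(spec.items):
        if not converged[j]:
            logger.warning(
                "scale %s item %s (position %d): variance decomposition did not "
                "converge; item excluded from the slope",
                spec.scale_name, label, pos,
            )
        estimates.append(
            IccEstimate(
                position=int(pos),
                sigma2_between=float(sb[j]) if converged[j] else float("nan"),
                sigma2_within=float(sw[j]) if converged[j] else float("nan"),
                icc=float(icc[j]) if converged[j] else float("nan"),
                converged=bool(converged[j]),
            )
        )
    series = IccSeries(scale_name=spec.scale_name, estimates=estimates)
    if not series.screenable:
        logger.warning(
            "scale %s: only %d converged items; scale is unscreenable",
            spec.scale_name, series.n_converged,
        )
    return series
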