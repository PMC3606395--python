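"""Empirical ROC curves, AROC, optimal cutpoints and correlated-AUC tests.

Conventions
-----------
Every marker has a direction of abnormality. Internally values are oriented
so that *higher = more abnormal*; thresholds are reported back in natural
units. Candidate thresholds are placed at the observed values, and a value
exactly at the threshold is classified as normal (matching the inclusive
normal ranges of the normative reference), so for an ``abnormal_low``
marker "test positive" means ``value < threshold``.

The AROC estimate is the Mann-Whitney probability that a random case is
more abnormal than a random control (ties count one half); it equals the
trapezoidal area under the empirical curve exactly. The optimal operating
point minimises the Euclidean distance to the (sensitivity=1,
specificity=1) corner, ``d = sqrt((1-sens)^2 + (1-spec)^2)``.

Paired AROCs are compared with the DeLong structural-components variance
(the standard paired z-test for correlated ROC areas).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .normative_reference import ABNORMAL_HIGH, ABNORMAL_LOW


class DegenerateSampleError(ValueError):
    """Cases or controls absent (or otherwise unusable) in the input."""


def _validate(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise ValueError("values and labels must be aligned")
    if np.isnan(values).any():
        raise ValueError("missing marker values must be filtered by the caller")
    if labels.all() or not labels.any():
        raise DegenerateSampleError("need at least one case and one control")
    return values, labels


def _orient(values, direction):
    if direction == ABNORMAL_LOW:
        return -np.asarray(values, dtype=float)
    if direction == ABNORMAL_HIGH:
        return np.asarray(values, dtype=float)
    raise ValueError(f"unknown direction {direction!r}")


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve: one operating point per distinct observed value
    plus the degenerate endpoints; thresholds in natural units (NaN for the
    all-positive endpoint)."""

    direction: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_cases: int
    n_controls: int

    def __len__(self):
        return len(self.sensitivity)


@dataclass(frozen=True)
class ThresholdResult:
    """Optimal cutpoint by distance-to-corner."""

    threshold: float
    sensitivity: float
    specificity: float
    distance: float


@dataclass(frozen=True)
class AucComparison:
    """Paired comparison of two correlated AROCs."""

    auc_a: float
    auc_b: float
    delta: float
    variance: float
    z: float
    p_value: float


def distance_to_corner(sensitivity: float, specificity: float) -> float:
    """Euclidean distance from an operating point to (sens=1, spec=1)."""
    return float(np.hypot(1.0 - sensitivity, 1.0 - specificity))


def roc_curve(values, labels, direction: str) -> RocCurve:
    """Empirical ROC curve of a marker.

    Parameters
    ----------
    values
        Marker values (no missing values; caller filters).
    labels
        Boolean case indicator, aligned with ``values``.
    direction
        ``'abnormal_low'`` or ``'abnormal_high'``.
    """
    values, labels = _validate(values, labels)
    scores = _orient(values, direction)
    cases = scores[labels]
    controls = scores[~labels]
    m, n = len(cases), len(controls)

    # Candidate thresholds at each distinct observed value. With the
    # boundary-normal rule a subject is positive iff score > threshold
    # (oriented scale), so sweeping thresholds downward traces the curve
    # from (0, 0) toward (1, 1) in (FPR, TPR).
    distinct = np.unique(scores)[::-1]
    sens = np.empty(len(distinct) + 2)
    spec = np.empty(len(distinct) + 2)
    thr = np.empty(len(distinct) + 2)
    sens[0], spec[0], thr[0] = 0.0, 1.0, np.inf  # nobody positive
    for i, t in enumerate(distinct, start=1):
        sens[i] = np.mean(cases > t)
        spec[i] = np.mean(controls <= t)
        thr[i] = t
    sens[-1], spec[-1], thr[-1] = 1.0, 0.0, np.nan  # everybody positive

    # Back to natural units: oriented score = -value for abnormal_low.
    if direction == ABNORMAL_LOW:
        thr = -thr

    auc = auc_mann_whitney(values, labels, direction)
    return RocCurve(
        direction=direction,
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n_cases=m,
        n_controls=n,
    )


def trapezoid_area(curve: RocCurve) -> float:
    """Trapezoidal area under the stored operating points."""
    fpr = 1.0 - curve.specificity
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(curve.sensitivity[order], fpr[order]))


def auc_mann_whitney(values, labels, direction: str) -> float:
    """AROC as the Mann-Whitney U statistic divided by ``n_cases * n_controls``
    (ties counted one half); identical to the trapezoidal area under the
    empirical curve."""
    values, labels = _validate(values, labels)
    scores = _orient(values, direction)
    m = int(labels.sum())
    n = len(labels) - m
    ranks = stats.rankdata(scores)  # midranks handle ties
    u = ranks[labels].sum() - m * (m + 1) / 2.0
    return float(u / (m * n))


def optimal_threshold(curve: RocCurve) -> ThresholdResult:
    """Operating point minimising the distance to the perfect corner.

    Ties on the distance are broken toward higher sensitivity, then toward
    the least abnormal threshold (deterministic sweep order).
    """
    if len(curve) < 3:
        raise DegenerateSampleError("curve has no non-degenerate operating points")
    d = np.hypot(1.0 - curve.sensitivity, 1.0 - curve.specificity)
    # Sweep order is from least to most abnormal threshold; argmin on the
    # compound key (d, -sens) keeps the first (least extreme) among full ties.
    best = min(
        range(len(curve)), key=lambda i: (d[i], -curve.sensitivity[i])
    )
    return ThresholdResult(
        threshold=float(curve.thresholds[best]),
        sensitivity=float(curve.sensitivity[best]),
        specificity=float(curve.specificity[best]),
        distance=float(d[best]),
    )


# ---------------------------------------------------------------------------
# Correlated-AUC comparison (DeLong structural components)
# ---------------------------------------------------------------------------

def _structural_components(scores, labels):
    cases = scores[labels]
    controls = scores[~labels]
    m, n = len(cases), len(controls)
    # psi(case, control) = 1 if case > control, 0.5 if tied, 0 otherwise
    diff = cases[:, None] - controls[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = psi.mean(axis=1)  # per-case components
    v01 = psi.mean(axis=0)  # per-control components
    return psi.mean(), v10, v01, m, n


def compare_auc(values_a, values_b, labels, direction_a: str, direction_b: str) -> AucComparison:
    """Paired comparison of two markers' AROCs on the same subjects.

    Uses the structural-components (DeLong-type) estimate of the variance
    of the AROC difference, accounting for the within-subject pairing, and
    a two-tailed p-value from the normal approximation. Comparing a marker
    with itself yields ``delta = 0`` and ``p = 1``.
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values_a.shape != values_b.shape or values_a.shape != labels.shape:
        raise ValueError("paired markers must be measured on the same subjects")
    _validate(values_a, labels)
    _validate(values_b, labels)

    sa = _orient(values_a, direction_a)
    sb = _orient(values_b, direction_b)
    auc_a, v10_a, v01_a, m, n = _structural_components(sa, labels)
    auc_b, v10_b, v01_b, _, _ = _structural_components(sb, labels)

    s10 = np.cov(np.vstack([v10_a, v10_b]))  # 2x2, over cases
    s01 = np.cov(np.vstack([v01_a, v01_b]))  # 2x2, over controls
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = float(auc_a - auc_b)
    if var <= 0 or np.isclose(delta, 0.0) and np.isclose(var, 0.0):
        z = 0.0 if delta == 0 else np.inf * np.sign(delta)
    else:
        z = delta / np.sqrt(var)
    p = 1.0 if z == 0.0 else float(2.0 * stats.norm.sf(abs(z)))
    return AucComparison(
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        delta=delta,
        variance=float(var),
        z=float(z),
        p_value=min(p, 1.0),
    )


def export_curve(curve: RocCurve, path) -> None:
    """Write the curve's operating points as delimited text."""
    arr = np.column_stack([curve.thresholds, curve.sensitivity, curve.specificity])
    header = f"threshold,sensitivity,specificity  # direction={curve.direction} auc={curve.auc:.6f}"
    np.savetxt(path, arr, delimiter=",", header=header, comments="# ")
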