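"""Per-subject analysis features from bilateral nerve conduction measurements.

Nerve conduction studies are performed bilaterally when possible; the
analysis value for each parameter is the mean of the two sides, or the
single available side for unilateral records (e.g. after amputation).
Three composite ("summative") parameters are formed by direct addition:

* ``sum_cv``     — sural + peroneal + tibial conduction velocity (m/s)
* ``sum_fwave``  — peroneal + tibial F-wave latency (ms)
* ``sum_amp``    — amplitude potentials added numerically *without unit
  conversion* (sural in µV, motor nerves in mV), hence "arbitrary units".
  The default composition is sural + peroneal + tibial; a two-nerve
  (sural + tibial) variant is available via ``sum_amp_mode="two_nerve"``.

A summative value is present only when all of its components are present;
no partial sums are formed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .normative_reference import INDIVIDUAL_PARAMETERS, SUMMATIVE_PARAMETERS

SUM_AMP_COMPONENTS = {
    "three_nerve": ("sural_amp", "peroneal_amp", "tibial_amp"),
    "two_nerve": ("sural_amp", "tibial_amp"),
}
SUM_CV_COMPONENTS = ("sural_cv", "peroneal_cv", "tibial_cv")
SUM_FWAVE_COMPONENTS = ("peroneal_fwave", "tibial_fwave")


class MissingMeasurementError(ValueError):
    """Both sides of a required parameter are missing."""


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def bilateral_mean(left, right):
    """Mean of left/right values; the single side when one is missing.

    Raises :class:`MissingMeasurementError` when both are missing.
    """
    left_missing, right_missing = _is_missing(left), _is_missing(right)
    if left_missing and right_missing:
        raise MissingMeasurementError("both sides missing")
    if left_missing:
        return right
    if right_missing:
        return left
    return (left + right) / 2.0


def summative_parameters(features, sum_amp_mode: str = "three_nerve"):
    """Composite parameters ``(sum_amp, sum_cv, sum_fwave)`` from the 8
    individual values (mapping or Series); a sum is NaN when any component
    is missing.
    """
    if sum_amp_mode not in SUM_AMP_COMPONENTS:
        raise ValueError(f"unknown sum_amp_mode {sum_amp_mode!r}")

    def total(components):
        vals = [features[c] for c in components]
        if any(_is_missing(v) for v in vals):
            return float("nan")
        return float(sum(vals))

    return (
        total(SUM_AMP_COMPONENTS[sum_amp_mode]),
        total(SUM_CV_COMPONENTS),
        total(SUM_FWAVE_COMPONENTS),
    )


def build_features(cohort: pd.DataFrame, sum_amp_mode: str = "three_nerve") -> pd.DataFrame:
    """Derive the 8 individual + 3 summative analysis features per subject.

    Parameters
    ----------
    cohort
        Table with ``<parameter>_left`` / ``<parameter>_right`` columns
        (missing side = NaN) for each of the 8 individual parameters.
    sum_amp_mode
        Composition of the summative amplitude (see module docstring).

    Returns
    -------
    DataFrame indexed like ``cohort`` with one column per parameter plus
    the three summative columns; all-NaN pairs yield NaN (the strict
    scalar path :func:`bilateral_mean` raises instead).
    """
    out = pd.DataFrame(index=cohort.index)
    for p in INDIVIDUAL_PARAMETERS:
        left = cohort[f"{p}_left"].to_numpy(dtype=float)
        right = cohort[f"{p}_right"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            out[p] = np.where(
                np.isnan(left), right, np.where(np.isnan(right), left, (left + right) / 2.0)
            )

    amp_parts = SUM_AMP_COMPONENTS[sum_amp_mode]
    for name, parts in (
        ("sum_amp", amp_parts),
        ("sum_cv", SUM_CV_COMPONENTS),
        ("sum_fwave", SUM_FWAVE_COMPONENTS),
    ):
        cols = out[list(parts)]
        total = cols.sum(axis=1)
        total[cols.isna().any(axis=1)] = np.nan
        out[name] = total

    for s in SUMMATIVE_PARAMETERS:
        out[f"{s}_missing"] = out[s].isna()
    return out
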