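"""Normative (normal/abnormal) thresholds for nerve conduction parameters.

Reference ranges for lower-limb nerve conduction studies are conventionally
expressed as one-sided cutoffs: amplitudes and conduction velocities are
abnormal when *low*, F-wave latencies when *high*. Several cutoffs are
stratified by age (sensory amplitudes decline with age) or by height (F-wave
latencies lengthen with limb length). The shipped table
(``data/normative_thresholds.yaml``) covers the 8 individual parameters and
the 3 summative parameters used in the analysis pipeline; an alternative
table can be supplied at load time.

Boundary convention: a value exactly at the cutoff lies in the *normal*
range (the normal side is inclusive, e.g. "sural amplitude >= 7.2 µV" is
normal).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

ABNORMAL_LOW = "abnormal_low"
ABNORMAL_HIGH = "abnormal_high"

#: Individual nerve conduction parameters, in conventional reporting order.
INDIVIDUAL_PARAMETERS = (
    "sural_amp",
    "sural_cv",
    "peroneal_amp",
    "peroneal_cv",
    "peroneal_fwave",
    "tibial_amp",
    "tibial_cv",
    "tibial_fwave",
)

#: Summative (composite) parameters.
SUMMATIVE_PARAMETERS = ("sum_amp", "sum_cv", "sum_fwave")

ALL_PARAMETERS = INDIVIDUAL_PARAMETERS + SUMMATIVE_PARAMETERS

#: Direction of abnormality by parameter family.
PARAMETER_DIRECTIONS: Mapping[str, str] = {
    p: (ABNORMAL_HIGH if p.endswith("fwave") else ABNORMAL_LOW)
    for p in ALL_PARAMETERS
}


class MissingCovariateError(ValueError):
    """A stratified threshold was looked up without its covariate."""


class UnknownParameterError(KeyError):
    """The parameter is not in the normative table."""


@dataclass(frozen=True)
class ThresholdStratum:
    """One covariate stratum of a normative threshold."""

    cutoff: float
    covariate: str | None = None  # 'age' (years) or 'height' (metres)
    le: float | None = None  # covariate <= le
    gt: float | None = None  # covariate >  gt
    ge: float | None = None  # covariate >= ge
    lt: float | None = None  # covariate <  lt

    def applies(self, covariate_value: float) -> bool:
        if self.covariate is None:
            return True
        v = covariate_value
        if self.le is not None and not v <= self.le:
            return False
        if self.gt is not None and not v > self.gt:
            return False
        if self.ge is not None and not v >= self.ge:
            return False
        if self.lt is not None and not v < self.lt:
            return False
        return True


@dataclass(frozen=True)
class NormativeThreshold:
    """Normative cutoff set for one parameter."""

    parameter: str
    direction: str
    units: str
    strata: tuple[ThresholdStratum, ...]

    @property
    def stratified_by(self) -> str | None:
        return self.strata[0].covariate

    def resolve(self, age: float | None = None, height: float | None = None) -> ThresholdStratum:
        """Return the unique stratum applying to a subject.

        Raises
        ------
        MissingCovariateError
            If the parameter is stratified and the covariate is missing/NaN.
        """
        cov_name = self.stratified_by
        if cov_name is None:
            return self.strata[0]
        value = {"age": age, "height": height}[cov_name]
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise MissingCovariateError(
                f"threshold for {self.parameter!r} is stratified by {cov_name}, "
                f"but no {cov_name} was supplied"
            )
        for stratum in self.strata:
            if stratum.applies(value):
                return stratum
        raise ValueError(  # pragma: no cover - table invariant
            f"no stratum of {self.parameter!r} covers {cov_name}={value}"
        )


def _default_table_path():
    return importlib.resources.files("dspval.data") / "normative_thresholds.yaml"


@dataclass
class NormativeReference:
    """A table of normative thresholds with lookup and classification."""

    thresholds: dict[str, NormativeThreshold] = field(default_factory=dict)

    @classmethod
    def load(cls, path=None) -> "NormativeReference":
        """Load a threshold table from YAML (the shipped table by default)."""
        source = _default_table_path() if path is None else path
        with open(str(source), "r") as fh:
            raw = yaml.safe_load(fh)
        thresholds = {}
        for name, entry in raw.items():
            strata = tuple(
                ThresholdStratum(
                    cutoff=float(s["cutoff"]),
                    covariate=s.get("covariate"),
                    le=s.get("le"),
                    gt=s.get("gt"),
                    ge=s.get("ge"),
                    lt=s.get("lt"),
                )
                for s in entry["strata"]
            )
            thresholds[name] = NormativeThreshold(
                parameter=name,
                direction=entry["direction"],
                units=entry.get("units", ""),
                strata=strata,
            )
        return cls(thresholds)

    def with_override(self, parameter: str, cutoff: float) -> "NormativeReference":
        """Return a copy with a single unstratified cutoff replaced."""
        t = self[parameter]
        new = NormativeThreshold(
            parameter=parameter,
            direction=t.direction,
            units=t.units,
            strata=(ThresholdStratum(cutoff=float(cutoff)),),
        )
        out = dict(self.thresholds)
        out[parameter] = new
        return NormativeReference(out)

    def __getitem__(self, parameter: str) -> NormativeThreshold:
        try:
            return self.thresholds[parameter]
        except KeyError:
            raise UnknownParameterError(
                f"unknown parameter {parameter!r}; known: {sorted(self.thresholds)}"
            ) from None

    def lookup_threshold(
        self, parameter: str, age: float | None = None, height: float | None = None
    ) -> tuple[float, str]:
        """Return ``(cutoff, direction)`` applying to a subject."""
        t = self[parameter]
        return t.resolve(age=age, height=height).cutoff, t.direction

    def is_abnormal(
        self,
        parameter: str,
        value: float,
        age: float | None = None,
        height: float | None = None,
    ) -> bool:
        """Classify a value; the cutoff itself is normal."""
        cutoff, direction = self.lookup_threshold(parameter, age=age, height=height)
        if direction == ABNORMAL_LOW:
            return bool(value < cutoff)
        return bool(value > cutoff)

    def abnormal_mask(
        self,
        parameter: str,
        values: Sequence[float],
        ages: Sequence[float] | None = None,
        heights: Sequence[float] | None = None,
    ) -> np.ndarray:
        """Vectorised :meth:`is_abnormal` over aligned arrays.

        Missing values classify as not-abnormal (callers handle missingness).
        """
        t = self[parameter]
        values = np.asarray(values, dtype=float)
        cutoffs = np.empty_like(values)
        cov = t.stratified_by
        if cov is None:
            cutoffs[:] = t.strata[0].cutoff
        else:
            cov_values = np.asarray(ages if cov == "age" else heights, dtype=float)
            if cov_values.shape != values.shape:
                raise MissingCovariateError(
                    f"{parameter!r} is stratified by {cov}; aligned {cov} values required"
                )
            if np.isnan(cov_values).any():
                raise MissingCovariateError(
                    f"{parameter!r} is stratified by {cov}; NaN {cov} encountered"
                )
            filled = np.full(values.shape, np.nan)
            for stratum in t.strata:
                mask = np.fromiter(
                    (stratum.applies(v) for v in cov_values), bool, len(cov_values)
                )
                filled[mask] = stratum.cutoff
            cutoffs = filled
        with np.errstate(invalid="ignore"):
            if t.direction == ABNORMAL_LOW:
                out = values < cutoffs
            else:
                out = values > cutoffs
        out[np.isnan(values)] = False
        return out
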