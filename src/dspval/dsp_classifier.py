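"""Case definition for diabetic sensorimotor polyneuropathy (DSP) and the
Toronto Clinical Neuropathy Score (TCNS).

Case definition (consensus-style): a subject is a DSP case when all three
hold —

1. at least one of six neuropathic symptoms (pain, numbness, tingling,
   weakness, ataxia/imbalance, upper-limb symptoms) OR at least one of seven
   neuropathic signs (reduced/absent ankle or knee reflexes, or abnormal
   position, pinprick, light-touch, temperature, or vibration sense);
2. at least one abnormal *sural* nerve parameter (amplitude or conduction
   velocity); and
3. at least one abnormal *peroneal* nerve parameter (amplitude, conduction
   velocity, or F-wave latency),

with abnormality judged against the normative reference thresholds at the
subject's age and height.

TCNS: 6 symptom points (1 each) + 8 reflex points (4 reflexes graded
0=normal, 1=reduced, 2=absent) + 5 examination points (1 per abnormal
sensory modality) = 19 possible points. Severity strata: <=5 none, 6-8 mild,
9-11 moderate, >=12 severe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normative_reference import NormativeReference

SYMPTOM_COLUMNS = (
    "symptom_pain",
    "symptom_numbness",
    "symptom_tingling",
    "symptom_weakness",
    "symptom_ataxia",
    "symptom_upper_limb",
)

#: Examination sign columns (abnormal sensory modality = 1).
EXAM_SIGN_COLUMNS = (
    "sign_pinprick",
    "sign_temperature",
    "sign_light_touch",
    "sign_vibration",
    "sign_position",
)

REFLEX_COLUMNS = (
    "reflex_knee_left",
    "reflex_knee_right",
    "reflex_ankle_left",
    "reflex_ankle_right",
)

SURAL_CRITERIA = ("sural_amp", "sural_cv")
PERONEAL_CRITERIA = ("peroneal_amp", "peroneal_cv", "peroneal_fwave")

TCNS_STRATA = ("none", "mild", "moderate", "severe")


class UnclassifiableRecordError(ValueError):
    """A required feature or clinical item is missing."""


@dataclass(frozen=True)
class DspStatus:
    """Case-definition outcome with its criterion breakdown."""

    is_case: bool
    has_symptom_or_sign: bool
    sural_abnormal: tuple[str, ...]  # which sural parameters are abnormal
    peroneal_abnormal: tuple[str, ...]


@dataclass(frozen=True)
class TcnsResult:
    """TCNS component scores, total and severity stratum."""

    symptom_points: int
    reflex_points: int
    exam_points: int

    @property
    def total(self) -> int:
        return self.symptom_points + self.reflex_points + self.exam_points

    @property
    def stratum(self) -> str:
        return tcns_stratum(self.total)


def tcns_stratum(total: int) -> str:
    if total <= 5:
        return "none"
    if total <= 8:
        return "mild"
    if total <= 11:
        return "moderate"
    return "severe"


def _reflex_sign_present(record, site: str) -> bool:
    # A reflex counts as a present sign when reduced or absent on either side.
    return any(int(record[f"reflex_{site}_{side}"]) > 0 for side in ("left", "right"))


def has_symptom_or_sign(record) -> bool:
    """First clause of the case definition (>=1 of 6 symptoms or 7 signs)."""
    if any(bool(record[c]) for c in SYMPTOM_COLUMNS):
        return True
    if any(bool(record[c]) for c in EXAM_SIGN_COLUMNS):
        return True
    return _reflex_sign_present(record, "ankle") or _reflex_sign_present(record, "knee")


def classify_dsp(record, features, reference: NormativeReference) -> DspStatus:
    """Apply the DSP case definition to one subject.

    Parameters
    ----------
    record
        Mapping/Series with symptom, sign and reflex items plus ``age`` and
        ``height``.
    features
        Mapping/Series with the analysis values for ``sural_amp``,
        ``sural_cv``, ``peroneal_amp``, ``peroneal_cv``, ``peroneal_fwave``.
    reference
        Normative threshold table.
    """
    age, height = record["age"], record["height"]
    required = SURAL_CRITERIA + PERONEAL_CRITERIA
    for p in required:
        v = features[p] if p in features else float("nan")
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise UnclassifiableRecordError(f"missing required feature {p!r}")
    missing_items = [
        c
        for c in SYMPTOM_COLUMNS + EXAM_SIGN_COLUMNS + REFLEX_COLUMNS
        if c not in record or pd.isna(record[c])
    ]
    if missing_items:
        raise UnclassifiableRecordError(f"missing clinical items: {missing_items}")

    sural = tuple(
        p for p in SURAL_CRITERIA if reference.is_abnormal(p, features[p], age=age, height=height)
    )
    peroneal = tuple(
        p
        for p in PERONEAL_CRITERIA
        if reference.is_abnormal(p, features[p], age=age, height=height)
    )
    clinical = has_symptom_or_sign(record)
    return DspStatus(
        is_case=bool(clinical and sural and peroneal),
        has_symptom_or_sign=clinical,
        sural_abnormal=sural,
        peroneal_abnormal=peroneal,
    )


def tcns_score(record) -> TcnsResult:
    """Toronto Clinical Neuropathy Score for one subject."""
    missing = [
        c
        for c in SYMPTOM_COLUMNS + EXAM_SIGN_COLUMNS + REFLEX_COLUMNS
        if c not in record or pd.isna(record[c])
    ]
    if missing:
        raise UnclassifiableRecordError(f"missing TCNS items: {missing}")
    symptom = sum(int(bool(record[c])) for c in SYMPTOM_COLUMNS)
    reflex = sum(int(record[c]) for c in REFLEX_COLUMNS)
    exam = sum(int(bool(record[c])) for c in EXAM_SIGN_COLUMNS)
    if not all(0 <= int(record[c]) <= 2 for c in REFLEX_COLUMNS):
        raise UnclassifiableRecordError("reflex grades must be 0 (normal), 1 (reduced) or 2 (absent)")
    return TcnsResult(symptom_points=symptom, reflex_points=reflex, exam_points=exam)


# ---------------------------------------------------------------------------
# Vectorised cohort-level classification
# ---------------------------------------------------------------------------

def classify_cohort(
    cohort: pd.DataFrame, features: pd.DataFrame, reference: NormativeReference
) -> pd.Series:
    """Vectorised case definition over a cohort table (baseline visit)."""
    ages = cohort["age"].to_numpy(dtype=float)
    heights = cohort["height"].to_numpy(dtype=float)

    def any_abnormal(params):
        mask = np.zeros(len(cohort), dtype=bool)
        for p in params:
            mask |= reference.abnormal_mask(
                p, features[p].to_numpy(dtype=float), ages=ages, heights=heights
            )
        return mask

    symptoms = cohort[list(SYMPTOM_COLUMNS)].to_numpy(dtype=bool).any(axis=1)
    exam = cohort[list(EXAM_SIGN_COLUMNS)].to_numpy(dtype=bool).any(axis=1)
    reflex = (cohort[list(REFLEX_COLUMNS)].to_numpy(dtype=int) > 0).any(axis=1)
    clinical = symptoms | exam | reflex

    is_case = clinical & any_abnormal(SURAL_CRITERIA) & any_abnormal(PERONEAL_CRITERIA)
    return pd.Series(is_case, index=cohort.index, name="dsp_baseline")


def tcns_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorised TCNS totals and strata."""
    symptom = cohort[list(SYMPTOM_COLUMNS)].to_numpy(dtype=bool).sum(axis=1)
    reflex = cohort[list(REFLEX_COLUMNS)].to_numpy(dtype=int).sum(axis=1)
    exam = cohort[list(EXAM_SIGN_COLUMNS)].to_numpy(dtype=bool).sum(axis=1)
    total = symptom + reflex + exam
    strata = pd.cut(
        total,
        bins=[-1, 5, 8, 11, 19],
        labels=TCNS_STRATA,
    ).astype(str)
    return pd.DataFrame(
        {"tcns_total": total, "tcns_stratum": strata}, index=cohort.index
    )


def annotate_cohort(
    cohort: pd.DataFrame,
    features: pd.DataFrame,
    reference: NormativeReference,
) -> pd.DataFrame:
    """Return the cohort with ``dsp_baseline``, ``dsp_incident``,
    ``tcns_total`` and ``tcns_stratum`` columns added.

    ``dsp_incident`` is defined for followed baseline non-cases only: it is
    True when the subject met the case definition at a follow-up visit. In
    cohorts carrying a generator group label the incident outcome is read
    from that label (the simulator encodes incidence there rather than in
    longitudinal conduction values); it is left missing otherwise.
    """
    out = cohort.copy()
    out["dsp_baseline"] = classify_cohort(cohort, features, reference)
    out[["tcns_total", "tcns_stratum"]] = tcns_cohort(cohort)

    incident = pd.Series(pd.NA, index=cohort.index, dtype="boolean")
    if "group_label" in cohort.columns and "followed_up" in cohort.columns:
        followed_controls = cohort["followed_up"].astype(bool) & ~out["dsp_baseline"]
        incident[followed_controls] = (
            cohort.loc[followed_controls, "group_label"] == "incident_case"
        )
    out["dsp_incident"] = incident
    return out
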