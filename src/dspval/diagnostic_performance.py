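"""Operating characteristics at a threshold, combined (serial/parallel)
tests, and group-comparison summary tables.

Predictive values depend on prevalence: ``PPV = TP/(TP+FP)`` and
``NPV = TN/(TN+FN)`` are post-test probabilities in the analysed sample.
Undefined rates (zero denominators) are reported as NaN with a warning,
never as 0.

Group comparisons follow the conventional two-group (Student's t /
chi-squared without continuity correction) and three-group (one-way ANOVA /
chi-squared) tests, with a simple Bonferroni correction over the family of
11 nerve-conduction rows (alpha = 0.05/11 ~ 0.0045).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normative_reference import ABNORMAL_HIGH, ABNORMAL_LOW, ALL_PARAMETERS
from .roc_toolkit import DegenerateSampleError

#: Family size of the nerve-conduction comparisons (8 individual + 3 summative).
NCS_FAMILY_SIZE = 11
BONFERRONI_ALPHA = 0.05 / NCS_FAMILY_SIZE


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts with the derived operating characteristics."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.n

    @property
    def sensitivity(self) -> float:
        return _safe_rate(self.tp, self.tp + self.fn, "sensitivity")

    @property
    def specificity(self) -> float:
        return _safe_rate(self.tn, self.tn + self.fp, "specificity")

    @property
    def ppv(self) -> float:
        return _safe_rate(self.tp, self.tp + self.fp, "PPV")

    @property
    def npv(self) -> float:
        return _safe_rate(self.tn, self.tn + self.fn, "NPV")


def _safe_rate(num: int, denom: int, name: str) -> float:
    if denom == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN", stacklevel=3)
        return float("nan")
    return num / denom


@dataclass(frozen=True)
class GroupComparisonRow:
    """One row of a group-comparison table."""

    variable: str
    summaries: dict          # group -> 'mean±SD' or 'count (%)'
    test: str                # 't', 'chi2', 'anova' or 'not_applicable'
    p_value: float
    in_ncs_family: bool
    significant_after_bonferroni: bool | None


def _positive_mask(values, threshold, direction):
    values = np.asarray(values, dtype=float)
    if direction == ABNORMAL_LOW:
        return values < threshold
    if direction == ABNORMAL_HIGH:
        return values > threshold
    raise ValueError(f"unknown direction {direction!r}")


def confusion_at_threshold(values, labels, threshold: float, direction: str) -> ConfusionSummary:
    """Confusion summary of a dichotomised marker.

    Test-positive means the value lies strictly on the abnormal side of the
    threshold (a boundary value is normal, matching the normative
    convention).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise DegenerateSampleError("need at least one case and one control")
    positive = _positive_mask(values, threshold, direction)
    return _from_masks(positive, labels)


def _from_masks(positive, labels) -> ConfusionSummary:
    return ConfusionSummary(
        tp=int((positive & labels).sum()),
        fp=int((positive & ~labels).sum()),
        tn=int((~positive & ~labels).sum()),
        fn=int((~positive & labels).sum()),
    )


def combined_test(
    values_1,
    values_2,
    labels,
    threshold_1: float,
    threshold_2: float,
    direction_1: str,
    direction_2: str,
    rule: str = "both_abnormal_positive",
) -> ConfusionSummary:
    """Confusion summary of a two-marker combination rule.

    ``both_abnormal_positive`` (serial/AND rule): positive only when both
    markers are abnormal — raises specificity and PPV at the cost of
    sensitivity. ``both_normal_negative`` (parallel/OR rule): negative only
    when both markers are normal — raises sensitivity and NPV at the cost
    of specificity.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise DegenerateSampleError("need at least one case and one control")
    p1 = _positive_mask(values_1, threshold_1, direction_1)
    p2 = _positive_mask(values_2, threshold_2, direction_2)
    if rule == "both_abnormal_positive":
        positive = p1 & p2
    elif rule == "both_normal_negative":
        positive = p1 | p2
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return _from_masks(positive, labels)


# ---------------------------------------------------------------------------
# Group-comparison table
# ---------------------------------------------------------------------------

def _is_categorical(series: pd.Series) -> bool:
    if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
        return True
    vals = series.dropna().unique()
    return set(np.asarray(vals).tolist()) <= {0, 1, True, False}


def _summarise(series: pd.Series, categorical: bool) -> str:
    s = series.dropna()
    if categorical:
        count = int(pd.Series(s).astype(bool).sum()) if s.dtype != object else len(s)
        if s.dtype != object:
            return f"{count} ({100 * count / max(len(s), 1):.0f}%)"
        top = s.mode().iloc[0]
        return f"{(s == top).sum()} {top}"
    return f"{s.mean():.2f}±{s.std(ddof=1):.2f}"

def group_comparison(
    cohort: pd.DataFrame,
    variables,
    grouping: str | pd.Series,
    ncs_family=None,
) -> list[GroupComparisonRow]:
    """Compare variables across 2 or 3 groups, one row per variable.

    Continuous variables use Student's t-test (2 groups) or one-way ANOVA
    (3 groups); binary/categorical variables use the chi-squared test
    without continuity correction. Variables named in ``ncs_family``
    (default: the 11 nerve-conduction parameters present) carry the
    Bonferroni significance flag at alpha = 0.05/11. Zero-variance
    variables are reported as not-applicable rather than failing.
    """
    groups = cohort[grouping] if isinstance(grouping, str) else pd.Series(grouping, index=cohort.index)
    levels = [g for g in groups.dropna().unique()]
    if len(levels) not in (2, 3):
        raise ValueError(f"grouping must define 2 or 3 groups, got {len(levels)}")
    if ncs_family is None:
        ncs_family = {v for v in variables if v in ALL_PARAMETERS}

    rows = []
    for var in variables:
        series = cohort[var]
        categorical = _is_categorical(series)
        per_group = [series[groups == g].dropna() for g in levels]
        summaries = {
            str(g): _summarise(series[groups == g], categorical) for g in levels
        }
        test, p = _run_test(per_group, categorical)
        in_family = var in ncs_family
        rows.append(
            GroupComparisonRow(
                variable=var,
                summaries=summaries,
                test=test,
                p_value=p,
                in_ncs_family=in_family,
                significant_after_bonferroni=(
                    bool(p < BONFERRONI_ALPHA) if in_family and not np.isnan(p) else None
                ),
            )
        )
    return rows


def _run_test(per_group, categorical: bool) -> tuple[str, float]:
    if any(len(g) == 0 for g in per_group):
        return "not_applicable", float("nan")
    if categorical:
        table = np.array(
            [
                [int(pd.Series(g).astype(bool).sum()), int((~pd.Series(g).astype(bool)).sum())]
                for g in per_group
            ]
        )
        if (table.sum(axis=0) == 0).any():
            return "not_applicable", float("nan")
        try:
            res = stats.chi2_contingency(table, correction=False)
        except ValueError:
            return "not_applicable", float("nan")
        return "chi2", float(res.pvalue)
    arrays = [np.asarray(g, dtype=float) for g in per_group]
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        # identical constant everywhere: no difference by construction
        return "not_applicable" if len(arrays[0]) < 2 else "t" if len(arrays) == 2 else "anova", 1.0
    if any(np.allclose(a, a[0]) for a in arrays) and len(arrays) == 2:
        # zero within-group variance in one arm: t statistic still defined
        pass
    if len(arrays) == 2:
        t, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
        return "t", float(p)
    f, p = stats.f_oneway(*arrays)
    return "anova", float(p)


def comparison_table(rows) -> pd.DataFrame:
    """Render :func:`group_comparison` rows as a DataFrame."""
    recs = []
    for r in rows:
        rec = {"variable": r.variable, **r.summaries, "test": r.test, "p_value": r.p_value}
        rec["bonferroni_significant"] = r.significant_after_bonferroni
        recs.append(rec)
    return pd.DataFrame(recs)
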