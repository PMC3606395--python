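"""End-to-end concurrent- and predictive-validity analyses.

``run_concurrent`` contrasts baseline DSP cases against baseline controls;
``run_predictive`` contrasts, among followed baseline controls, those who
develop DSP (incident cases) against those who do not, using *baseline*
marker values. Each of the 11 markers (8 individual + 3 summative NCS
parameters) is analysed with its direction of abnormality: ROC curve,
AROC, distance-to-corner optimal threshold, confusion summary at that
threshold, and a paired correlated-AUC comparison against the
highest-AROC marker. ``replicate`` wraps either analysis in a seeded
Monte-Carlo loop over freshly generated synthetic cohorts and averages
the per-marker AROCs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dsp_classifier, ncs_features, roc_toolkit, synthetic_cohort
from .diagnostic_performance import ConfusionSummary, confusion_at_threshold
from .normative_reference import (
    ALL_PARAMETERS,
    NormativeReference,
    PARAMETER_DIRECTIONS,
)
from .roc_toolkit import AucComparison, RocCurve, ThresholdResult

#: Default marker list: all 8 individual + 3 summative parameters.
DEFAULT_MARKERS = ALL_PARAMETERS


class MissingMarkerError(KeyError):
    """A requested marker column is absent from the feature table."""


@dataclass
class AnalysisConfig:
    """Settings for one analysis run."""

    analysis: str = "concurrent"  # 'concurrent' or 'predictive'
    markers: tuple = DEFAULT_MARKERS
    sum_amp_mode: str = "three_nerve"
    #: Optional marker -> threshold mapping evaluated alongside the
    #: empirically optimal thresholds (e.g. previously published cutoffs).
    reference_thresholds: dict = field(default_factory=dict)
    bonferroni_alpha: float = 0.05 / 11
    seed: int | None = None
    n_replicates: int = 200

    def __post_init__(self):
        if self.analysis not in ("concurrent", "predictive"):
            raise ValueError(f"unknown analysis {self.analysis!r}")
        unknown = [m for m in self.markers if m not in ALL_PARAMETERS]
        if unknown:
            raise ValueError(f"unknown markers {unknown}; registry: {list(ALL_PARAMETERS)}")
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")


@dataclass(frozen=True)
class MarkerResult:
    """Per-marker analysis bundle."""

    marker: str
    direction: str
    curve: RocCurve
    optimal: ThresholdResult
    confusion: ConfusionSummary
    reference_confusion: ConfusionSummary | None
    comparison_vs_best: AucComparison | None  # None for the best marker itself

    @property
    def auc(self) -> float:
        return self.curve.auc


@dataclass(frozen=True)
class AnalysisResult:
    """Result of one concurrent or predictive analysis."""

    analysis: str
    n_subjects: int
    n_cases: int
    best_marker: str
    markers: dict  # marker name -> MarkerResult

    def auc_table(self) -> pd.DataFrame:
        rows = []
        for name, r in self.markers.items():
            rows.append(
                {
                    "marker": name,
                    "direction": r.direction,
                    "auc": r.auc,
                    "p_vs_best": r.comparison_vs_best.p_value if r.comparison_vs_best else np.nan,
                    "optimal_threshold": r.optimal.threshold,
                    "sensitivity": r.optimal.sensitivity,
                    "specificity": r.optimal.specificity,
                    "distance": r.optimal.distance,
                }
            )
        return pd.DataFrame(rows).set_index("marker")


def prepare_cohort(
    cohort: pd.DataFrame,
    reference: NormativeReference | None = None,
    sum_amp_mode: str = "three_nerve",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive features and DSP labels for a raw cohort table.

    Returns ``(annotated cohort, feature table)`` where the cohort gains
    ``dsp_baseline``/``dsp_incident``/TCNS columns.
    """
    reference = reference if reference is not None else NormativeReference.load()
    features = ncs_features.build_features(cohort, sum_amp_mode=sum_amp_mode)
    annotated = dsp_classifier.annotate_cohort(cohort, features, reference)
    return annotated, features


def _analyse(
    features: pd.DataFrame,
    labels: pd.Series,
    config: AnalysisConfig,
) -> AnalysisResult:
    labels = labels.astype(bool)
    results: dict[str, MarkerResult] = {}
    partial: dict[str, tuple] = {}
    for marker in config.markers:
        if marker not in features.columns:
            raise MissingMarkerError(f"marker column {marker!r} missing from features")
        values = features[marker]
        keep = values.notna()
        v = values[keep].to_numpy(dtype=float)
        y = labels[keep].to_numpy()
        direction = PARAMETER_DIRECTIONS[marker]
        curve = roc_toolkit.roc_curve(v, y, direction)
        optimal = roc_toolkit.optimal_threshold(curve)
        confusion = confusion_at_threshold(v, y, optimal.threshold, direction)
        ref_confusion = None
        if marker in config.reference_thresholds:
            ref_confusion = confusion_at_threshold(
                v, y, config.reference_thresholds[marker], direction
            )
        partial[marker] = (direction, curve, optimal, confusion, ref_confusion)

    best = max(partial, key=lambda m: partial[m][1].auc)
    best_values = features[best]
    for marker, (direction, curve, optimal, confusion, ref_confusion) in partial.items():
        comparison = None
        if marker != best:
            keep = features[marker].notna() & best_values.notna()
            comparison = roc_toolkit.compare_auc(
                features.loc[keep, marker].to_numpy(dtype=float),
                best_values[keep].to_numpy(dtype=float),
                labels[keep].to_numpy(),
                PARAMETER_DIRECTIONS[marker],
                PARAMETER_DIRECTIONS[best],
            )
        results[marker] = MarkerResult(
            marker=marker,
            direction=direction,
            curve=curve,
            optimal=optimal,
            confusion=confusion,
            reference_confusion=ref_confusion,
            comparison_vs_best=comparison,
        )
    return AnalysisResult(
        analysis=config.analysis,
        n_subjects=int(len(labels)),
        n_cases=int(labels.sum()),
        best_marker=best,
        markers=results,
    )


def run_concurrent(
    cohort: pd.DataFrame,
    config: AnalysisConfig | None = None,
    reference: NormativeReference | None = None,
    label_column: str = "dsp_baseline",
) -> AnalysisResult:
    """Concurrent-validity analysis: baseline cases vs baseline controls.

    The cohort must carry a boolean ``label_column`` (produced by
    :func:`prepare_cohort`, or ``group_label``-derived for simulation
    studies); markers are the bilateral-mean/summative feature values.
    """
    config = config or AnalysisConfig(analysis="concurrent")
    annotated, features = prepare_cohort(cohort, reference, config.sum_amp_mode)
    if label_column == "group_label":
        labels = annotated["group_label"] == "prevalent_case"
    else:
        labels = annotated[label_column].astype(bool)
    return _analyse(features, labels, config)


def run_predictive(
    cohort: pd.DataFrame,
    config: AnalysisConfig | None = None,
    reference: NormativeReference | None = None,
    label_column: str = "dsp_incident",
) -> AnalysisResult:
    """Predictive-validity analysis among followed baseline controls.

    Baseline marker values of followed non-case subjects predict incident
    DSP at follow-up. Raises if the cohort has no followed subjects.
    """
    config = config or AnalysisConfig(analysis="predictive")
    annotated, features = prepare_cohort(cohort, reference, config.sum_amp_mode)
    followed = annotated["followed_up"].astype(bool)
    if label_column == "group_label":
        subset = followed & annotated["group_label"].isin(synthetic_cohort.CONTROL_GROUPS)
        labels = annotated.loc[subset, "group_label"] == "incident_case"
    else:
        subset = followed & annotated[label_column].notna()
        labels = annotated.loc[subset, label_column].astype(bool)
    if not subset.any():
        raise ValueError("no followed control subjects; predictive analysis impossible")
    return _analyse(features.loc[subset], labels, config)


def replicate(
    mode: str,
    n_replicates: int = 200,
    cohort_config: synthetic_cohort.CohortConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
    seed: int | None = None,
    reference: NormativeReference | None = None,
) -> pd.DataFrame:
    """Monte-Carlo AROC estimation over freshly simulated cohorts.

    Each replicate generates a cohort from ``cohort_config`` with a child
    seed, runs the requested analysis with outcomes taken from the
    generator's group labels (so the case/control split has exactly the
    configured sizes), and records each marker's AROC. Returns a DataFrame
    indexed by marker with ``mean_auc``, ``sd_auc`` and ``n_replicates``.

    Label-consistency enforcement is off by default here: AROC estimation
    uses the unconditioned group-conditional distributions whose moments
    match the configured summary statistics exactly.
    """
    if mode not in ("concurrent", "predictive"):
        raise ValueError(f"unknown mode {mode!r}")
    if cohort_config is None:
        cohort_config = synthetic_cohort.CohortConfig(enforce_label_consistency=False)
    analysis_config = analysis_config or AnalysisConfig(analysis=mode)
    reference = reference if reference is not None else NormativeReference.load()

    child_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    run = run_concurrent if mode == "concurrent" else run_predictive
    aucs: dict[str, list[float]] = {m: [] for m in analysis_config.markers}
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        cohort = synthetic_cohort.generate_cohort(cohort_config, rng=rng, reference=reference)
        result = run(cohort, analysis_config, reference, label_column="group_label")
        for m, r in result.markers.items():
            aucs[m].append(r.auc)
    rows = {
        m: {"mean_auc": float(np.mean(v)), "sd_auc": float(np.std(v, ddof=1)), "n_replicates": n_replicates}
        for m, v in aucs.items()
    }
    return pd.DataFrame(rows).T.rename_axis("marker")


# ---------------------------------------------------------------------------
# Report serialisation
# ---------------------------------------------------------------------------

def result_summary(result: AnalysisResult) -> dict:
    """JSON-serialisable summary of an analysis result."""
    out = {
        "analysis": result.analysis,
        "n_subjects": result.n_subjects,
        "n_cases": result.n_cases,
        "best_marker": result.best_marker,
        "markers": {},
    }
    for name, r in result.markers.items():
        entry = {
            "direction": r.direction,
            "auc": r.auc,
            "optimal_threshold": r.optimal.threshold,
            "sensitivity": r.optimal.sensitivity,
            "specificity": r.optimal.specificity,
            "distance": r.optimal.distance,
            "ppv": r.confusion.ppv,
            "npv": r.confusion.npv,
        }
        if r.comparison_vs_best is not None:
            entry["p_vs_best"] = r.comparison_vs_best.p_value
        if r.reference_confusion is not None:
            c = r.reference_confusion
            entry["at_reference_threshold"] = {
                "sensitivity": c.sensitivity,
                "specificity": c.specificity,
                "ppv": c.ppv,
                "npv": c.npv,
            }
        out["markers"][name] = entry
    return out


def write_report(result: AnalysisResult, out_dir) -> None:
    """Write the per-marker table, ROC curves and a structured summary."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.auc_table().to_csv(out / f"{result.analysis}_markers.csv")
    for name, r in result.markers.items():
        roc_toolkit.export_curve(r.curve, out / f"roc_{result.analysis}_{name}.csv")
    with open(out / f"{result.analysis}_summary.json", "w") as fh:
        json.dump(result_summary(result), fh, indent=2, allow_nan=True)
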