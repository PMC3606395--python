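"""Synthetic diabetic-neuropathy cohort generator.

Emulates a clinic cohort of subjects with diabetes assessed by nerve
conduction studies (NCS), stratified into three analysis groups:

* ``prevalent_case``    — DSP present at baseline (default n=246);
* ``incident_control``  — no DSP at baseline or follow-up (n=84);
* ``incident_case``     — no DSP at baseline, DSP at follow-up (n=25);

plus a configurable number of additional baseline controls never
re-assessed (default 51, drawn from the pooled-control mixture), so the
default baseline cohort has 406 subjects of whom 160 are controls and the
predictive analysis set is the 109 followed controls.

Statistical model
-----------------
Per group, the 8 NCS parameters are driven by one equicorrelated latent
Gaussian vector oriented along *abnormality* (low amplitude, low velocity,
long latency all correspond to high latent values, so F-wave latencies are
sign-flipped relative to velocities). Velocities and latencies are linear
(Gaussian marginals with the configured mean/SD); amplitudes map through a
Gaussian copula onto zero-truncated normal marginals whose parent
parameters are moment-matched so the *truncated* distribution reproduces
the configured mean/SD exactly. The single equicorrelation per group is
either given or calibrated in closed form against the configured SD of the
summed conduction velocities (the best-identified joint constraint).

Bilateral measurements are the subject's latent value plus small
independent side noise; a small fraction of subjects is unilateral.
Symptoms, examination signs and reflex grades are independent draws with
per-group prevalences. With label-consistency enforcement on, case-labelled
subjects are rejection-resampled until they satisfy the DSP case definition
and control-labelled subjects until they do not, so the rule-based
classifier reproduces group labels exactly at baseline.
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from . import dsp_classifier, ncs_features
from .normative_reference import INDIVIDUAL_PARAMETERS, NormativeReference

GROUPS = ("prevalent_case", "incident_control", "incident_case")
CONTROL_GROUPS = ("incident_control", "incident_case")

AMPLITUDE_PARAMETERS = ("sural_amp", "peroneal_amp", "tibial_amp")
FWAVE_PARAMETERS = ("peroneal_fwave", "tibial_fwave")
CV_PARAMETERS = ("sural_cv", "peroneal_cv", "tibial_cv")

#: Group-conditional (mean, SD) of each individual NCS parameter, natural
#: units (µV sural amplitude, mV motor amplitudes, m/s velocities, ms
#: latencies).
DEFAULT_NCS_MOMENTS: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "prevalent_case": {
        "sural_amp": (2.61, 2.23),
        "sural_cv": (39.4, 5.51),
        "peroneal_amp": (2.60, 2.05),
        "peroneal_cv": (36.6, 5.21),
        "peroneal_fwave": (59.5, 6.64),
        "tibial_amp": (4.23, 3.37),
        "tibial_cv": (36.4, 5.37),
        "tibial_fwave": (63.9, 7.40),
    },
    "incident_control": {
        "sural_amp": (9.60, 5.55),
        "sural_cv": (47.2, 5.04),
        "peroneal_amp": (6.37, 2.58),
        "peroneal_cv": (45.0, 3.26),
        "peroneal_fwave": (49.7, 4.46),
        "tibial_amp": (9.34, 4.45),
        "tibial_cv": (44.8, 5.43),
        "tibial_fwave": (53.6, 5.54),
    },
    "incident_case": {
        "sural_amp": (5.74, 3.99),
        "sural_cv": (42.2, 5.10),
        "peroneal_amp": (5.08, 2.95),
        "peroneal_cv": (41.2, 3.60),
        "peroneal_fwave": (56.5, 9.47),
        "tibial_amp": (7.23, 3.83),
        "tibial_cv": (40.1, 4.17),
        "tibial_fwave": (59.9, 6.08),
    },
}

#: Group-conditional SDs of the summative parameters; the sum-of-CV SD is
#: the correlation-calibration target.
DEFAULT_SUMMATIVE_SDS: Mapping[str, Mapping[str, float]] = {
    "prevalent_case": {"sum_amp": 6.19, "sum_cv": 12.3, "sum_fwave": 12.6},
    "incident_control": {"sum_amp": 9.80, "sum_cv": 10.2, "sum_fwave": 8.99},
    "incident_case": {"sum_amp": 7.73, "sum_cv": 9.72, "sum_fwave": 14.3},
}

DEFAULT_DEMOGRAPHICS: Mapping[str, Mapping[str, float]] = {
    "prevalent_case": {
        "age_mean": 57.0, "age_sd": 10.0,
        "height_mean": 1.72, "height_sd": 0.09,
        "male_prob": 0.73, "type1_prob": 0.16,
        "duration_mean": 14.0, "duration_sd": 11.0,
    },
    "incident_control": {
        "age_mean": 56.0, "age_sd": 9.0,
        "height_mean": 1.67, "height_sd": 0.09,
        "male_prob": 0.57, "type1_prob": 0.16,
        "duration_mean": 10.0, "duration_sd": 11.0,
    },
    "incident_case": {
        "age_mean": 55.0, "age_sd": 10.0,
        "height_mean": 1.70, "height_sd": 0.09,
        "male_prob": 0.64, "type1_prob": 0.16,
        "duration_mean": 10.0, "duration_sd": 7.0,
    },
}

# Clinical-item prevalences: chosen so mean TCNS lands near the observed
# group means (cases ~11, controls ~8); the printed group statistics
# constrain them only loosely.
DEFAULT_SYMPTOM_PREVALENCE = {"prevalent_case": 0.70, "incident_control": 0.45, "incident_case": 0.45}
DEFAULT_REFLEX_GRADE_PROBS = {
    "prevalent_case": (0.30, 0.40, 0.30),     # P(normal), P(reduced), P(absent)
    "incident_control": (0.55, 0.30, 0.15),
    "incident_case": (0.55, 0.30, 0.15),
}

CLINICAL_COLUMNS = (
    dsp_classifier.SYMPTOM_COLUMNS
    + dsp_classifier.EXAM_SIGN_COLUMNS
    + dsp_classifier.REFLEX_COLUMNS
)
NCS_SIDE_COLUMNS = tuple(
    f"{p}_{side}" for p in INDIVIDUAL_PARAMETERS for side in ("left", "right")
)
COHORT_COLUMNS = (
    ("subject_id", "group_label", "age", "height", "sex", "diabetes_type",
     "diabetes_duration")
    + CLINICAL_COLUMNS
    + NCS_SIDE_COLUMNS
    + ("followed_up", "follow_up_years")
)


class LabelEnforcementError(RuntimeError):
    """Rejection resampling exhausted its retry budget."""


@dataclass
class CohortConfig:
    """Simulation parameters for one synthetic cohort.

    Defaults reproduce the reference study conditions: group sizes 246/84/25
    plus 51 unfollowed controls, group-conditional NCS moments, calibrated
    equicorrelation, 109/160 follow-up with mean 3.9 (SD 2.4) years.
    """

    group_sizes: dict = field(
        default_factory=lambda: {"prevalent_case": 246, "incident_control": 84, "incident_case": 25}
    )
    n_extra_controls: int = 51
    ncs_moments: dict = field(default_factory=lambda: _deep_copy(DEFAULT_NCS_MOMENTS))
    summative_sds: dict = field(default_factory=lambda: _deep_copy(DEFAULT_SUMMATIVE_SDS))
    #: 'calibrated', a single float, or a per-group mapping.
    correlation: object = "calibrated"
    symptom_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_SYMPTOM_PREVALENCE))
    reflex_grade_probs: dict = field(default_factory=lambda: _deep_copy(DEFAULT_REFLEX_GRADE_PROBS))
    demographics: dict = field(default_factory=lambda: _deep_copy(DEFAULT_DEMOGRAPHICS))
    #: Probabilities of death / loss-to-follow-up among baseline controls.
    death_prob: float = 11 / 160
    loss_prob: float = 40 / 160
    followup_mean: float = 3.9
    followup_sd: float = 2.4
    side_noise_frac: float = 0.05   # side noise SD as a fraction of the group SD
    unilateral_prob: float = 0.05   # fraction of subjects with one side missing
    enforce_label_consistency: bool = True
    rejection_budget: int = 1000    # resampling rounds per subject
    sum_amp_mode: str = "three_nerve"
    seed: int | None = None

    def __post_init__(self):
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group size for {g!r} must be >= 1")
        for g, mom in self.ncs_moments.items():
            for p, (_, sd) in mom.items():
                if sd <= 0:
                    raise ValueError(f"SD for ({g}, {p}) must be > 0")
        for prob in (self.death_prob, self.loss_prob, self.unilateral_prob):
            if not 0 <= prob <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for g, p in self.symptom_prevalence.items():
            vals = p.values() if isinstance(p, Mapping) else [p]
            if not all(0 <= v <= 1 for v in vals):
                raise ValueError(f"symptom prevalence for {g!r} outside [0, 1]")

    # -- serialisation ------------------------------------------------------
    def to_yaml(self, path=None) -> str | None:
        doc = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is None:
            return doc
        with open(path, "w") as fh:
            fh.write(doc)
        return None

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        # YAML round-trips tuples as lists; normalise the moment pairs.
        if "ncs_moments" in raw:
            raw["ncs_moments"] = {
                g: {p: tuple(mv) for p, mv in mom.items()} for g, mom in raw["ncs_moments"].items()
            }
        if "reflex_grade_probs" in raw:
            raw["reflex_grade_probs"] = {
                g: tuple(v) for g, v in raw["reflex_grade_probs"].items()
            }
        return cls(**raw)

    # -- derived quantities -------------------------------------------------
    def group_correlation(self, group: str) -> float:
        """Equicorrelation for a group (calibrating if requested)."""
        k = len(INDIVIDUAL_PARAMETERS)
        if self.correlation == "calibrated":
            sds = [self.ncs_moments[group][p][1] for p in CV_PARAMETERS]
            target = self.summative_sds[group]["sum_cv"]
            return calibrate_correlation(sds, target, n_joint=k)
        if isinstance(self.correlation, Mapping):
            rho = float(self.correlation[group])
        else:
            rho = float(self.correlation)
        if not -1.0 / (k - 1) < rho < 1.0:
            raise ValueError(f"correlation {rho} outside (-1/{k-1}, 1)")
        return rho


def _deep_copy(mapping):
    return {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in mapping.items()}


# ---------------------------------------------------------------------------
# Correlation calibration
# ---------------------------------------------------------------------------

def calibrate_correlation(component_sds, target_sum_sd, n_joint: int | None = None) -> float:
    """Equicorrelation reproducing a target SD for a sum of components.

    For components with SDs ``s_i`` and pairwise correlation ``rho``,
    ``Var(sum) = sum s_i^2 + 2 rho sum_{i<j} s_i s_j``; solving for ``rho``
    given the target sum SD gives the calibrated value. The result is
    clipped (with a warning) to the positive-definite range for the
    ``n_joint`` jointly simulated variables.
    """
    sds = np.asarray(component_sds, dtype=float)
    if sds.size < 2:
        raise ValueError("at least two component SDs are required")
    if target_sum_sd < 0:
        raise ValueError("target_sum_sd must be >= 0")
    cross = float(np.sum(np.outer(sds, sds)) - np.sum(sds**2)) / 2.0
    rho = (target_sum_sd**2 - float(np.sum(sds**2))) / (2.0 * cross)
    k = n_joint if n_joint is not None else sds.size
    lo, hi = -1.0 / (k - 1), 1.0
    eps = 1e-9
    if not lo < rho < hi:
        clipped = float(np.clip(rho, lo + eps, hi - eps))
        warnings.warn(
            f"calibrated correlation {rho:.4f} outside ({lo:.4f}, 1); clipped to {clipped:.4f}",
            stacklevel=2,
        )
        return clipped
    return float(rho)


# ---------------------------------------------------------------------------
# Zero-truncated Gaussian amplitude marginals
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _matched_truncnorm_params(mean: float, sd: float) -> tuple[float, float]:
    """Parent ``(mu, sigma)`` of a normal truncated at 0 whose truncated
    distribution has the given mean and SD.

    The mean/SD ratio of a zero-truncated normal is a strictly decreasing
    function of ``alpha = -mu/sigma`` ranging from +inf (no truncation) down
    to ~1 (heavy truncation), so the ratio pins down ``alpha`` and the scale
    follows.
    """
    ratio = mean / sd
    if ratio <= 1.0:
        raise ValueError(
            f"mean/SD ratio {ratio:.3f} <= 1 is not attainable by a zero-truncated normal"
        )

    def ratio_minus_target(alpha):
        lam = stats.norm.pdf(alpha) / stats.norm.sf(alpha)
        m = -alpha + lam
        v = 1.0 + alpha * lam - lam**2
        return m / np.sqrt(v) - ratio

    alpha = optimize.brentq(ratio_minus_target, -12.0, 12.0, xtol=1e-12)
    lam = stats.norm.pdf(alpha) / stats.norm.sf(alpha)
    v = 1.0 + alpha * lam - lam**2
    sigma = sd / np.sqrt(v)
    mu = -alpha * sigma
    return float(mu), float(sigma)


def _truncnorm_ppf(u, mean, sd):
    mu, sigma = _matched_truncnorm_params(float(mean), float(sd))
    a = -mu / sigma
    return stats.truncnorm.ppf(u, a, np.inf, loc=mu, scale=sigma)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _equicorr_cholesky(rho: float, k: int) -> np.ndarray:
    cov = np.full((k, k), rho)
    np.fill_diagonal(cov, 1.0)
    return np.linalg.cholesky(cov)


def _positive_gamma(rng, mean, sd, size):
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=size)


def _draw_ncs(group: str, n: int, config: CohortConfig, rho: float, rng) -> pd.DataFrame:
    """Bilateral NCS measurements for ``n`` subjects of one group."""
    params = INDIVIDUAL_PARAMETERS
    k = len(params)
    chol = _equicorr_cholesky(rho, k)
    # Latent abnormality: higher value = more abnormal for every parameter.
    z = rng.standard_normal((n, k)) @ chol.T

    out = {}
    moments = config.ncs_moments[group]
    latent = {}
    for j, p in enumerate(params):
        mean, sd = moments[p]
        if p in AMPLITUDE_PARAMETERS:
            # Gaussian copula onto a moment-matched zero-truncated normal;
            # high abnormality -> low amplitude.
            u = stats.norm.cdf(-z[:, j])
            latent[p] = _truncnorm_ppf(u, mean, sd)
        elif p in FWAVE_PARAMETERS:
            latent[p] = mean + sd * z[:, j]          # long latency = abnormal
        else:
            latent[p] = mean - sd * z[:, j]          # low velocity = abnormal

    unilateral = rng.random(n) < config.unilateral_prob
    drop_left = rng.random(n) < 0.5
    for p in params:
        _, sd = moments[p]
        noise_sd = config.side_noise_frac * sd
        left = latent[p] + rng.normal(0.0, noise_sd, size=n)
        right = latent[p] + rng.normal(0.0, noise_sd, size=n)
        if p in AMPLITUDE_PARAMETERS:
            left = np.maximum(left, 0.0)
            right = np.maximum(right, 0.0)
        left = np.where(unilateral & drop_left, np.nan, left)
        right = np.where(unilateral & ~drop_left, np.nan, right)
        out[f"{p}_left"] = left
        out[f"{p}_right"] = right
    return pd.DataFrame(out)


def _draw_clinical(group: str, n: int, config: CohortConfig, rng) -> pd.DataFrame:
    prev = config.symptom_prevalence[group]
    out = {}
    for c in dsp_classifier.SYMPTOM_COLUMNS + dsp_classifier.EXAM_SIGN_COLUMNS:
        p = prev[c] if isinstance(prev, Mapping) else prev
        out[c] = (rng.random(n) < p).astype(int)
    grade_probs = np.asarray(config.reflex_grade_probs[group], dtype=float)
    grade_probs = grade_probs / grade_probs.sum()
    for c in dsp_classifier.REFLEX_COLUMNS:
        out[c] = rng.choice(3, size=n, p=grade_probs)
    return pd.DataFrame(out)


def _draw_demographics(group: str, n: int, config: CohortConfig, rng) -> pd.DataFrame:
    d = config.demographics[group]
    age = np.clip(rng.normal(d["age_mean"], d["age_sd"], n), 20.0, 90.0)
    height = np.clip(rng.normal(d["height_mean"], d["height_sd"], n), 1.40, 2.10)
    sex = np.where(rng.random(n) < d["male_prob"], "M", "F")
    dtype = np.where(rng.random(n) < d["type1_prob"], "type1", "type2")
    duration = _positive_gamma(rng, d["duration_mean"], d["duration_sd"], n)
    return pd.DataFrame(
        {
            "age": age,
            "height": height,
            "sex": sex,
            "diabetes_type": dtype,
            "diabetes_duration": duration,
        }
    )


def _draw_group(group: str, n: int, config: CohortConfig, rho: float, rng) -> pd.DataFrame:
    demo = _draw_demographics(group, n, config, rng)
    clin = _draw_clinical(group, n, config, rng)
    ncs = _draw_ncs(group, n, config, rho, rng)
    df = pd.concat([demo, clin, ncs], axis=1)
    df.insert(0, "group_label", group)
    return df


def _enforce_labels(
    df: pd.DataFrame,
    group: str,
    config: CohortConfig,
    rho: float,
    rng,
    reference: NormativeReference,
) -> pd.DataFrame:
    """Rejection-resample until the case definition matches the group label.

    Demographics are kept (they are subject covariates); clinical items and
    NCS values are redrawn for violating subjects, up to the configured
    budget of rounds.
    """
    want_case = group == "prevalent_case"
    redraw_cols = list(CLINICAL_COLUMNS + NCS_SIDE_COLUMNS)
    for _ in range(config.rejection_budget):
        feats = ncs_features.build_features(df, sum_amp_mode=config.sum_amp_mode)
        is_case = dsp_classifier.classify_cohort(df, feats, reference).to_numpy()
        bad = is_case != want_case
        if not bad.any():
            return df
        n_bad = int(bad.sum())
        fresh = pd.concat(
            [
                _draw_clinical(group, n_bad, config, rng),
                _draw_ncs(group, n_bad, config, rho, rng),
            ],
            axis=1,
        )
        df.loc[bad, redraw_cols] = fresh[redraw_cols].to_numpy()
    raise LabelEnforcementError(
        f"label-consistency resampling exhausted {config.rejection_budget} rounds "
        f"for group {group!r}; the configured moments/prevalences make the "
        f"target label too improbable"
    )


def generate_cohort(
    config: CohortConfig | None = None,
    rng: np.random.Generator | int | None = None,
    reference: NormativeReference | None = None,
) -> pd.DataFrame:
    """Generate one synthetic baseline cohort.

    Returns a table with one row per subject: demographics, the 13 clinical
    indicator items, 4 reflex grades, bilateral values for the 8 NCS
    parameters (missing side = NaN), the generator group label, and
    follow-up status. With default sizes: 246 prevalent cases + 160
    controls (84 incident controls + 25 incident cases, followed, plus 51
    unfollowed controls from the pooled-control mixture) = 406 subjects.
    """
    config = config if config is not None else CohortConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if reference is None:
        reference = NormativeReference.load()

    frames = []
    for group in GROUPS:
        n = config.group_sizes[group]
        rho = config.group_correlation(group)
        df = _draw_group(group, n, config, rho, rng)
        df["followed_up"] = group in CONTROL_GROUPS
        if config.enforce_label_consistency:
            df = _enforce_labels(df, group, config, rho, rng, reference)
        frames.append(df)

    # Unfollowed extra controls from the pooled-control mixture (assumed
    # exchangeable with the followed controls).
    if config.n_extra_controls > 0:
        n_ic = config.group_sizes["incident_control"]
        n_icase = config.group_sizes["incident_case"]
        p_case = n_icase / (n_ic + n_icase)
        comp = rng.binomial(config.n_extra_controls, p_case)
        for group, n in (("incident_control", config.n_extra_controls - comp), ("incident_case", comp)):
            if n == 0:
                continue
            rho = config.group_correlation(group)
            df = _draw_group(group, n, config, rho, rng)
            df["followed_up"] = False
            if config.enforce_label_consistency:
                df = _enforce_labels(df, group, config, rho, rng, reference)
            frames.append(df)

    cohort = pd.concat(frames, ignore_index=True)
    cohort.insert(0, "subject_id", [f"S{i:04d}" for i in range(len(cohort))])
    followed = cohort["followed_up"].to_numpy(dtype=bool)
    years = np.full(len(cohort), np.nan)
    if followed.any():
        years[followed] = _positive_gamma(
            rng, config.followup_mean, config.followup_sd, int(followed.sum())
        )
    cohort["follow_up_years"] = years
    return cohort[list(COHORT_COLUMNS)]


def apply_attrition(
    controls: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator | int | None = None,
    keep_followed: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mark a fixed-size followed subset among baseline controls.

    The followed count is ``round(n * (1 - death_prob - loss_prob))``,
    selected by sampling without replacement (rows flagged in
    ``keep_followed`` are retained first). Followed subjects receive a
    positive follow-up time (gamma with the configured mean/SD).
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng if rng is not None else config.seed)
    n = len(controls)
    n_followed = int(round(n * (1.0 - config.death_prob - config.loss_prob)))
    if n_followed > n:
        raise ValueError(f"requested {n_followed} followed subjects but only {n} controls")

    order = rng.permutation(n)
    if keep_followed is not None:
        keep = np.asarray(keep_followed, dtype=bool)
        order = np.concatenate([order[keep[order]], order[~keep[order]]])
    followed_idx = order[:n_followed]
    followed = np.zeros(n, dtype=bool)
    followed[followed_idx] = True

    out = controls.copy()
    out["followed_up"] = followed
    years = np.full(n, np.nan)
    if n_followed:
        years[followed] = _positive_gamma(rng, config.followup_mean, config.followup_sd, n_followed)
    out["follow_up_years"] = years
    return out


# ---------------------------------------------------------------------------
# Cohort table I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write the cohort as CSV with a seed-recording comment header."""
    buf = io.StringIO()
    buf.write(f"# dspval synthetic cohort; seed={seed}\n")
    cohort.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort table written by :func:`write_cohort` (or compatible)."""
    return pd.read_csv(path, comment="#")
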