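# Methods

## Study design emulated

The package analyses a cross-sectional + longitudinal diagnostic-accuracy
design in a diabetes clinic population. At baseline every subject is
classified by a rule-based DSP case definition; prevalent cases and
controls form the **concurrent** contrast. Baseline controls are followed
(with attrition) and re-classified; converters (incident cases) versus
non-converters form the **predictive** contrast, evaluated on *baseline*
marker values. The default study conditions are 246 prevalent cases and
160 baseline controls, of whom 109 are followed (84 incident controls, 25
incident cases; mean follow-up 3.9 y, SD 2.4 y) and 51 are lost (11 deaths,
40 losses to follow-up).

## Case definition and TCNS

DSP ⇔ all of: (i) ≥1 of 6 symptoms (pain, numbness, tingling, weakness,
ataxia/imbalance, upper-limb) or ≥1 of 7 signs (reduced/absent ankle or
knee reflexes; abnormal position, pinprick, light-touch, temperature or
vibration sense); (ii) ≥1 abnormal sural parameter (amplitude, conduction
velocity); (iii) ≥1 abnormal peroneal parameter (amplitude, conduction
velocity, F-wave latency). Bilaterality of a sign is not required — any
abnormality counts. TCNS assigns 1 point per symptom, 0/1/2 per reflex
(normal/reduced/absent, 4 reflexes, 8 points — the only reading under
which the components sum to the canonical 19-point maximum) and 1 point
per abnormal examination modality; strata: ≤5 none, 6–8 mild, 9–11
moderate, ≥12 severe.

## Normative thresholds

Shipped as an editable YAML table. Directions: amplitudes and velocities
abnormal-low, F-wave latencies abnormal-high. Sural amplitude and peroneal
amplitude are age-stratified (≤65 vs >65 y), F-wave latencies
height-stratified (≥1.829 m vs below). A value exactly at a cutoff is
**normal** (normal ranges are stated inclusively). The tibial F-wave
cutoff defaults to 55 ms; an empirically derived 58.5 ms convention also
circulates and can be set via `NormativeReference.with_override`. The
tibial amplitude cutoff is 10 mV (motor amplitudes are measured in mV).

## Derived features

Per parameter the analysis value is the bilateral mean, or the single side
when one side is missing; a subject with both sides missing is
unclassifiable for that parameter. Summatives are plain sums with no
partial sums: Σcv = sural + peroneal + tibial velocity; Σfwave = peroneal +
tibial latency; Σamp adds sural (µV), peroneal and tibial (mV) amplitudes
*numerically without unit conversion* ("arbitrary units"). The default
Σamp composition is the three-nerve sum, which is the composition
consistent with the published group means (9.44 ≈ 9.49, 25.31 ≈ 25.3,
18.05 ≈ 18.0); a two-nerve (sural + tibial) variant, matching the narrative
description of the composite, is available by flag.

## Synthetic cohort model

No patient-level data exist to ship, so the generator reproduces the
published group-conditional summary statistics; all downstream code is
exercised against it.

* **Marginals.** Only means and SDs are published, so Gaussian marginals
  are assumed for velocities and latencies. Amplitudes are non-negative:
  they use zero-truncated Gaussians whose parent (µ, σ) are solved (Brent
  root-find on the mean/SD ratio) so the *truncated* law has exactly the
  configured mean and SD. Naive truncation of an N(mean, SD) would bias
  the sural amplitude of prevalent cases upward by ≈0.23 SD and break
  moment recovery.
* **Dependence.** One equicorrelation ρ per group across the 8 parameters,
  on a latent scale oriented along abnormality (latencies sign-flipped so
  "slower velocity ↔ longer latency" is a positive association).
  Amplitudes attach through a Gaussian copula. ρ is calibrated in closed
  form against the published SD of Σcv,
  ρ = (SD²(Σcv) − Σσᵢ²) / (2 Σᵢ<ⱼ σᵢσⱼ), the best-identified joint
  constraint (≈0.38/0.31/0.35 in the three groups); within-subject
  correlations are otherwise unpublished, so equicorrelation is an
  acknowledged stand-in, settable in the config.
* **Bilaterality.** Left/right = latent value + independent noise with SD
  5% of the group SD (inflates the bilateral-mean SD by <0.2%); 5% of
  subjects are unilateral. Published sources confirm bilateral testing
  with occasional unilateral records but give no rates; these are chosen
  as clinically plausible.
* **Clinical items.** Symptoms and examination signs are Bernoulli (0.70
  per item in prevalent cases, 0.45 in controls) and reflex grades
  categorical (cases 0.30/0.40/0.30 normal/reduced/absent; controls
  0.55/0.30/0.15), chosen so mean TCNS lands near the observed group means
  (≈11.7 cases, ≈7.4 controls); the published statistics constrain these
  only loosely.
* **Structure.** The three analysed groups (246/84/25) are drawn from
  their own columns; 51 additional never-followed controls are drawn from
  the pooled-control mixture (assumed exchangeable with the followed
  controls — unverifiable but standard), giving 406 baseline subjects,
  60% baseline prevalence and a 109-subject predictive set. Follow-up
  times are gamma with mean 3.9, SD 2.4 y. `apply_attrition` marks exactly
  ⌊n·(1−p_death−p_loss)⌉ controls as followed by sampling without
  replacement.
* **Label consistency.** Optionally (default on), subjects are
  rejection-resampled (clinical + NCS items; demographics kept; up to
  1000 rounds) until prevalent cases satisfy the case definition and
  controls do not, making the classifier reproduce group labels exactly —
  this is what yields the exact 246/406 and 25/109 counts. Enforcement is
  exact rejection sampling from the conditioned distribution, so moments
  shift toward the enforced label: measured shifts under the default
  moments stay below 0.3 SD for prevalent cases and incident controls,
  while incident-case *baseline* values (conditioned not to meet the
  definition yet, although an unconditional draw from their column often
  would) shift toward normality by up to ≈0.7 SD. These magnitudes are the
  documented enforcement tolerance and are regression-tested.

**What the generator does not emulate:** longitudinal NCS trajectories
(incidence is encoded in the group label, not in follow-up conduction
values), biochemical covariates, visit-level timing of incident detection,
measurement drift, and any non-Gaussian skew/kurtosis of real conduction
data. Passing tests therefore demonstrate correctness of the analysis
machinery and consistency with the published summary statistics — not
validity on any particular clinical dataset.

## ROC analysis

Candidate thresholds sit at the observed values with the boundary-normal
convention, plus the two degenerate endpoints. AROC is the Mann–Whitney
statistic (midranks for ties), provably equal to the trapezoidal area of
the stored curve (tested to 1e−12). The optimal cutpoint minimises
d = √((1−Se)² + (1−Sp)²); ties break toward higher sensitivity, then by
the deterministic sweep order. Paired AROCs are compared with the DeLong
structural-components variance and a two-tailed normal p; comparing a
marker with itself gives Δ = 0, p = 1. The asymptotic p is well calibrated
at realistic sizes (type-I error 0.05 within binomial 99% bounds at
40 cases/60 controls over 1000 null replicates) but rough at very small n
(deviations up to ≈0.2 from the exact within-subject permutation p at
n = 12) — use a permutation test below a few dozen subjects. A
Pencina-style added-marker reclassification framework is sometimes cited
in this context; what is implemented here is the standard paired
correlated-AUC z-test.

## Replicate (Monte-Carlo) protocol

`replicate(mode, n_replicates, ...)` generates fresh cohorts from child
seeds (`numpy` `SeedSequence.spawn`) and averages per-marker AROCs.
Outcomes are taken from the generator's group labels with enforcement
*off*: estimation then happens under the unconditioned group-conditional
distributions whose moments match the configured statistics exactly, and
the case/control split has exactly the configured sizes. (Enforcement is
for structural realism of the classifier pipeline; switching it on couples
the outcome to the markers through the case definition and conditions the
incident-case baseline distribution, which is a different — also
supported — experiment.) Default problem sizes: 200 replicates of the
406-subject cohort for either analysis, a few tens of seconds on one CPU;
the dispersion across replicates (SD ≈ 0.02 concurrent, ≈ 0.05
predictive) is reported alongside the means.

## Group-comparison tables

Two groups: Student's t (continuous) and χ² without continuity correction
(categorical); three groups: one-way ANOVA and χ². The 11 NCS rows (8
individual + 3 summative) form the Bonferroni family, α = 0.05/11 ≈
0.0045. Zero-variance variables report "not applicable" rather than
failing; undefined predictive values (zero denominators) are NaN with a
warning.

## Known limitations

* Equicorrelation and Gaussian/truncated-Gaussian marginals are
  identification choices, not estimates; only the Σcv SD constrains the
  dependence.
* Published PPV/NPV figures are not reproducible exactly from rounded
  sensitivities/specificities and group sizes, so predictive values are
  reported by the pipeline but not used as calibration targets.
* The CLI `analyze --labels classifier` on an *unenforced* synthetic
  cohort mixes generator labels and classifier output; for simulation
  studies prefer `--labels group` (the replicate wrapper does this
  automatically).
* Optimal thresholds sit at observed values, so threshold estimates are
  granular at small n and not age/height-adjusted.
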