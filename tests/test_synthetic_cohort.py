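"""Synthetic cohort generator: calibration, moments, attrition, determinism."""

import io

import numpy as np
import pytest

from dspval import CohortConfig, apply_attrition, calibrate_correlation, generate_cohort
from dspval.ncs_features import build_features
from dspval.normative_reference import INDIVIDUAL_PARAMETERS
from dspval.synthetic_cohort import (
    AMPLITUDE_PARAMETERS,
    CONTROL_GROUPS,
    DEFAULT_NCS_MOMENTS,
    _matched_truncnorm_params,
    write_cohort,
)


class TestCalibrateCorrelation:
    def test_closed_form_example(self):
        # rho = (target^2 - sum s_i^2) / (2 sum_{i<j} s_i s_j), evaluated by hand
        assert calibrate_correlation([5.51, 5.21, 5.37], 12.3) == pytest.approx(0.3764, abs=5e-4)

    def test_independence_and_perfect_correlation(self):
        assert calibrate_correlation([1, 1], np.sqrt(2)) == pytest.approx(0.0, abs=1e-12)
        assert calibrate_correlation([1, 1], 2.0, n_joint=2) == pytest.approx(1.0, abs=1e-6)

    def test_fewer_than_two_components_errors(self):
        with pytest.raises(ValueError):
            calibrate_correlation([5.0], 5.0)

    def test_out_of_range_is_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            rho = calibrate_correlation([1, 1], 3.0, n_joint=2)
        assert rho < 1.0

    def test_simulation_recovers_target_sum_sd(self):
        """Monte-Carlo cross-check: equicorrelated triples with the calibrated
        rho reproduce the target sum SD."""
        sds = np.array([5.51, 5.21, 5.37])
        target = 12.3
        rho = calibrate_correlation(sds, target)
        cov = np.outer(sds, sds) * rho
        np.fill_diagonal(cov, sds**2)
        rng = np.random.default_rng(0)
        draws = rng.multivariate_normal(np.zeros(3), cov, size=200_000)
        assert draws.sum(axis=1).std(ddof=1) == pytest.approx(target, rel=0.01)


class TestStructure:
    def test_default_sizes_and_groups(self, default_cohort):
        assert len(default_cohort) == 406
        labels = default_cohort["group_label"]
        assert (labels == "prevalent_case").sum() == 246
        assert (labels != "prevalent_case").sum() == 160
        assert default_cohort["followed_up"].sum() == 109
        followed = default_cohort[default_cohort["followed_up"]]
        assert set(followed["group_label"]) <= set(CONTROL_GROUPS)

    def test_amplitudes_nonnegative_and_sides_present(self, default_cohort):
        for p in AMPLITUDE_PARAMETERS:
            for side in ("left", "right"):
                vals = default_cohort[f"{p}_{side}"].dropna()
                assert (vals >= 0).all()
        for p in INDIVIDUAL_PARAMETERS:
            both_missing = (
                default_cohort[f"{p}_left"].isna() & default_cohort[f"{p}_right"].isna()
            )
            assert not both_missing.any()

    def test_follow_up_years_positive_for_followed(self, default_cohort):
        followed = default_cohort["followed_up"].astype(bool)
        assert (default_cohort.loc[followed, "follow_up_years"] > 0).all()
        assert default_cohort.loc[~followed, "follow_up_years"].isna().all()

    def test_determinism_byte_identical(self, reference):
        def render(seed):
            cohort = generate_cohort(CohortConfig(seed=seed), reference=reference)
            buf = io.StringIO()
            cohort.to_csv(buf, index=False)
            return buf.getvalue()

        assert render(5) == render(5)
        assert render(5) != render(6)


class TestMomentRecovery:
    @pytest.fixture(scope="class")
    def big_cohort(self, reference):
        cfg = CohortConfig(
            group_sizes={"prevalent_case": 12000, "incident_control": 12000, "incident_case": 10},
            n_extra_controls=0,
            enforce_label_consistency=False,
            seed=42,
        )
        return generate_cohort(cfg, reference=reference)

    @pytest.mark.parametrize("group", ["prevalent_case", "incident_control"])
    @pytest.mark.parametrize("parameter", INDIVIDUAL_PARAMETERS)
    def test_mean_and_sd_within_3_se(self, big_cohort, group, parameter):
        mean, sd = DEFAULT_NCS_MOMENTS[group][parameter]
        feats = build_features(big_cohort[big_cohort["group_label"] == group])
        x = feats[parameter].dropna().to_numpy()
        n = len(x)
        se_mean = sd / np.sqrt(n)
        # side noise inflates the bilateral-mean SD by < 0.15% at the default
        # settings; 3-SE bands absorb it
        se_sd = sd / np.sqrt(2 * (n - 1))
        assert abs(x.mean() - mean) < 3 * se_mean + 0.01 * sd
        assert abs(x.std(ddof=1) - sd) < 3 * se_sd + 0.01 * sd

    def test_summative_cv_sd_calibration_within_5pct(self, big_cohort):
        for group in ("prevalent_case", "incident_control"):
            target = {"prevalent_case": 12.3, "incident_control": 10.2}[group]
            feats = build_features(big_cohort[big_cohort["group_label"] == group])
            got = feats["sum_cv"].dropna().std(ddof=1)
            assert abs(got - target) / target < 0.05

    def test_truncated_moment_matching_is_exact(self):
        # parent parameters reproduce the target moments of the truncated law
        from scipy import stats

        for mean, sd in [(2.61, 2.23), (9.60, 5.55), (4.23, 3.37)]:
            mu, sigma = _matched_truncnorm_params(mean, sd)
            a = -mu / sigma
            dist = stats.truncnorm(a, np.inf, loc=mu, scale=sigma)
            assert dist.mean() == pytest.approx(mean, abs=1e-8)
            assert dist.std() == pytest.approx(sd, abs=1e-8)


class TestEnforcement:
    def test_moments_within_documented_tolerance_under_enforcement(self, reference):
        """Label enforcement conditions each group's NCS distribution on the
        case definition, shifting moments toward the enforced label: under
        the default study moments the shift stays below 0.25 SD for
        prevalent cases and incident controls. Incident cases (conditioned
        at baseline to *not* yet meet the definition, although their
        unconditional distribution often would) shift further — bounded by
        1 SD here — and always toward normality."""
        cfg = CohortConfig(
            group_sizes={"prevalent_case": 4000, "incident_control": 4000, "incident_case": 1500},
            n_extra_controls=0,
            seed=3,
        )
        cohort = generate_cohort(cfg, reference=reference)
        for group in ("prevalent_case", "incident_control"):
            feats = build_features(cohort[cohort["group_label"] == group])
            for p in INDIVIDUAL_PARAMETERS:
                mean, sd = DEFAULT_NCS_MOMENTS[group][p]
                assert abs(feats[p].mean() - mean) < 0.30 * sd, (group, p)
        feats = build_features(cohort[cohort["group_label"] == "incident_case"])
        for p in INDIVIDUAL_PARAMETERS:
            mean, sd = DEFAULT_NCS_MOMENTS["incident_case"][p]
            shift = feats[p].mean() - mean
            assert abs(shift) < 1.0 * sd, p
            if abs(shift) > 0.1 * sd:  # material shifts point toward normal
                assert (shift < 0) == p.endswith("fwave"), p

    def test_impossible_configuration_errors(self, reference):
        # controls whose conduction values are deep in the abnormal range can
        # never avoid the case definition
        cfg = CohortConfig(
            group_sizes={"prevalent_case": 2, "incident_control": 5, "incident_case": 2},
            n_extra_controls=0,
            rejection_budget=10,
            seed=0,
        )
        for p, (m, s) in cfg.ncs_moments["incident_control"].items():
            cfg.ncs_moments["incident_control"][p] = (
                (m * 0.2, s * 0.1) if not p.endswith("fwave") else (m * 2.0, s * 0.1)
            )
        with pytest.raises(RuntimeError, match="incident_control"):
            generate_cohort(cfg, reference=reference)

    def test_zero_prevalence_controls_have_no_cases_without_ncs_signs(self, reference):
        """With no symptoms or clinical signs anywhere, nobody can meet the
        case definition (first clause fails regardless of NCS)."""
        cfg = CohortConfig(
            group_sizes={"prevalent_case": 1, "incident_control": 30, "incident_case": 5},
            n_extra_controls=0,
            symptom_prevalence={g: 0.0 for g in DEFAULT_NCS_MOMENTS},
            reflex_grade_probs={g: (1.0, 0.0, 0.0) for g in DEFAULT_NCS_MOMENTS},
            enforce_label_consistency=False,
            seed=1,
        )
        cohort = generate_cohort(cfg, reference=reference)
        from dspval.dsp_classifier import classify_cohort

        feats = build_features(cohort)
        controls = cohort["group_label"] != "prevalent_case"
        assert not classify_cohort(cohort[controls], feats[controls], reference).any()


class TestAttrition:
    def test_exact_followed_count(self, reference):
        cfg = CohortConfig(seed=2, enforce_label_consistency=False)
        cohort = generate_cohort(cfg, reference=reference)
        controls = cohort[cohort["group_label"] != "prevalent_case"].reset_index(drop=True)
        out = apply_attrition(controls, cfg, rng=0)
        assert out["followed_up"].sum() == 109

    def test_zero_attrition_keeps_everyone(self, reference):
        cfg = CohortConfig(death_prob=0.0, loss_prob=0.0, seed=2, enforce_label_consistency=False)
        cohort = generate_cohort(cfg, reference=reference)
        controls = cohort[cohort["group_label"] != "prevalent_case"].reset_index(drop=True)
        out = apply_attrition(controls, cfg, rng=0)
        assert out["followed_up"].all()

    def test_followup_time_moments(self):
        import pandas as pd

        cfg = CohortConfig()
        df = pd.DataFrame({"group_label": ["incident_control"] * 10_000})
        out = apply_attrition(df, CohortConfig(death_prob=0.0, loss_prob=0.0), rng=1)
        years = out["follow_up_years"]
        assert (years > 0).all()
        assert abs(years.mean() - cfg.followup_mean) < 3 * cfg.followup_sd / 100
        assert abs(years.std(ddof=1) - cfg.followup_sd) < 0.1

    def test_overfull_request_errors(self):
        import pandas as pd

        df = pd.DataFrame({"group_label": ["incident_control"] * 5})
        cfg = CohortConfig()
        # doctor the attrition after construction to request > n followed
        cfg.death_prob, cfg.loss_prob = -0.5, 0.0
        with pytest.raises(ValueError, match="followed"):
            apply_attrition(df, cfg, rng=0)


class TestConfigIO:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = CohortConfig(seed=9)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = CohortConfig.from_yaml(path)
        assert back == cfg

    def test_cohort_io_roundtrip(self, tmp_path, small_cohort):
        from dspval import read_cohort

        path = tmp_path / "cohort.csv"
        write_cohort(small_cohort, path, seed=7)
        assert open(path).readline().startswith("# dspval synthetic cohort; seed=7")
        back = read_cohort(path)
        assert len(back) == len(small_cohort)
        np.testing.assert_allclose(
            back["sural_amp_left"].to_numpy(), small_cohort["sural_amp_left"].to_numpy()
        )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(group_sizes={"prevalent_case": 0, "incident_control": 1, "incident_case": 1})
        bad = {g: dict(m) for g, m in DEFAULT_NCS_MOMENTS.items()}
        bad["prevalent_case"]["sural_cv"] = (39.4, -1.0)
        with pytest.raises(ValueError):
            CohortConfig(ncs_moments=bad)
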