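"""Synthetic cohort generation: determinism, invariants, correlation wiring,
systemic-lab associations and preset calibration contracts."""

import math

import numpy as np
import pandas as pd
import pytest

from choriflow.cohort import (
    CalibrationError,
    CohortConfig,
    ConfigurationError,
    DEFAULT_PRESETS,
    GroupPreset,
    calibrate_preset,
    generate_cohort,
    generate_risk_dataset,
    latent_loadings,
    sample_systemic,
)
from dataclasses import replace


class TestGenerateCohort:
    def test_default_sizes(self):
        df = generate_cohort(CohortConfig(base_seed=1))
        assert len(df) == 45
        assert df["group"].value_counts().to_dict() == {
            "dr": 18, "dm_no_dr": 15, "control": 12,
        }

    def test_byte_identical_for_fixed_seed(self):
        a = generate_cohort(CohortConfig(base_seed=3))
        b = generate_cohort(CohortConfig(base_seed=3))
        assert a.to_csv(index=False) == b.to_csv(index=False)
        c = generate_cohort(CohortConfig(base_seed=4))
        assert a.to_csv(index=False) != c.to_csv(index=False)

    def test_zero_variance_presets_hit_means_exactly(self):
        presets = {
            name: replace(
                p, target_ccfa_sd=0.0, target_cv_sd=0.0, target_vld_sd=0.0,
                pros_sd=0.0, rpe_sd=0.0,
            )
            for name, p in DEFAULT_PRESETS.items()
        }
        df = generate_cohort(CohortConfig(n_per_group=(2, 2, 2), base_seed=9, presets=presets))
        for name, p in presets.items():
            sub = df[df["group"] == name]
            assert (sub["pros_length"] == p.pros_mean).all()

    def test_inclusion_invariants_always_hold(self):
        df = generate_cohort(CohortConfig(n_per_group=(60, 60, 60), base_seed=5))
        assert (df["bcva_logmar"] < 0.05).all()
        assert (df["axial_length"] < 27).all()
        assert (df[["pros_length", "rpe_volume", "target_cv", "target_vld"]] > 0).all().all()
        assert df["target_ccfa"].between(0, 100).all()
        assert (df["quality_index"] > 7).all()

    def test_group_mean_recovery_at_large_n(self):
        """Law of large numbers: group means approach preset targets
        (3 sigma / sqrt(n) bounds at n = 500)."""
        n = 500
        df = generate_cohort(CohortConfig(n_per_group=(n, n, n), base_seed=7))
        checks = {
            "pros_length": ("pros_mean", "pros_sd"),
            "target_ccfa": ("target_ccfa_mean", "target_ccfa_sd"),
            "target_vld": ("target_vld_mean", "target_vld_sd"),
            "target_cv": ("target_cv_mean", "target_cv_sd"),
        }
        for g, preset in DEFAULT_PRESETS.items():
            sub = df[df["group"] == g]
            for col, (mf, sf) in checks.items():
                mean, sd = getattr(preset, mf), getattr(preset, sf)
                assert abs(sub[col].mean() - mean) < 3 * sd / math.sqrt(n) + 1e-9, col

    def test_control_pros_converges_to_64_5(self):
        df = generate_cohort(CohortConfig(n_per_group=(500, 500, 500), base_seed=7))
        control = df[df["group"] == "control"]
        assert abs(control["pros_length"].mean() - 64.5) < 0.5

    def test_correlation_wiring_at_large_n(self):
        """Pooled target-channel CCFA-VLD correlation hits the configured
        0.572 within +/-0.03 at n=5000."""
        df = generate_cohort(CohortConfig(n_per_group=(1334, 1667, 1999), base_seed=11))
        r = np.corrcoef(df["target_ccfa"], df["target_vld"])[0, 1]
        assert r == pytest.approx(0.572, abs=0.03)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_per_group=(1, 2, 2))
        with pytest.raises(ConfigurationError, match="target_ccfa_sd"):
            replace(DEFAULT_PRESETS["control"], target_ccfa_sd=-1.0)
        with pytest.raises(ConfigurationError, match="target_ccfa_mean"):
            replace(DEFAULT_PRESETS["control"], target_ccfa_mean=120.0)


class TestLatentLoadings:
    def test_loadings_in_range_and_signed(self):
        lam = latent_loadings()
        assert set(lam) == {"ccfa", "vld", "cv", "pros", "rpe"}
        assert all(-1 < v < 1 for v in lam.values())
        assert lam["ccfa"] > 0 and lam["vld"] > 0 and lam["pros"] > 0
        assert lam["cv"] < 0 and lam["rpe"] < 0

    def test_sign_structure_of_generated_measures(self):
        df = generate_cohort(CohortConfig(n_per_group=(700, 700, 700), base_seed=2))
        c = df[["target_ccfa", "target_cv", "target_vld", "pros_length", "rpe_volume"]].corr()
        assert c.loc["target_ccfa", "target_vld"] > 0
        assert c.loc["target_ccfa", "pros_length"] > 0
        assert c.loc["target_ccfa", "rpe_volume"] < 0
        assert c.loc["target_cv", "target_vld"] < 0


class TestSampleSystemic:
    def test_null_association_equalizes_groups(self):
        from choriflow.cohort import ExposureSpec

        spec = {"hba1c": ExposureSpec("hba1c", 7.0, 1.0, age_coef=0.0)}
        n = 4000
        df = pd.DataFrame({"age": np.full(n, 50.0),
                           "impaired": np.arange(n) < n // 2})
        out = sample_systemic(df, "impaired", spec, seed=0)
        p_imp = out.loc[out["impaired"], "hba1c_exceed"].mean()
        p_ok = out.loc[~out["impaired"], "hba1c_exceed"].mean()
        assert abs(p_imp - p_ok) < 0.04

    def test_crude_or_recovers_preset_at_large_n(self):
        """2x2 count oracle: simulated crude OR within 15% of the 4.992
        generative preset at n = 5000."""
        out = generate_risk_dataset(5000, seed=3)
        a = ((out["impaired"]) & (out["hba1c_exceed"])).sum()
        b = ((~out["impaired"]) & (out["hba1c_exceed"])).sum()
        c = ((out["impaired"]) & (~out["hba1c_exceed"])).sum()
        d = ((~out["impaired"]) & (~out["hba1c_exceed"])).sum()
        crude = (a * d) / (b * c)
        assert crude == pytest.approx(4.992, rel=0.15)

    def test_values_consistent_with_indicator(self):
        out = generate_risk_dataset(500, seed=1)
        assert (out.loc[out["hba1c_exceed"], "hba1c"] >= 7.0).all()
        assert (out.loc[~out["hba1c_exceed"], "hba1c"] < 7.0).all()
        assert (out.loc[~out["hdl_c_exceed"], "hdl_c"] >= 40.0).all()  # low HDL is the exposure
        assert (out[["hdl_c", "ldl_c", "triglyceride", "total_cholesterol"]] > 0).all().all()

    def test_all_impaired_degenerate_design_flagged_downstream(self):
        from choriflow.stats import fit_logistic

        n = 300
        df = pd.DataFrame({"age": np.random.default_rng(0).normal(50, 8, n),
                           "impaired": np.ones(n, dtype=bool)})
        out = sample_systemic(df, "impaired", seed=2)
        res = fit_logistic(out["impaired"], out[["hba1c_exceed", "age"]].astype(float))
        assert res[0].separation


class TestCalibration:
    """Contracts of the bisection calibrator on a cheap analytic stand-in
    pipeline (the real image-pipeline calibration is exercised in the
    acceptance suite)."""

    @staticmethod
    def _toy_pipeline(void, het, seed):
        # smooth monotone response with deterministic per-seed jitter
        rng = np.random.default_rng(seed)
        ccfa = 97.0 * (1.0 - void) + rng.normal(0, 0.3)
        cv = 0.05 + 0.12 * het + rng.normal(0, 0.004)
        return ccfa, cv

    def test_calibrates_to_targets(self):
        cal = calibrate_preset(DEFAULT_PRESETS["control"], self._toy_pipeline,
                               tol=0.5, cv_tol=0.01, seed=1, n_eyes=10)
        assert abs(cal.achieved_ccfa - 69.1) <= 0.5
        assert abs(cal.achieved_cv - 0.124) <= 0.01
        assert cal.ccfa_slope < 0 and cal.cv_slope > 0

    def test_controls_for_maps_linearly(self):
        cal = calibrate_preset(DEFAULT_PRESETS["control"], self._toy_pipeline,
                               tol=0.5, cv_tol=0.01, seed=1, n_eyes=10)
        v_lo, _ = cal.controls_for(60.0, 0.124)
        v_hi, _ = cal.controls_for(75.0, 0.124)
        assert v_lo > cal.void_param > v_hi  # lower CCFA needs more void

    def test_non_bracketing_target_raises(self):
        # a CV target below the pipeline's floor cannot be bracketed
        bad = replace(DEFAULT_PRESETS["control"], target_cv_mean=0.01)
        with pytest.raises(CalibrationError):
            calibrate_preset(bad, self._toy_pipeline, tol=0.5, cv_tol=0.005,
                             seed=1, n_eyes=10)

    def test_boundary_target_full_flow(self):
        perfect = replace(DEFAULT_PRESETS["control"], target_ccfa_mean=97.0)
        cal = calibrate_preset(perfect, self._toy_pipeline, tol=0.5, cv_tol=0.01,
                               seed=1, n_eyes=10)
        assert cal.void_param <= 0.01
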