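"""Self-calibrated synthetic recovery of the study-level quantities.

Runs the whole stack end to end — preset calibration against the image
pipeline, cohort generation at the study's group sizes, per-eye rendering
and measurement, and the downstream statistics — and reports the recovered
group means, correlation, AUC and risk odds ratios.  Used by the
acceptance script and the acceptance test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.random import default_rng

from .cohort import (
    CalibratedPreset,
    CohortConfig,
    DEFAULT_PRESETS,
    calibrate_preset,
    generate_cohort,
    generate_risk_dataset,
)
from .pipeline import PipelineConfig, make_cc_pipeline, run_image_cohort
from .stats import fit_logistic, pearson_r, roc_auc

__all__ = [
    "calibrate_default_presets",
    "recover_group_image_means",
    "recover_pros_mean",
    "recover_pooled_correlation",
    "recover_logistic_or",
    "recover_preset_auc",
]


def calibrate_default_presets(
    seed: int = 1,
    config: PipelineConfig | None = None,
    tol: float = 0.5,
    cv_tol: float = 0.01,
    n_eyes: int = 20,
) -> dict[str, CalibratedPreset]:
    """Calibrate all three group presets against the full image pipeline."""
    config = config or PipelineConfig()
    handle = make_cc_pipeline(config)
    return {
        name: calibrate_preset(preset, handle, tol=tol, cv_tol=cv_tol, seed=seed, n_eyes=n_eyes)
        for name, preset in DEFAULT_PRESETS.items()
    }


def cohort_seeds(seed: int, n_cohorts: int = 10) -> list[int]:
    """Spaced base seeds so the per-eye streams of repeated cohorts are
    disjoint (per-eye seed = base + eye index)."""
    return [seed + 1000 * k for k in range(n_cohorts)]


def recover_group_image_means(
    calibrated: dict[str, CalibratedPreset],
    seeds,
    config: PipelineConfig | None = None,
    measure_vld: bool = True,
) -> pd.DataFrame:
    """Grand group means of measured CCFA, CV (and VLD) over repeated cohorts.

    One cohort at the study's 12/15/18 group sizes is generated per seed;
    every eye goes through simulate -> magnification-correct -> binarize ->
    measure (and superficial-slab VLD estimation when requested).
    """
    config = config or PipelineConfig()
    frames = []
    for s in seeds:
        cohort = generate_cohort(CohortConfig(base_seed=int(s)))
        frames.append(
            run_image_cohort(cohort, calibrated, config, base_seed=int(s), measure_vld=measure_vld)
        )
    allm = pd.concat(frames, ignore_index=True)
    cols = ["ccfa_ratio", "cv_ccfa"] + (["vld"] if measure_vld else [])
    return allm.groupby("group")[cols].mean()


def recover_pros_mean(seeds, group: str = "control") -> float:
    """Grand mean PROS length of one group's tabular channel over cohorts."""
    vals = []
    for s in seeds:
        cohort = generate_cohort(CohortConfig(base_seed=int(s)))
        vals.append(cohort.loc[cohort["group"] == group, "pros_length"].mean())
    return float(np.mean(vals))


def recover_pooled_correlation(
    calibrated: dict[str, CalibratedPreset],
    n_per_group: int = 150,
    seed: int = 42,
    config: PipelineConfig | None = None,
) -> tuple[float, int]:
    """Pearson r between measured CCFA and measured VLD on one pooled cohort."""
    config = config or PipelineConfig()
    cohort = generate_cohort(
        CohortConfig(n_per_group=(n_per_group,) * 3, base_seed=seed)
    )
    metrics = run_image_cohort(cohort, calibrated, config, base_seed=seed, measure_vld=True)
    sub = metrics[["ccfa_ratio", "vld"]].dropna()
    r, _ = pearson_r(sub["ccfa_ratio"], sub["vld"])
    return float(r), int(len(sub))


def recover_logistic_or(
    exposure: str = "hba1c", n: int = 5000, seed: int = 7, replicates: int = 5
) -> float:
    """Age-adjusted logistic OR of impaired flow on an exceedance exposure,
    recovered from synthetic risk datasets at the default association.

    The estimator is unbiased but a single n=5000 draw carries ~10%
    Monte-Carlo noise on the OR, so the log-OR is averaged over independent
    replicate datasets (geometric mean of the ORs).
    """
    logs = []
    for k in range(replicates):
        data = generate_risk_dataset(n, seed=seed + 1000 * k)
        X = pd.DataFrame(
            {exposure: data[f"{exposure}_exceed"].astype(float), "age": data["age"]}
        )
        fits = fit_logistic(data["impaired"].to_numpy(dtype=bool), X)
        logs.append(np.log(fits[0].odds_ratio))
    return float(np.exp(np.mean(logs)))


def recover_preset_auc(n_per_class: int = 20000, seed: int = 3) -> float:
    """AUC for control vs pooled-diabetic CCFA under the preset normals.

    Diabetic values come from the 15:18 mixture of the dm_no_dr and dr
    preset normals; low CCFA flags diabetes.
    """
    rng = default_rng(seed)
    ctl = DEFAULT_PRESETS["control"]
    dm, dr = DEFAULT_PRESETS["dm_no_dr"], DEFAULT_PRESETS["dr"]
    control = rng.normal(ctl.target_ccfa_mean, ctl.target_ccfa_sd, n_per_class)
    from_dm = rng.random(n_per_class) < 15 / 33
    diabetic = np.where(
        from_dm,
        rng.normal(dm.target_ccfa_mean, dm.target_ccfa_sd, n_per_class),
        rng.normal(dr.target_ccfa_mean, dr.target_ccfa_sd, n_per_class),
    )
    values = np.concatenate([control, diabetic])
    labels = np.concatenate(
        [np.zeros(n_per_class, dtype=bool), np.ones(n_per_class, dtype=bool)]
    )
    return float(roc_auc(values, labels, direction="low").auc)
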