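"""End-to-end helpers: simulate an eye, run the measurement chain, batch cohorts.

The per-eye chain for the choriocapillaris slab is
simulate -> magnification-correct and crop to 2.7 mm -> Phansalkar
binarize -> CCFA ratio / tile CV / impaired flag; the superficial slab is
measured on the nominal scan area (no axial-length correction, matching
device behaviour).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import CalibratedPreset, calibrate_preset, GroupPreset
from .flow import (
    DEFAULT_IMPAIRED_CUTOFFS,
    PhansalkarParams,
    binarize_flow,
    compute_flow_metrics,
)
from .preprocess import EyeExcludedError, ScanGeometry, correct_and_crop
from .simulate import CcSlabStyle, SuperficialStyle, simulate_cc_slab, simulate_superficial_slab
from .vld import vld

__all__ = ["PipelineConfig", "measure_cc_eye", "measure_superficial_eye",
           "make_cc_pipeline", "calibrate_all_presets", "run_image_cohort"]


@dataclass(frozen=True)
class PipelineConfig:
    """Imaging/measurement settings shared by calibration and cohort runs."""

    side_px: int = 512
    scan_size_mm: float = 3.0
    crop_size_mm: float = 2.7
    assumed_axial_length: float = 24.46
    grid: int = 18
    phansalkar: PhansalkarParams = field(default_factory=PhansalkarParams)
    cc_style: CcSlabStyle = field(default_factory=CcSlabStyle)
    sup_style: SuperficialStyle = field(default_factory=SuperficialStyle)
    cutoffs: tuple[float, float] = DEFAULT_IMPAIRED_CUTOFFS

    @property
    def pixel_size(self) -> float:
        return self.scan_size_mm / self.side_px


def measure_cc_eye(
    void_param: float,
    heterogeneity_param: float,
    seed: int,
    config: PipelineConfig | None = None,
    axial_length: Optional[float] = None,
) -> tuple[float, float]:
    """Simulate one choriocapillaris slab and measure (CCFA %, tile CV)."""
    config = config or PipelineConfig()
    al = config.assumed_axial_length if axial_length is None else axial_length
    image, _ = simulate_cc_slab(
        void_param,
        heterogeneity_param,
        side_px=config.side_px,
        pixel_size=config.pixel_size,
        seed=seed,
        style=config.cc_style,
    )
    geometry = ScanGeometry(
        axial_length=al,
        assumed_axial_length=config.assumed_axial_length,
        nominal_scan_size=config.scan_size_mm,
        pixel_size=config.pixel_size,
    )
    cropped = correct_and_crop(image, geometry, config.crop_size_mm)
    mask = binarize_flow(cropped.pixels, config.phansalkar, pixel_size=cropped.pixel_size)
    metrics = compute_flow_metrics(mask, grid=config.grid, cutoffs=config.cutoffs)
    return metrics.ccfa_ratio, metrics.cv_ccfa


def measure_superficial_eye(
    target_vld: float, seed: int, config: PipelineConfig | None = None
) -> float:
    """Simulate one superficial slab at a target density and estimate VLD."""
    config = config or PipelineConfig()
    image, _ = simulate_superficial_slab(
        target_vld,
        side_px=config.side_px,
        pixel_size=config.pixel_size,
        seed=seed,
        style=config.sup_style,
    )
    return vld(image).vld


def make_cc_pipeline(config: PipelineConfig | None = None):
    """Pipeline handle for :func:`choriflow.cohort.calibrate_preset`."""
    config = config or PipelineConfig()

    def handle(void_param: float, heterogeneity_param: float, seed: int):
        return measure_cc_eye(void_param, heterogeneity_param, seed, config)

    return handle


def calibrate_all_presets(
    presets: dict[str, GroupPreset],
    config: PipelineConfig | None = None,
    tol: float = 0.5,
    cv_tol: float = 0.01,
    seed: int = 1,
    n_eyes: int = 20,
) -> dict[str, CalibratedPreset]:
    handle = make_cc_pipeline(config)
    return {
        name: calibrate_preset(
            preset, handle, tol=tol, cv_tol=cv_tol, seed=seed, n_eyes=n_eyes
        )
        for name, preset in presets.items()
    }


def run_image_cohort(
    cohort: pd.DataFrame,
    calibrated: dict[str, CalibratedPreset],
    config: PipelineConfig | None = None,
    base_seed: int = 0,
    measure_vld: bool = True,
) -> pd.DataFrame:
    """Run the full image pipeline for every eye of a cohort table.

    Each eye's simulator controls come from its group's calibrated preset
    mapped through the per-eye (target_ccfa, target_cv) draw; the
    superficial slab is generated at the eye's target VLD.  Returns one
    metrics row per eye (excluded eyes carry the exclusion code and NaNs).
    """
    config = config or PipelineConfig()
    rows = []
    for i, rec in cohort.reset_index(drop=True).iterrows():
        cal = calibrated[rec["group"]]
        v, h = cal.controls_for(rec["target_ccfa"], rec["target_cv"])
        seed = int(base_seed + 10_000 + i)
        row = {"eye_id": rec["eye_id"], "group": rec["group"]}
        try:
            al = float(rec.get("axial_length", config.assumed_axial_length))
            ccfa, cv = measure_cc_eye(v, h, seed, config, axial_length=al)
            row.update(ccfa_ratio=ccfa, cv_ccfa=cv, exclusion=None)
            row["impaired"] = bool(
                ccfa < config.cutoffs[0] and cv is not None and cv >= config.cutoffs[1]
            )
        except EyeExcludedError as err:
            row.update(ccfa_ratio=np.nan, cv_ccfa=np.nan, impaired=None, exclusion=err.code)
        if measure_vld:
            row["vld"] = measure_superficial_eye(float(rec["target_vld"]), seed + 5000, config)
        rows.append(row)
    return pd.DataFrame(rows)
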