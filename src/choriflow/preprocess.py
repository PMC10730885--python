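"""Magnification correction, analysis-area cropping and quality filtering.

OCTA scan dimensions are nominal for an assumed eye; the true lateral
scale of an individual eye depends on its axial length.  The
Littmann-Bennett relation gives the true size of a fundus feature as
``t = p * q * s`` with ``q = 0.01306 * (AL - 1.82)``; relative to the
device's assumed axial length the constant cancels and the correction is
the pure ratio ``(AL - 1.82) / (AL_assumed - 1.82)``.

Correction here is a metadata rescale (the pixel grid is untouched), after
which a centered crop takes the common analyzed extent (2.7 x 2.7 mm for
the choriocapillaris slab).  Eyes whose corrected scan is smaller than the
crop, or whose signal quality index is not above 7, are excluded with an
explicit reason code.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .simulate import EnFaceImage

__all__ = [
    "ScanGeometry",
    "EyeExcludedError",
    "bennett_scale_factor",
    "correct_and_crop",
    "quality_filter",
]

#: Axial position of the eye's second nodal plane in Bennett's schematic eye (mm).
BENNETT_OFFSET_MM = 1.82
#: Device default axial length (mm), configurable per ScanGeometry.
DEFAULT_ASSUMED_AXIAL_LENGTH = 24.46


@dataclass(frozen=True)
class ScanGeometry:
    """Per-eye scan geometry: axial length and nominal scan scale."""

    axial_length: float
    assumed_axial_length: float = DEFAULT_ASSUMED_AXIAL_LENGTH
    nominal_scan_size: float = 3.0  # mm
    pixel_size: float = 3.0 / 512  # mm / pixel, nominal

    def __post_init__(self) -> None:
        if not (15.0 < self.axial_length < 27.0):
            raise ValueError(
                f"axial_length must be in (15, 27) mm, got {self.axial_length}"
            )
        if self.assumed_axial_length <= BENNETT_OFFSET_MM:
            raise ValueError("assumed_axial_length must exceed 1.82 mm")


class EyeExcludedError(Exception):
    """Raised when an eye fails an inclusion rule; carries a reason code."""

    def __init__(self, code: str, detail: str = ""):
        self.code = code
        super().__init__(f"{code}: {detail}" if detail else code)


def bennett_scale_factor(
    axial_length: float,
    assumed_axial_length: float = DEFAULT_ASSUMED_AXIAL_LENGTH,
) -> float:
    """Littmann-Bennett magnification ratio relative to the assumed eye.

    factor = (AL - 1.82) / (AL_assumed - 1.82); the 0.01306 constant of
    q = 0.01306 (AL - 1.82) cancels in the ratio.  Strictly increasing in
    AL and exactly 1 at the assumed axial length.
    """
    if axial_length <= BENNETT_OFFSET_MM or assumed_axial_length <= BENNETT_OFFSET_MM:
        raise ValueError("axial lengths must exceed 1.82 mm (Bennett nodal offset)")
    return (axial_length - BENNETT_OFFSET_MM) / (assumed_axial_length - BENNETT_OFFSET_MM)


def correct_and_crop(
    image: EnFaceImage,
    geometry: ScanGeometry,
    crop_size_mm: float = 2.7,
) -> EnFaceImage:
    """Rescale pixel size by the Bennett factor, then center-crop to crop_size_mm.

    The crop side in pixels floors to an integer; the exact physical size
    achieved is recorded in the returned image's metadata.  Raises
    :class:`EyeExcludedError` (code ``corrected_width_below_crop``) when the
    corrected scan does not cover the requested analysis area.
    """
    factor = bennett_scale_factor(geometry.axial_length, geometry.assumed_axial_length)
    pixel_mm = geometry.pixel_size * factor
    side = image.pixels.shape[0]
    corrected_width = side * pixel_mm
    # one-pixel tolerance keeps the crop idempotent despite flooring
    if corrected_width < crop_size_mm - pixel_mm:
        raise EyeExcludedError(
            "corrected_width_below_crop",
            f"corrected width {corrected_width:.4f} mm < crop {crop_size_mm} mm "
            f"(AL {geometry.axial_length} mm, factor {factor:.5f})",
        )
    crop_px = int(np.floor(crop_size_mm / pixel_mm))
    crop_px = min(crop_px, side)
    r0 = (side - crop_px) // 2
    c0 = (image.pixels.shape[1] - crop_px) // 2
    return EnFaceImage(
        pixels=image.pixels[r0 : r0 + crop_px, c0 : c0 + crop_px],
        pixel_size=pixel_mm,
        nominal_scan_size=image.nominal_scan_size,
        modality=image.modality,
        meta={
            **image.meta,
            "bennett_factor": factor,
            "crop_size_mm_requested": crop_size_mm,
            "crop_size_mm_actual": crop_px * pixel_mm,
        },
    )


def quality_filter(
    records: pd.DataFrame, column: str = "quality_index", id_column: str = "eye_id"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep eyes with quality index strictly greater than 7.

    Returns (included, exclusion_log); the log has one (eye_id, reason) row
    per excluded eye, with a missing index logged distinctly from a low one.
    """
    if column not in records.columns:
        raise KeyError(f"records lack a {column!r} column")
    qi = pd.to_numeric(records[column], errors="coerce")
    missing = qi.isna()
    low = ~missing & (qi <= 7)
    keep = ~missing & (qi > 7)
    log = pd.DataFrame(
        {
            id_column: records.loc[missing | low, id_column],
            "reason": np.where(
                missing[missing | low], "missing_quality_index", "quality_index_le_7"
            ),
        }
    ).reset_index(drop=True)
    return records.loc[keep].reset_index(drop=True), log
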