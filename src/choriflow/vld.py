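"""Superficial retinal vessel length density (VLD).

VLD is the total length of perfused vasculature per unit area (mm/mm^2).
The estimator mirrors what OCTA device software reports from the
superficial capillary plexus: segment the vessels, thin to a one-pixel
skeleton, and sum centerline length over the analyzed area.  Measurement
is done on the nominal scan area without axial-length correction, matching
common device behaviour.

Skeleton length uses step-weighted adjacency — each 4-neighbour pixel pair
contributes one pixel size, each diagonal pair sqrt(2) pixel sizes, every
adjacent pair counted once — rather than a raw pixel count, which would
understate diagonal vessels by up to 41%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import remove_small_objects, skeletonize

from .simulate import EnFaceImage

__all__ = ["VldResult", "segment_vessels", "skeleton_length_mm", "vld"]


@dataclass
class VldResult:
    vessel_length: float  # mm
    area: float  # mm^2
    vld: float  # mm / mm^2
    skeleton: np.ndarray
    vessel_mask: np.ndarray


def segment_vessels(
    image: np.ndarray, dark_vessels: bool = False, min_size: int = 3
) -> np.ndarray:
    """Global Otsu segmentation on a background-flattened image.

    The low-frequency background (Gaussian at 1/8 of the image side) is
    subtracted before thresholding so slow illumination drifts do not bias
    the global cut.  Specks below ``min_size`` pixels are removed.  A blank
    (constant) image yields an empty mask, not an error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if dark_vessels:
        img = img.max() - img
    flat = img - gaussian(img, sigma=img.shape[0] / 8.0, preserve_range=True)
    if np.ptp(flat) == 0:
        return np.zeros_like(img, dtype=bool)
    mask = flat > threshold_otsu(flat)
    return remove_small_objects(mask, max_size=min_size - 1)


def skeleton_length_mm(mask: np.ndarray, pixel_size: float) -> float:
    """Centerline length of a binary mask after thinning, in mm.

    The mask is thinned to a 1-px skeleton; length is the step-weighted sum
    over skeleton adjacencies (orthogonal step = pixel_size, diagonal step
    = sqrt(2) * pixel_size).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    return _step_length(skeletonize(mask), pixel_size)


def _step_length(sk: np.ndarray, pixel_size: float) -> float:
    horiz = np.count_nonzero(sk[:, 1:] & sk[:, :-1])
    vert = np.count_nonzero(sk[1:, :] & sk[:-1, :])
    diag1 = np.count_nonzero(sk[1:, 1:] & sk[:-1, :-1])
    diag2 = np.count_nonzero(sk[1:, :-1] & sk[:-1, 1:])
    return ((horiz + vert) + math.sqrt(2.0) * (diag1 + diag2)) * pixel_size


def vld(image: EnFaceImage | np.ndarray, pixel_size: float | None = None, **kw) -> VldResult:
    """Segment, skeletonize and report vessel length per analyzed area."""
    if isinstance(image, EnFaceImage):
        pixels = image.pixels
        pixel_size = image.pixel_size if pixel_size is None else pixel_size
    else:
        pixels = np.asarray(image, dtype=float)
        if pixel_size is None:
            raise ValueError("pixel_size required when passing a bare array")
    mask = segment_vessels(pixels, **kw)
    sk = skeletonize(mask) if mask.any() else np.zeros_like(mask)
    length = _step_length(sk, pixel_size)
    area = pixels.shape[0] * pixels.shape[1] * pixel_size * pixel_size
    return VldResult(
        vessel_length=length,
        area=area,
        vld=length / area,
        skeleton=sk,
        vessel_mask=mask,
    )
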