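"""Synthetic en-face OCTA rendering with exported ground truth.

Two slabs are modelled:

* a choriocapillaris slab — a bright perfused texture organized in
  ~200-250 um hexagonal lobules, on which dark flow voids (unions of
  random ellipses on the 20-120 um scale) are placed by a spatially
  heterogeneous point process until a target coverage fraction is reached;
* a superficial retinal slab — a branching vessel network grown segment by
  segment until its centerline length per unit area reaches a target
  vessel length density, then dilated to capillary calibre.

Both carry a :class:`SceneTruth` sidecar: the exact void mask / flow
fraction, the heterogeneity field, and (superficial) the exact centerline
length, so downstream estimators can be validated pixel-for-pixel.

Controls relevant to calibration:

* ``void_param`` in [0, 1] — the target void *coverage fraction*; the
  renderer keeps adding voids until the mask reaches it, so
  ``true_flow_fraction = 1 - void_param`` up to one ellipse of granularity.
* ``heterogeneity_param`` >= 0 — amplitude of the log-Gaussian random field
  (smoothed at the ~300 um scale, normalized to mean 1) that modulates the
  local void rate.  0 gives spatially homogeneous voids; larger values
  cluster voids and raise the tile-CV without changing total coverage.

Speckle is multiplicative log-normal, mean-preserving before clipping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.random import Generator, default_rng
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import line as draw_line
from skimage.morphology import disk

__all__ = [
    "EnFaceImage",
    "SceneTruth",
    "CcSlabStyle",
    "SuperficialStyle",
    "add_speckle",
    "simulate_cc_slab",
    "simulate_superficial_slab",
]


@dataclass
class EnFaceImage:
    """Square grayscale en-face slab with physical scale metadata."""

    pixels: np.ndarray  # float in [0, 1]
    pixel_size: float  # mm / pixel (isotropic)
    nominal_scan_size: float = 3.0  # mm
    modality: str = "cc_slab"  # or "superficial_slab"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("EnFaceImage requires a 2-D pixel grid")


@dataclass
class SceneTruth:
    """Generator-side ground truth for a rendered slab."""

    true_flow_fraction: float
    void_mask: Optional[np.ndarray] = None
    heterogeneity_field: Optional[np.ndarray] = None
    lobule_diameter_um: float = 225.0
    vessel_centerline_length_mm: Optional[float] = None
    centerline_mask: Optional[np.ndarray] = None


@dataclass(frozen=True)
class CcSlabStyle:
    """Appearance knobs of the choriocapillaris renderer (not calibrated)."""

    baseline: float = 0.80  # perfused-texture intensity
    void_level: float = 0.06  # intensity inside a flow void
    border_dip: float = 0.12  # relative darkening at lobule borders
    border_width_px: float = 1.6
    lobule_diameter_um: float = 225.0  # mid of the 200-250 um domain scale
    lobule_jitter: float = 0.12  # center jitter, fraction of spacing
    void_axis_um: tuple[float, float] = (10.0, 45.0)  # full-axis range of void ellipses
    heterogeneity_scale_um: float = 300.0
    speckle_sigma: float = 0.15


@dataclass(frozen=True)
class SuperficialStyle:
    """Appearance/growth knobs of the superficial-plexus renderer."""

    vessel_intensity: float = 0.85
    background: float = 0.12
    calibre_radius_px: int = 1  # dilation radius; ~3 px vessel width
    step_px: float = 14.0  # growth-segment length
    turn_sd_rad: float = 0.25  # direction jitter per step
    branch_prob: float = 0.14  # per step
    branch_angle_rad: tuple[float, float] = (0.6, 1.1)
    n_tips: int = 10
    speckle_sigma: float = 0.15


def add_speckle(image: np.ndarray, sigma: float, seed: int | Generator = 0) -> np.ndarray:
    """Multiplicative log-normal speckle; mean-preserving before clipping.

    The multiplier is exp(N(-sigma^2/2, sigma^2)) so E[multiplier] = 1.
    sigma = 0 returns the input unchanged.  No clipping is applied here;
    callers clip after compositing.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    image = np.asarray(image, dtype=float)
    if sigma == 0:
        return image.copy()
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    noise = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=image.shape))
    return image * noise


def _hex_lobule_texture(
    side_px: int, pixel_um: float, style: CcSlabStyle, rng: Generator
) -> np.ndarray:
    """Bright baseline modulated by darker borders of a jittered hex lattice."""
    spacing = style.lobule_diameter_um / pixel_um
    dy = spacing * math.sqrt(3.0) / 2.0
    margin = 2.0 * spacing
    centers = []
    row = 0
    y = -margin
    while y < side_px + margin:
        x0 = -margin + (spacing / 2.0 if row % 2 else 0.0)
        x = x0
        while x < side_px + margin:
            centers.append((y, x))
            x += spacing
        y += dy
        row += 1
    centers = np.asarray(centers)
    centers += rng.normal(0.0, style.lobule_jitter * spacing, size=centers.shape)
    tree = cKDTree(centers)
    # evaluate on a quarter-resolution grid; borders are soft texture, not truth
    step = 4
    yy, xx = np.meshgrid(
        np.arange(0, side_px, step, dtype=float),
        np.arange(0, side_px, step, dtype=float),
        indexing="ij",
    )
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    d, _ = tree.query(pts, k=2)
    borderness = np.exp(-(((d[:, 1] - d[:, 0]) / style.border_width_px) ** 2))
    coarse = style.baseline * (1.0 - style.border_dip * borderness)
    coarse = coarse.reshape(yy.shape)
    tex = ndimage.zoom(coarse, step, order=1)
    return tex[:side_px, :side_px]


def _heterogeneity_field(
    side_px: int, pixel_um: float, amplitude: float, style: CcSlabStyle, rng: Generator
) -> np.ndarray:
    """Smooth positive rate field with mean 1: exp of blurred white noise."""
    # quarter-resolution evaluation: the field only varies on the ~300 um scale
    step = 4
    n = -(-side_px // step)
    g = rng.standard_normal((n, n))
    sigma_px = style.heterogeneity_scale_um / pixel_um / step
    g = ndimage.gaussian_filter(g, sigma=sigma_px, mode="reflect")
    sd = g.std()
    if sd > 0:
        g /= sd
    f = np.exp(amplitude * ndimage.zoom(g, step, order=1)[:side_px, :side_px])
    return f / f.mean()


def _ellipse_stamp(a: float, b: float, phi: float) -> np.ndarray:
    """Boolean stamp of an ellipse with semi-axes a, b (px) rotated by phi."""
    r = int(math.ceil(max(a, b))) + 1
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    c, s = math.cos(phi), math.sin(phi)
    u = (xx * c + yy * s) / a
    v = (-xx * s + yy * c) / b
    return (u * u + v * v) <= 1.0


def _paint_stamp(mask: np.ndarray, stamp: np.ndarray, cy: int, cx: int) -> int:
    """OR a stamp into the mask centered at (cy, cx); return newly set count."""
    r = stamp.shape[0] // 2
    y0, y1 = cy - r, cy + r + 1
    x0, x1 = cx - r, cx + r + 1
    sy0, sx0 = max(0, -y0), max(0, -x0)
    y0, x0 = max(0, y0), max(0, x0)
    y1, x1 = min(mask.shape[0], y1), min(mask.shape[1], x1)
    if y0 >= y1 or x0 >= x1:
        return 0
    sub = mask[y0:y1, x0:x1]
    st = stamp[sy0 : sy0 + (y1 - y0), sx0 : sx0 + (x1 - x0)]
    new = int(np.count_nonzero(st & ~sub))
    sub |= st
    return new


def simulate_cc_slab(
    void_param: float,
    heterogeneity_param: float,
    side_px: int = 512,
    pixel_size: float = 3.0 / 512,
    seed: int = 0,
    style: CcSlabStyle | None = None,
    speckle_sigma: float | None = None,
) -> tuple[EnFaceImage, SceneTruth]:
    """Render a choriocapillaris slab with controllable void coverage/clustering.

    Parameters
    ----------
    void_param
        Target void coverage fraction in [0, 1]; ellipses are added until
        the void mask reaches it.
    heterogeneity_param
        Amplitude of the log-Gaussian field modulating local void rate.
    speckle_sigma
        Overrides the style's speckle amplitude; pass 0 for noise-free.
    """
    if side_px < 128:
        raise ValueError(f"side_px must be >= 128, got {side_px}")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if not (0.0 <= void_param <= 1.0):
        raise ValueError(f"void_param must lie in [0, 1], got {void_param}")
    if heterogeneity_param < 0:
        raise ValueError("heterogeneity_param must be >= 0")
    style = style or CcSlabStyle()
    sigma = style.speckle_sigma if speckle_sigma is None else speckle_sigma
    rng = default_rng(seed)
    pixel_um = pixel_size * 1000.0

    texture = _hex_lobule_texture(side_px, pixel_um, style, rng)
    het = _heterogeneity_field(side_px, pixel_um, heterogeneity_param, style, rng)

    void = np.zeros((side_px, side_px), dtype=bool)
    n_total = side_px * side_px
    target_px = int(round(void_param * n_total))
    if target_px > 0:
        cdf = np.cumsum(het.ravel())
        cdf /= cdf[-1]
        lo_ax, hi_ax = style.void_axis_um
        # pool of pre-rendered void stamps reused across placements
        pool = [
            _ellipse_stamp(
                rng.uniform(lo_ax, hi_ax) / 2.0 / pixel_um,
                rng.uniform(lo_ax, hi_ax) / 2.0 / pixel_um,
                rng.uniform(0.0, math.pi),
            )
            for _ in range(64)
        ]
        small = [
            _ellipse_stamp(
                rng.uniform(lo_ax, lo_ax * 1.4) / 2.0 / pixel_um,
                rng.uniform(lo_ax, lo_ax * 1.4) / 2.0 / pixel_um,
                rng.uniform(0.0, math.pi),
            )
            for _ in range(16)
        ]
        covered = 0
        batch = 64
        stalled = 0
        while covered < target_px:
            # shrink voids near the end to land close to the target coverage
            use = pool if target_px - covered > 400 else small
            u = rng.random(batch)
            idx = np.searchsorted(cdf, u)
            cys, cxs = np.unravel_index(idx, het.shape)
            which = rng.integers(len(use), size=batch)
            before = covered
            for j in range(batch):
                covered += _paint_stamp(void, use[which[j]], int(cys[j]), int(cxs[j]))
                if covered >= target_px:
                    break
            # near-total coverage: random blobs stop finding unset pixels
            # (coupon-collector regime); place the last few directly
            if covered - before < batch // 8:
                stalled += 1
                if stalled >= 3:
                    free = np.flatnonzero(~void.ravel())
                    take = rng.choice(free, size=target_px - covered, replace=False)
                    void.ravel()[take] = True
                    covered = target_px

    image = np.where(void, style.void_level, texture)
    image = add_speckle(image, sigma, rng)
    np.clip(image, 0.0, 1.0, out=image)

    truth = SceneTruth(
        true_flow_fraction=1.0 - float(np.count_nonzero(void)) / n_total,
        void_mask=void,
        heterogeneity_field=het,
        lobule_diameter_um=style.lobule_diameter_um,
    )
    en_face = EnFaceImage(
        pixels=image,
        pixel_size=pixel_size,
        nominal_scan_size=side_px * pixel_size,
        modality="cc_slab",
        meta={"seed": seed, "void_param": void_param, "heterogeneity_param": heterogeneity_param},
    )
    return en_face, truth


def simulate_superficial_slab(
    target_vld: float,
    side_px: int = 512,
    pixel_size: float = 3.0 / 512,
    seed: int = 0,
    style: SuperficialStyle | None = None,
    speckle_sigma: float | None = None,
) -> tuple[EnFaceImage, SceneTruth]:
    """Render a superficial-plexus slab with known total centerline length.

    Vessels grow as a branching random walk: each active tip advances by a
    fixed step with angular jitter and may spawn a branch; tips leaving the
    field are replaced.  Growth stops when total centerline length per
    image area reaches ``target_vld`` (mm/mm^2); the final segment is
    trimmed so the recorded ground-truth density is exact.
    """
    if not (0.0 < target_vld <= 40.0):
        raise ValueError(f"target_vld must be in (0, 40], got {target_vld}")
    if side_px < 128:
        raise ValueError(f"side_px must be >= 128, got {side_px}")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    style = style or SuperficialStyle()
    sigma = style.speckle_sigma if speckle_sigma is None else speckle_sigma
    rng = default_rng(seed)

    area_mm2 = (side_px * pixel_size) ** 2
    target_len_mm = target_vld * area_mm2
    step_mm = style.step_px * pixel_size

    centerline = np.zeros((side_px, side_px), dtype=bool)
    tips: list[tuple[float, float, float]] = []

    def new_tip() -> tuple[float, float, float]:
        return (
            rng.uniform(0, side_px - 1),
            rng.uniform(0, side_px - 1),
            rng.uniform(0, 2 * math.pi),
        )

    for _ in range(style.n_tips):
        tips.append(new_tip())

    def draw_segment(y0: float, x0: float, y1: float, x1: float) -> None:
        rr, cc = draw_line(
            int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1))
        )
        ok = (rr >= 0) & (rr < side_px) & (cc >= 0) & (cc < side_px)
        centerline[rr[ok], cc[ok]] = True

    total_mm = 0.0
    max_steps = int(4e6)  # hard stop; saturation check below fires first
    steps = 0
    while total_mm < target_len_mm:
        steps += 1
        if steps > max_steps or (
            steps % 2000 == 0 and centerline.mean() > 0.9
        ):
            raise RuntimeError(
                "vessel field saturated before reaching target density; "
                f"achieved {total_mm / area_mm2:.2f} mm/mm^2 of {target_vld}"
            )
        i = int(rng.integers(len(tips)))
        y, x, theta = tips[i]
        theta += rng.normal(0.0, style.turn_sd_rad)
        seg_mm = min(step_mm, target_len_mm - total_mm)
        seg_px = seg_mm / pixel_size
        y1 = y + seg_px * math.sin(theta)
        x1 = x + seg_px * math.cos(theta)
        draw_segment(y, x, y1, x1)
        total_mm += seg_mm
        if not (0 <= y1 < side_px and 0 <= x1 < side_px):
            tips[i] = new_tip()
        else:
            tips[i] = (y1, x1, theta)
            if rng.random() < style.branch_prob:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                ang = rng.uniform(*style.branch_angle_rad)
                tips.append((y1, x1, theta + sign * ang))
                if len(tips) > 4 * style.n_tips:
                    tips.pop(int(rng.integers(len(tips))))

    vessel = ndimage.binary_dilation(centerline, structure=disk(style.calibre_radius_px))
    image = np.where(vessel, style.vessel_intensity, style.background)
    image = add_speckle(image, sigma, rng)
    np.clip(image, 0.0, 1.0, out=image)

    truth = SceneTruth(
        true_flow_fraction=float(vessel.mean()),
        void_mask=~vessel,
        vessel_centerline_length_mm=total_mm,
        centerline_mask=centerline,
    )
    en_face = EnFaceImage(
        pixels=image,
        pixel_size=pixel_size,
        nominal_scan_size=side_px * pixel_size,
        modality="superficial_slab",
        meta={"seed": seed, "target_vld": target_vld},
    )
    return en_face, truth
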