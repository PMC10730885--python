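"""Disk round-trips: en-face slabs as TIFF/PNG, ground truth as JSON sidecars.

Images are written 16-bit TIFF by default (8-bit PNG on request), scaled
from the [0, 1] float range; files are named ``{eye_id}_{modality}.tif``.
The SceneTruth sidecar stores scalars in JSON next to a TIFF of the void
mask so truth survives the round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .simulate import EnFaceImage, SceneTruth

__all__ = ["write_image", "read_image", "write_truth", "read_truth"]


def write_image(image: EnFaceImage, directory: str | Path, eye_id: str,
                fmt: str = "tiff") -> Path:
    """Write a slab as ``{eye_id}_{modality}.tif`` (16-bit) or ``.png`` (8-bit)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pixels = np.clip(image.pixels, 0.0, 1.0)
    if fmt == "tiff":
        path = directory / f"{eye_id}_{image.modality}.tif"
        tifffile.imwrite(path, (pixels * 65535).round().astype(np.uint16))
    elif fmt == "png":
        from imageio.v3 import imwrite

        path = directory / f"{eye_id}_{image.modality}.png"
        imwrite(path, (pixels * 255).round().astype(np.uint8))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    meta = {
        "pixel_size": image.pixel_size,
        "nominal_scan_size": image.nominal_scan_size,
        "modality": image.modality,
        **{k: v for k, v in image.meta.items() if isinstance(v, (int, float, str))},
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def read_image(path: str | Path) -> EnFaceImage:
    """Read a slab written by :func:`write_image`, restoring [0, 1] floats."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path).astype(float) / 65535.0
    else:
        from imageio.v3 import imread

        arr = imread(path).astype(float) / 255.0
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return EnFaceImage(
        pixels=arr,
        pixel_size=float(meta.get("pixel_size", 3.0 / arr.shape[0])),
        nominal_scan_size=float(meta.get("nominal_scan_size", 3.0)),
        modality=meta.get("modality", "cc_slab"),
        meta=meta,
    )


def write_truth(truth: SceneTruth, directory: str | Path, eye_id: str) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{eye_id}_truth.json"
    payload = {
        "true_flow_fraction": truth.true_flow_fraction,
        "lobule_diameter_um": truth.lobule_diameter_um,
        "vessel_centerline_length_mm": truth.vessel_centerline_length_mm,
    }
    path.write_text(json.dumps(payload, indent=2))
    if truth.void_mask is not None:
        tifffile.imwrite(
            directory / f"{eye_id}_void_mask.tif", truth.void_mask.astype(np.uint8)
        )
    return path


def read_truth(path: str | Path) -> SceneTruth:
    path = Path(path)
    payload = json.loads(path.read_text())
    mask_path = path.with_name(path.name.replace("_truth.json", "_void_mask.tif"))
    void = tifffile.imread(mask_path).astype(bool) if mask_path.exists() else None
    return SceneTruth(
        true_flow_fraction=payload["true_flow_fraction"],
        void_mask=void,
        lobule_diameter_um=payload.get("lobule_diameter_um", 225.0),
        vessel_centerline_length_mm=payload.get("vessel_centerline_length_mm"),
    )
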