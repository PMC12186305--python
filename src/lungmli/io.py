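"""Image and mask readers/writers plus cohort manifests.

Masks live on disk as single-channel 8-bit PNG/TIFF with values {0, 255}
(255 = tissue) and in memory as {0, 1} uint8 arrays; images keep their
channel count.  Only 8-bit inputs are supported.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_cohort",
    "read_manifest",
]


class FormatError(ValueError):
    pass


_TIFF_SUFFIXES = {".tif", ".tiff"}


def _check_8bit(arr: np.ndarray, path) -> np.ndarray:
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: only 8-bit images are supported, got {arr.dtype}")
    return arr


def read_image(path) -> np.ndarray:
    """Read an 8-bit PNG/TIFF as (H, W) or (H, W, 3) uint8."""
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
    else:
        with Image.open(path) as im:
            if im.mode not in ("L", "RGB"):
                im = im.convert("RGB" if len(im.getbands()) >= 3 else "L")
            arr = np.asarray(im)
    return _check_8bit(np.asarray(arr), path)


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    image = _check_8bit(np.asarray(image), path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, image)
    else:
        Image.fromarray(image).save(path)


def read_mask(path) -> np.ndarray:
    """Read a binary mask: {0, 255} on disk -> {0, 1} uint8 in memory."""
    arr = read_image(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: masks must be single-channel")
    vals = np.unique(arr)
    if not np.isin(vals, (0, 255)).all():
        raise FormatError(f"{path}: mask values must be 0 or 255, got {vals[:5]}")
    return (arr > 0).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise FormatError("in-memory masks must contain only 0 and 1")
    write_image(path, (mask * 255).astype(np.uint8))


def write_cohort(cohort, out_dir) -> pd.DataFrame:
    """Write a synthetic cohort to disk and return its manifest.

    Images go to ``images/<sample_id>.png``, masks to
    ``masks/<sample_id>.png``, and the manifest CSV (sample_id, group,
    mouse_id, path_image, path_mask, seed) to ``manifest.csv``.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        img_path = out_dir / "images" / f"{s.sample_id}.png"
        mask_path = out_dir / "masks" / f"{s.sample_id}.png"
        write_image(img_path, s.image)
        write_mask(mask_path, s.truth_mask)
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "mouse_id": s.mouse_id,
                "path_image": str(img_path),
                "path_mask": str(mask_path),
                "seed": s.spec.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    required = {"sample_id", "group", "mouse_id", "path_image"}
    missing = required - set(manifest.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    return manifest
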