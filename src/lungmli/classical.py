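"""Threshold/morphology annotation of lung micrographs.

The six-step classical procedure that turns a raw micrograph into a binary
tissue/airspace mask: (1) greyscale conversion, (2) thresholding, (3) white
erosion, (4-5) two white dilations, (6) a final white erosion.  "White"
operations act on the bright airspace phase.  The package-wide class
convention is tissue = 1 (positive), background/airspace = 0.

This procedure serves double duty, as in the original pipeline: it creates
training annotations for the learned segmenter, and it is itself the
"classic segmentation" comparison arm of the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "MorphologyConfig",
    "to_grayscale",
    "binarize",
    "apply_morphology",
    "annotate",
    "GRAY_WEIGHTS",
]

#: ITU-R BT.601 luma weights used for greyscale conversion.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)

DEFAULT_STEPS = ("erode_white", "dilate_white", "dilate_white", "erode_white")


class UnsupportedFormatError(ValueError):
    pass


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class MorphologyConfig:
    """Threshold and morphology settings for the annotation procedure.

    The default step sequence is one white erosion, two white dilations and a
    final white erosion with a 3x3 square kernel; both the kernel and the
    per-step sequence are configurable because the published procedure fixes
    only the order of operations, not the kernel geometry.
    """

    threshold_mode: Literal["otsu", "fixed"] = "otsu"
    fixed_threshold: int = 128
    kernel_shape: Literal["square", "cross"] = "square"
    kernel_size: int = 3
    step_sequence: tuple[str, ...] = field(default=DEFAULT_STEPS)

    def __post_init__(self) -> None:
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise InvalidConfigError("kernel_size must be odd and >= 3")
        bad = set(self.step_sequence) - {"erode_white", "dilate_white"}
        if bad:
            raise InvalidConfigError(f"unknown morphology steps: {sorted(bad)}")

    def kernel(self) -> np.ndarray:
        k = self.kernel_size
        if self.kernel_shape == "square":
            return np.ones((k, k), dtype=bool)
        cross = np.zeros((k, k), dtype=bool)
        cross[k // 2, :] = True
        cross[:, k // 2] = True
        return cross


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a 3-channel 8-bit image to greyscale with BT.601 luma weights.

    Single-channel input passes through unchanged; achromatic input (all
    channels equal) maps to the shared channel value because the weights sum
    to 1.
    """
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 1:
        return image[:, :, 0]
    if image.ndim != 3 or image.shape[2] != 3:
        raise UnsupportedFormatError(
            f"expected 1- or 3-channel image, got shape {image.shape}"
        )
    w = np.asarray(GRAY_WEIGHTS)
    gray = image.astype(np.float64) @ w
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def binarize(gray: np.ndarray, config: MorphologyConfig | None = None) -> np.ndarray:
    """Threshold a greyscale image into tissue (1, dark) vs airspace (0, bright).

    Pixels at or above the threshold are labelled background (airspaces are
    bright); pixels below it are tissue.  In ``otsu`` mode the threshold is
    derived from the image histogram; a constant image has no histogram
    valley, so it falls back to an all-background mask with a warning.
    """
    config = config or MorphologyConfig()
    if gray.ndim != 2:
        raise UnsupportedFormatError("binarize expects a single-channel image")
    if config.threshold_mode == "fixed":
        thr = float(config.fixed_threshold)
    else:
        if gray.min() == gray.max():
            warnings.warn(
                "constant image: Otsu threshold undefined, returning all-background",
                stacklevel=2,
            )
            return np.zeros_like(gray, dtype=np.uint8)
        # threshold_otsu returns t with "foreground > t"; shift by 1/2 so the
        # ">= threshold is background" rule is unambiguous on integer images
        thr = float(threshold_otsu(gray)) + 0.5
    return (gray < thr).astype(np.uint8)


def _white_op(white: np.ndarray, op: str, kernel: np.ndarray) -> np.ndarray:
    # Border convention: values outside the image replicate the edge pixel.
    # Padding by the kernel radius with edge mode makes scipy's own border
    # value irrelevant for every original pixel.
    r = kernel.shape[0] // 2
    padded = np.pad(white, r, mode="edge")
    if op == "erode_white":
        out = ndimage.binary_erosion(padded, structure=kernel)
    else:
        out = ndimage.binary_dilation(padded, structure=kernel)
    return out[r:-r, r:-r]


def apply_morphology(mask: np.ndarray, config: MorphologyConfig | None = None) -> np.ndarray:
    """Run the configured erosion/dilation sequence on the white (airspace) phase.

    ``erode_white`` shrinks airspace regions (thickening tissue) and
    ``dilate_white`` grows them.  The default sequence is an opening of the
    white phase followed by its closing, which removes specks smaller than
    the kernel in either phase.
    """
    config = config or MorphologyConfig()
    kernel = config.kernel()
    if kernel.shape[0] > mask.shape[0] or kernel.shape[1] > mask.shape[1]:
        raise InvalidConfigError("kernel larger than image")
    if not np.isin(mask, (0, 1)).all():
        raise UnsupportedFormatError("mask must be binary {0,1}")
    white = mask == 0
    for step in config.step_sequence:
        white = _white_op(white, step, kernel)
    return (~white).astype(np.uint8)


def annotate(image: np.ndarray, config: MorphologyConfig | None = None) -> np.ndarray:
    """Full annotation procedure: greyscale -> threshold -> morphology."""
    config = config or MorphologyConfig()
    gray = to_grayscale(image)
    mask = binarize(gray, config)
    return apply_morphology(mask, config)
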