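"""Overlapping patch extraction and lossless stitching.

Full micrographs are split into square patches on a regular grid with a
stride of half the patch side by default, so every interior pixel is covered
by several tiles and no border information is lost.  Per-patch predictions
are stitched back by averaging overlapping values and cropping to the
original size, which reproduces the input exactly when the per-tile
transform is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PatchSet", "extract_patches", "stitch"]


class InvalidConfigError(ValueError):
    pass


class IncompletePatchSetError(ValueError):
    pass


@dataclass
class PatchSet:
    """Tiles plus the geometry needed to reassemble the full raster."""

    patches: list[tuple[np.ndarray, int, int]] = field(default_factory=list)
    patch_size: int = 352
    stride: int = 176
    padded_height: int = 0
    padded_width: int = 0
    original_height: int = 0
    original_width: int = 0

    def __len__(self) -> int:
        return len(self.patches)

    def map(self, fn) -> "PatchSet":
        """Apply ``fn`` to every tile, keeping offsets and geometry."""
        return PatchSet(
            patches=[(fn(t), r, c) for t, r, c in self.patches],
            patch_size=self.patch_size,
            stride=self.stride,
            padded_height=self.padded_height,
            padded_width=self.padded_width,
            original_height=self.original_height,
            original_width=self.original_width,
        )


def _padded_length(length: int, patch: int, stride: int) -> int:
    if length <= patch:
        return patch
    n_steps = -(-(length - patch) // stride)  # ceil division
    return patch + n_steps * stride


def _mirror_pad(a: np.ndarray, pad_b: int, pad_r: int) -> np.ndarray:
    # Mirror padding preserves local intensity statistics at the borders.
    # np.pad(mode="symmetric") caps a single application at the array size,
    # so loop for the (rare) case of patches much larger than the image.
    while pad_b > 0 or pad_r > 0:
        db = min(pad_b, a.shape[0])
        dr = min(pad_r, a.shape[1])
        a = np.pad(a, ((0, db), (0, dr)), mode="symmetric")
        pad_b -= db
        pad_r -= dr
    return a


def extract_patches(image: np.ndarray, patch_size: int = 352, stride: int | None = None) -> PatchSet:
    """Cut a 2-D raster into overlapping tiles on a stride grid.

    The image is mirror-padded on the bottom/right so that the tile grid
    covers it exactly: offsets run over {0, stride, 2*stride, ...} and the
    tile count is ``(1 + (padded_h - patch)/stride) * (1 + (padded_w -
    patch)/stride)``.  The default stride is half the patch side.
    """
    if patch_size < 1:
        raise InvalidConfigError("patch_size must be >= 1")
    stride = patch_size // 2 if stride is None else stride
    if stride < 1:
        raise InvalidConfigError("stride must be >= 1")
    if image.ndim != 2:
        raise InvalidConfigError("extract_patches expects a 2-D raster")

    h, w = image.shape
    ph = _padded_length(h, patch_size, stride)
    pw = _padded_length(w, patch_size, stride)
    padded = _mirror_pad(image, ph - h, pw - w)

    patches = []
    for r in range(0, ph - patch_size + 1, stride):
        for c in range(0, pw - patch_size + 1, stride):
            patches.append((padded[r : r + patch_size, c : c + patch_size], r, c))
    return PatchSet(
        patches=patches,
        patch_size=patch_size,
        stride=stride,
        padded_height=ph,
        padded_width=pw,
        original_height=h,
        original_width=w,
    )


def stitch(patchset: PatchSet) -> np.ndarray:
    """Reassemble tiles into the original raster size.

    Overlapping values are combined by the per-pixel arithmetic mean, then
    the padded canvas is cropped back to the original dimensions.  For
    integer-valued tiles produced by an identity transform the mean of k
    identical values is exact in floating point, so the round-trip is
    bit-exact.
    """
    if not patchset.patches:
        raise IncompletePatchSetError("patchset has no tiles")
    acc = np.zeros((patchset.padded_height, patchset.padded_width), dtype=np.float64)
    cnt = np.zeros_like(acc)
    p = patchset.patch_size
    for tile, r, c in patchset.patches:
        if tile.shape != (p, p):
            raise IncompletePatchSetError(
                f"tile at ({r},{c}) has shape {tile.shape}, expected {(p, p)}"
            )
        acc[r : r + p, c : c + p] += tile
        cnt[r : r + p, c : c + p] += 1.0
    if (cnt == 0).any():
        raise IncompletePatchSetError("tiles do not cover the padded raster")
    out = acc / cnt
    return out[: patchset.original_height, : patchset.original_width]
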