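"""Synthetic lung-parenchyma phantoms with exactly known ground truth.

Real murine lung sections show bright (white) airspace lumens separated by
darker stained tissue walls; emphysematous ("smoker") lungs have visibly
larger lumens than healthy ("control") lungs.  This module generates two
kinds of stand-ins:

* analytic stripe/band phantoms whose intercept counts are forced by
  construction, used to pin down the line-intercept arithmetic exactly; and
* Voronoi-tessellation parenchyma images with a controllable characteristic
  lumen diameter, a paired ground-truth mask, and the cohort layout of a
  two-group mouse study (2 groups x n mice x m images per mouse).

All generators are deterministic: the same spec and seed give bit-identical
output, and cohort sub-seeds are derived from the master seed by a stable
hash so a cohort is reproducible across runs and platforms.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PhantomSpec",
    "ParenchymaSpec",
    "SyntheticSample",
    "CohortDataset",
    "generate_stripe_phantom",
    "generate_single_stripe",
    "generate_parenchyma",
    "generate_cohort",
    "control_spec",
    "smoker_spec",
    "subseed",
]


class InvalidSpecError(ValueError):
    """Raised when a generator spec violates its invariants."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters for an analytic binary phantom.

    ``stripes`` produces alternating vertical tissue/air bands of width
    ``period / 2`` each; ``single_stripe`` one centred tissue band covering
    ``tissue_fraction`` of the width; ``disks`` scattered tissue disks.
    """

    width: int
    height: int
    kind: Literal["stripes", "single_stripe", "disks"] = "stripes"
    period: int = 64
    tissue_fraction: float = 0.5
    disk_radius: int = 8
    disk_count: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise InvalidSpecError("phantom dimensions must be >= 1")
        if not 0.0 < self.tissue_fraction < 1.0:
            raise InvalidSpecError("tissue_fraction must lie in (0, 1)")
        if self.kind == "stripes":
            if self.period < 2 or self.period > self.width:
                raise InvalidSpecError(
                    f"stripe period {self.period} must be in [2, width]"
                )


@dataclass(frozen=True)
class ParenchymaSpec:
    """Parameters of the Voronoi parenchyma generator.

    ``lumen_scale`` is the characteristic airspace diameter in pixels (the
    knob that separates control from smoker morphology); ``wall_thickness``
    the nominal inter-alveolar wall width.  Airspaces render brighter than
    tissue, as in H&E micrographs where the background is white.
    """

    width: int = 128
    height: int = 128
    lumen_scale: float = 24.0
    wall_thickness: float = 4.0
    intensity_tissue: int = 90
    intensity_background: int = 220
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise InvalidSpecError("parenchyma images must be at least 8x8")
        if not self.lumen_scale > self.wall_thickness >= 1:
            raise InvalidSpecError("require lumen_scale > wall_thickness >= 1")
        if not self.intensity_background > self.intensity_tissue:
            raise InvalidSpecError(
                "airspaces must render brighter than tissue "
                "(intensity_background > intensity_tissue)"
            )
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticSample:
    """One generated image with its ground-truth mask and cohort labels."""

    image: np.ndarray
    truth_mask: np.ndarray
    spec: ParenchymaSpec | PhantomSpec
    mouse_id: str = ""
    group: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.truth_mask.shape[:2]:
            raise InvalidSpecError("image and truth_mask dimensions differ")


@dataclass
class CohortDataset:
    """Ordered samples from a two-group mouse study layout."""

    samples: list[SyntheticSample] = field(default_factory=list)
    n_mice_per_group: int = 3
    images_per_mouse: int = 12

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, i: int) -> SyntheticSample:
        return self.samples[i]

    @property
    def mouse_ids(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.mouse_id not in seen:
                seen.append(s.mouse_id)
        return seen


def control_spec(**overrides) -> ParenchymaSpec:
    """Default healthy-morphology spec (small lumens)."""
    return replace(ParenchymaSpec(), **overrides)


def smoker_spec(**overrides) -> ParenchymaSpec:
    """Default emphysematous-morphology spec: lumens 1.5x the control scale."""
    base = ParenchymaSpec()
    merged = {"lumen_scale": base.lumen_scale * 1.5}
    merged.update(overrides)
    return replace(base, **merged)


# ---------------------------------------------------------------------------
# Analytic phantoms
# ---------------------------------------------------------------------------


def generate_stripe_phantom(spec: PhantomSpec) -> np.ndarray:
    """Alternating vertical tissue/air bands of width ``period/2``.

    Column ``x`` is tissue iff ``floor(x / (period/2))`` is even, so a row of
    width ``w`` has exactly ``ceil(2w/period) - 1`` value transitions at the
    multiples of ``period/2``.  Deterministic and seed-independent.
    """
    if spec.kind != "stripes":
        raise InvalidSpecError(f"expected kind='stripes', got {spec.kind!r}")
    if spec.period % 2 != 0:
        raise InvalidSpecError("stripe period must be even")
    half = spec.period // 2
    cols = np.arange(spec.width) // half
    row = (cols % 2 == 0).astype(np.uint8)
    return np.tile(row, (spec.height, 1))


def generate_single_stripe(spec: PhantomSpec) -> np.ndarray:
    """One centred vertical tissue band; every row has exactly 2 transitions."""
    if spec.kind != "single_stripe":
        raise InvalidSpecError(f"expected kind='single_stripe', got {spec.kind!r}")
    band = int(round(spec.tissue_fraction * spec.width))
    if band < 1 or band >= spec.width:
        raise InvalidSpecError(
            f"tissue band of width {band} is degenerate for image width {spec.width}"
        )
    start = (spec.width - band) // 2
    mask = np.zeros((spec.height, spec.width), dtype=np.uint8)
    mask[:, start : start + band] = 1
    return mask


def generate_disk_phantom(spec: PhantomSpec) -> np.ndarray:
    """Seeded random tissue disks on an airspace background."""
    if spec.kind != "disks":
        raise InvalidSpecError(f"expected kind='disks', got {spec.kind!r}")
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    mask = np.zeros((spec.height, spec.width), dtype=np.uint8)
    for _ in range(spec.disk_count):
        cy = rng.uniform(0, spec.height)
        cx = rng.uniform(0, spec.width)
        mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= spec.disk_radius**2] = 1
    return mask


# ---------------------------------------------------------------------------
# Voronoi parenchyma
# ---------------------------------------------------------------------------


def _lumen_seeds(spec: ParenchymaSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid lumen centres with mean spacing ~ lumen_scale.

    A jittered grid approximates Poisson-disk sampling: one centre per
    lumen_scale-sized cell, uniformly jittered inside it, which keeps lumen
    diameters near the requested scale without clustering artefacts.
    """
    s = spec.lumen_scale
    nx = max(2, int(np.ceil(spec.width / s)) + 1)
    ny = max(2, int(np.ceil(spec.height / s)) + 1)
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny))
    jitter = rng.uniform(0.0, 1.0, size=(ny, nx, 2))
    pts = np.stack(
        [
            (gy + jitter[..., 0]) * s - s / 2,
            (gx + jitter[..., 1]) * s - s / 2,
        ],
        axis=-1,
    ).reshape(-1, 2)
    return pts


def _regularize_walls(mask: np.ndarray) -> np.ndarray:
    # Iterate the default white-opening/closing sequence to a fixed point so
    # truth masks carry no sub-kernel structure (specks, single-pixel spurs).
    from .classical import MorphologyConfig, apply_morphology

    cfg = MorphologyConfig()
    for _ in range(5):
        out = apply_morphology(mask, cfg)
        if np.array_equal(out, mask):
            break
        mask = out
    return mask


def generate_parenchyma(spec: ParenchymaSpec) -> SyntheticSample:
    """Render one parenchyma image plus its ground-truth tissue mask.

    The tissue wall network is the thickened edge set of a Voronoi
    tessellation of jittered-grid lumen centres: a pixel is tissue when the
    distance gap between its two nearest centres is below ``wall_thickness``,
    which places walls of roughly that width along every cell boundary.  The
    image is the two-level rendering of the mask (dark tissue on bright
    airspace) plus i.i.d. Gaussian noise, clipped to 8-bit.
    """
    rng = np.random.default_rng(spec.seed)
    pts = _lumen_seeds(spec, rng)
    tree = cKDTree(pts)
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    pix = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    dist, _ = tree.query(pix, k=2)
    wall = (dist[:, 1] - dist[:, 0]) < spec.wall_thickness
    mask = wall.reshape(spec.height, spec.width).astype(np.uint8)
    mask = _regularize_walls(mask)

    levels = np.where(mask == 1, spec.intensity_tissue, spec.intensity_background)
    noise = rng.normal(0.0, spec.noise_sd, size=mask.shape)
    image = np.clip(np.rint(levels + noise), 0, 255).astype(np.uint8)
    return SyntheticSample(image=image, truth_mask=mask, spec=spec)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def subseed(master_seed: int, group: str, mouse_index: int, image_index: int) -> int:
    """Stable per-sample sub-seed: SHA-256 of "(seed:group:mouse:image)" mod 2^31."""
    key = f"{master_seed}:{group}:{mouse_index}:{image_index}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:8], "big") % (2**31)


def generate_cohort(
    control: ParenchymaSpec | None = None,
    smoker: ParenchymaSpec | None = None,
    n_mice: int = 3,
    images_per_mouse: int = 12,
    seed: int = 0,
) -> CohortDataset:
    """Generate the two-group study layout: 2 x n_mice x images_per_mouse.

    The default layout mirrors a smoke-exposure mouse study with three
    animals per group and twelve analysed fields per animal (72 images).
    Per-sample seeds are derived from the master seed via :func:`subseed`.
    """
    if n_mice < 1 or images_per_mouse < 1:
        raise InvalidSpecError("n_mice and images_per_mouse must be >= 1")
    ctrl = control if control is not None else control_spec()
    smk = smoker if smoker is not None else smoker_spec()

    samples: list[SyntheticSample] = []
    for group, base in (("control", ctrl), ("smoker", smk)):
        for m in range(n_mice):
            mouse_id = f"{group}_m{m + 1}"
            for i in range(images_per_mouse):
                s = subseed(seed, group, m, i)
                sample = generate_parenchyma(replace(base, seed=s))
                samples.append(
                    replace(
                        sample,
                        mouse_id=mouse_id,
                        group=group,
                        sample_id=f"{mouse_id}_img{i + 1:02d}",
                    )
                )
    return CohortDataset(
        samples=samples, n_mice_per_group=n_mice, images_per_mouse=images_per_mouse
    )
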