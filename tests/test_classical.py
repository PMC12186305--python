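"""Threshold/morphology annotation against brute-force oracles."""

import numpy as np
import pytest

from lungmli import (
    MorphologyConfig,
    annotate,
    apply_morphology,
    binarize,
    confusion,
    control_spec,
    generate_parenchyma,
    generate_stripe_phantom,
    iou,
    to_grayscale,
)
from lungmli import PhantomSpec
from lungmli.classical import GRAY_WEIGHTS, UnsupportedFormatError, InvalidConfigError


# ---------------------------------------------------------------------------
# Brute-force set-morphology oracle: per-pixel min/max over the structuring
# element with edge-replicated out-of-bounds values.
# ---------------------------------------------------------------------------


def oracle_white_op(mask, op, k=3):
    h, w = mask.shape
    white = mask == 0
    out = np.zeros_like(white)
    r = k // 2
    for y in range(h):
        for x in range(w):
            vals = []
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    yy = min(max(y + dy, 0), h - 1)
                    xx = min(max(x + dx, 0), w - 1)
                    vals.append(white[yy, xx])
            out[y, x] = all(vals) if op == "erode_white" else any(vals)
    return (~out).astype(np.uint8)


def oracle_sequence(mask, steps, k=3):
    for step in steps:
        mask = oracle_white_op(mask, step, k)
    return mask


class TestGrayscale:
    def test_achromatic_identity(self):
        img = np.full((4, 4, 3), 77, dtype=np.uint8)
        assert np.array_equal(to_grayscale(img), np.full((4, 4), 77, dtype=np.uint8))

    def test_pure_white(self):
        img = np.full((2, 2, 3), 255, dtype=np.uint8)
        assert (to_grayscale(img) == 255).all()

    def test_elementwise_oracle(self, rng):
        img = rng.integers(0, 256, size=(4, 4, 3), dtype=np.uint8)
        got = to_grayscale(img)
        for y in range(4):
            for x in range(4):
                expected = sum(float(img[y, x, c]) * GRAY_WEIGHTS[c] for c in range(3))
                assert got[y, x] == round(expected)

    def test_single_channel_passthrough(self):
        img = np.arange(16, dtype=np.uint8).reshape(4, 4)
        assert to_grayscale(img) is img

    def test_bad_channel_count(self):
        with pytest.raises(UnsupportedFormatError):
            to_grayscale(np.zeros((4, 4, 2), dtype=np.uint8))


class TestBinarize:
    def test_two_level_image_otsu(self):
        # exhaustive-threshold oracle: any threshold separating 50 from 200
        # yields the same labels, so Otsu must label 50 tissue, 200 background
        gray = np.array([[50, 200], [200, 50]], dtype=np.uint8)
        mask = binarize(gray, MorphologyConfig(threshold_mode="otsu"))
        assert np.array_equal(mask, np.array([[1, 0], [0, 1]], dtype=np.uint8))

    def test_constant_below_fixed_threshold_all_tissue(self):
        gray = np.full((3, 3), 10, dtype=np.uint8)
        cfg = MorphologyConfig(threshold_mode="fixed", fixed_threshold=128)
        assert (binarize(gray, cfg) == 1).all()

    def test_at_fixed_threshold_is_background(self):
        gray = np.full((3, 3), 128, dtype=np.uint8)
        cfg = MorphologyConfig(threshold_mode="fixed", fixed_threshold=128)
        assert (binarize(gray, cfg) == 0).all()

    def test_constant_image_otsu_warns_all_background(self):
        gray = np.full((3, 3), 99, dtype=np.uint8)
        with pytest.warns(UserWarning, match="constant"):
            mask = binarize(gray, MorphologyConfig(threshold_mode="otsu"))
        assert (mask == 0).all()


class TestMorphology:
    def test_isolated_white_pixel_removed_by_erode_white(self):
        mask = np.ones((5, 5), dtype=np.uint8)
        mask[2, 2] = 0  # one airspace pixel in a tissue field
        cfg = MorphologyConfig(step_sequence=("erode_white",))
        assert (apply_morphology(mask, cfg) == 1).all()

    def test_all_white_fixed_point(self):
        mask = np.zeros((6, 6), dtype=np.uint8)  # all airspace
        out = apply_morphology(mask, MorphologyConfig())
        assert (out == 0).all()

    def test_default_sequence_matches_bruteforce_on_handbuilt_mask(self):
        mask = np.array(
            [
                [1, 1, 1, 1, 0, 0, 0, 0],
                [1, 1, 1, 1, 0, 0, 0, 0],
                [1, 1, 0, 1, 0, 0, 1, 0],
                [1, 1, 1, 1, 0, 0, 0, 0],
                [0, 0, 0, 0, 0, 1, 0, 0],
                [0, 0, 0, 1, 1, 1, 0, 0],
                [0, 0, 0, 1, 1, 1, 0, 0],
                [1, 0, 0, 1, 1, 1, 0, 1],
            ],
            dtype=np.uint8,
        )
        cfg = MorphologyConfig()
        got = apply_morphology(mask, cfg)
        expected = oracle_sequence(mask, cfg.step_sequence)
        assert np.array_equal(got, expected)

    @pytest.mark.parametrize("op", ["erode_white", "dilate_white"])
    def test_single_ops_match_bruteforce_on_random_masks(self, op, rng):
        for _ in range(25):
            mask = rng.integers(0, 2, size=(16, 16)).astype(np.uint8)
            got = apply_morphology(mask, MorphologyConfig(step_sequence=(op,)))
            assert np.array_equal(got, oracle_white_op(mask, op))

    def test_duality_erode_white_is_complement_dilate_complement(self, rng):
        # eroding the white phase == complementing, dilating, complementing
        for _ in range(10):
            mask = rng.integers(0, 2, size=(16, 16)).astype(np.uint8)
            eroded = apply_morphology(mask, MorphologyConfig(step_sequence=("erode_white",)))
            comp = (1 - mask).astype(np.uint8)
            dilated_comp = apply_morphology(comp, MorphologyConfig(step_sequence=("dilate_white",)))
            assert np.array_equal(eroded, 1 - dilated_comp)

    def test_cross_kernel_matches_bruteforce(self, rng):
        def oracle_cross(mask, op):
            h, w = mask.shape
            white = mask == 0
            out = np.zeros_like(white)
            offs = [(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)]
            for y in range(h):
                for x in range(w):
                    vals = [
                        white[min(max(y + dy, 0), h - 1), min(max(x + dx, 0), w - 1)]
                        for dy, dx in offs
                    ]
                    out[y, x] = all(vals) if op == "erode_white" else any(vals)
            return (~out).astype(np.uint8)

        mask = rng.integers(0, 2, size=(12, 12)).astype(np.uint8)
        cfg = MorphologyConfig(kernel_shape="cross", step_sequence=("dilate_white",))
        assert np.array_equal(apply_morphology(mask, cfg), oracle_cross(mask, "dilate_white"))

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(InvalidConfigError):
            apply_morphology(np.ones((2, 2), dtype=np.uint8), MorphologyConfig(kernel_size=5))

    def test_even_kernel_rejected(self):
        with pytest.raises(InvalidConfigError):
            MorphologyConfig(kernel_size=4)


class TestAnnotate:
    def test_noiseless_roundtrip_exact(self, noiseless_sample):
        ann = annotate(noiseless_sample.image)
        assert np.array_equal(ann, noiseless_sample.truth_mask)

    def test_noisy_annotation_high_iou(self):
        ious = []
        for seed in range(20):
            s = generate_parenchyma(control_spec(seed=seed, noise_sd=8.0))
            ann = annotate(s.image)
            ious.append(iou(confusion(ann, s.truth_mask), "tissue"))
        assert min(ious) >= 0.95

    def test_stripe_phantom_rendered_roundtrip(self):
        mask = generate_stripe_phantom(PhantomSpec(width=64, height=32, period=16))
        image = np.where(mask == 1, 80, 230).astype(np.uint8)
        assert np.array_equal(annotate(image), mask)

    def test_output_dims_and_range(self, parenchyma_sample):
        ann = annotate(parenchyma_sample.image)
        assert ann.shape == parenchyma_sample.image.shape[:2]
        assert 0.0 <= ann.mean() <= 1.0
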