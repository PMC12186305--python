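"""Trainable symmetric encoder-decoder for binary tissue segmentation.

A small U-Net-style fully convolutional network written directly on NumPy:
3x3 same-padded convolutions, ReLU, 2x2 max-pooling in the encoder, nearest
upsampling with skip concatenation in the decoder, and a 1x1 convolution
producing per-pixel tissue logits.  Training minimises per-pixel binary
cross-entropy with Adam.  The architecture is deliberately specified only by
its contract — symmetric, equal input/output spatial dimensions, output a
probability in [0,1] per pixel — with depth and width as configuration.

The default training recipe is 20 epochs, learning rate 1e-4, batch size 9,
patch size 352 with stride 176, and no augmentation or oversampling; scaled
runs override these through :class:`TrainConfig`.

Why NumPy: the segmentation task the pipeline needs (two-level histology
masks) is learnable by a very small network, and an explicit im2col
implementation keeps the package dependency-light and bit-reproducible.
All heavy lifting is BLAS matrix multiplication.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .patchwork import extract_patches, stitch

__all__ = [
    "TrainConfig",
    "SplitSpec",
    "SegmentationModel",
    "build_model",
    "split_dataset",
    "train",
    "predict_image",
    "predict_proba",
]


class InvalidConfigError(ValueError):
    pass


class StratificationError(ValueError):
    pass


class NoDataError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Training and architecture settings.

    Defaults follow the published recipe (20 epochs, lr 1e-4, batch 9, patch
    352 / stride 176, no augmentation); ``depth`` and ``base_channels`` size
    the encoder-decoder.
    """

    epochs: int = 20
    learning_rate: float = 1e-4
    batch_size: int = 9
    seed: int = 0
    patch_size: int = 352
    stride: int = 176
    depth: int = 2
    base_channels: int = 8

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise InvalidConfigError("epochs and batch_size must be >= 1")
        if self.depth < 1 or self.base_channels < 1:
            raise InvalidConfigError("depth and base_channels must be >= 1")


@dataclass(frozen=True)
class SplitSpec:
    """Requested train/validation/test sizes with per-mouse stratification."""

    n_train: int = 50
    n_val: int = 11
    n_test: int = 11
    stratify_by: str = "mouse_id"
    seed: int = 0


# ---------------------------------------------------------------------------
# Dataset splitting
# ---------------------------------------------------------------------------


def split_dataset(dataset, spec: SplitSpec) -> tuple[list[int], list[int], list[int]]:
    """Partition sample indices into disjoint train/val/test sets by mouse.

    Each mouse contributes to every split when it has at least three images
    (so held-out performance is measured on every animal), per-mouse
    allocations follow the requested split proportions with largest-remainder
    rounding, and the concrete indices are drawn by a seeded shuffle.
    """
    n = len(dataset)
    sizes = (spec.n_train, spec.n_val, spec.n_test)
    if sum(sizes) != n:
        raise InvalidConfigError(
            f"split sizes {sizes} must sum to the dataset size {n}"
        )
    by_mouse: dict[str, list[int]] = {}
    for i, s in enumerate(dataset):
        by_mouse.setdefault(getattr(s, spec.stratify_by), []).append(i)

    n_splits = 3
    for mouse, idx in by_mouse.items():
        if len(idx) < n_splits:
            raise StratificationError(
                f"mouse {mouse!r} has {len(idx)} images, fewer than {n_splits} splits"
            )

    mice = list(by_mouse)
    fracs = [s / n for s in sizes]
    # base allocation: floor of the proportional share, at least 1 per split
    alloc = {m: [max(1, int(len(by_mouse[m]) * f)) for f in fracs] for m in mice}
    for m in mice:
        # trim if the minimums overshoot this mouse's image count
        while sum(alloc[m]) > len(by_mouse[m]):
            j = int(np.argmax(alloc[m]))
            alloc[m][j] -= 1
    # distribute the remaining images to match the global split sizes exactly;
    # handle over-allocated splits first so they free capacity for the rest
    order = sorted(
        range(n_splits), key=lambda j: sizes[j] - sum(alloc[m][j] for m in mice)
    )
    for j in order:
        deficit = sizes[j] - sum(alloc[m][j] for m in mice)
        while deficit != 0:
            step = 1 if deficit > 0 else -1
            # prefer the mouse with the largest (signed) unallocated remainder
            cands = [
                m
                for m in mice
                if (step > 0 and sum(alloc[m]) < len(by_mouse[m]))
                or (step < 0 and alloc[m][j] > 1)
            ]
            if not cands and step < 0:
                # a split smaller than the mouse count cannot keep one image
                # from every mouse; drop the per-mouse minimum
                cands = [m for m in mice if alloc[m][j] > 0]
            key = lambda m: (len(by_mouse[m]) * fracs[j] - alloc[m][j]) * step
            m = max(cands, key=key)
            alloc[m][j] += step
            deficit -= step

    rng = np.random.default_rng(spec.seed)
    splits: tuple[list[int], list[int], list[int]] = ([], [], [])
    for m in mice:
        idx = np.array(by_mouse[m])
        rng.shuffle(idx)
        pos = 0
        for j in range(n_splits):
            take = alloc[m][j]
            splits[j].extend(int(i) for i in idx[pos : pos + take])
            pos += take
    return tuple(sorted(s) for s in splits)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Layers (im2col convolution with explicit backprop)
# ---------------------------------------------------------------------------


class _Conv:
    """k x k same-padded convolution; weights stored as (Cout, Cin*k*k)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))  # He initialisation
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * k * k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self._cache = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(1, 4, 5, 0, 2, 3).reshape(c * self.k * self.k, n * h * w)
        return np.ascontiguousarray(cols)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        out = (self.W @ cols + self.b[:, None]).reshape(-1, n, h, w)
        self._cache = (cols, x.shape)
        return out.transpose(1, 0, 2, 3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        c_out = dout.shape[1]
        g = dout.transpose(1, 0, 2, 3).reshape(c_out, n * h * w)
        self.dW = g @ cols.T
        self.db = g.sum(axis=1)
        dcols = (self.W.T @ g).reshape(c, self.k, self.k, n, h, w)
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, i, j].transpose(1, 0, 2, 3)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp

    def params(self):
        return [("W", self), ("b", self)]


def _relu_forward(x):
    mask = x > 0
    return x * mask, mask


def _pool_forward(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool_backward(dout, idx, shape):
    n, c, h, w = shape
    dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dxr.reshape(n, c, h, w)


def _upsample_forward(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample_backward(dout):
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


class SegmentationModel:
    """Symmetric encoder-decoder with skip connections.

    ``forward`` maps a (N, 1, H, W) float32 batch in [0,1] to (N, 1, H, W)
    tissue logits; spatial dimensions are preserved for any input whose side
    lengths are divisible by ``2**depth``.
    """

    def __init__(self, config: TrainConfig):
        if config.patch_size % (2**config.depth) != 0:
            raise InvalidConfigError(
                f"patch_size {config.patch_size} not divisible by 2^depth"
            )
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = [config.base_channels * (2**d) for d in range(config.depth + 1)]
        self.enc: list[tuple[_Conv, _Conv]] = []
        c_prev = 1
        for d in range(config.depth):
            self.enc.append((_Conv(c_prev, ch[d], 3, rng), _Conv(ch[d], ch[d], 3, rng)))
            c_prev = ch[d]
        self.mid = (_Conv(c_prev, ch[-1], 3, rng), _Conv(ch[-1], ch[-1], 3, rng))
        self.dec: list[tuple[_Conv, _Conv]] = []
        c_prev = ch[-1]
        for d in reversed(range(config.depth)):
            c_cat = c_prev + ch[d]
            self.dec.append((_Conv(c_cat, ch[d], 3, rng), _Conv(ch[d], ch[d], 3, rng)))
            c_prev = ch[d]
        self.head = _Conv(c_prev, 1, 1, rng)

    # -- plumbing ----------------------------------------------------------

    def _convs(self) -> list[_Conv]:
        out = []
        for a, b in self.enc:
            out += [a, b]
        out += list(self.mid)
        for a, b in self.dec:
            out += [a, b]
        out.append(self.head)
        return out

    def _check_input(self, x: np.ndarray) -> None:
        h, w = x.shape[2], x.shape[3]
        f = 2**self.config.depth
        if h % f or w % f:
            raise InvalidConfigError(
                f"input {h}x{w} not divisible by 2^depth = {f}"
            )

    # -- forward/backward --------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Tissue logits for a (N,1,H,W) batch; caches activations for backward."""
        self._check_input(x)
        caches = {"relu": [], "pool": [], "skip_ch": []}
        skips = []
        h = x.astype(np.float32)
        for c1, c2 in self.enc:
            h, m1 = _relu_forward(c1.forward(h))
            h, m2 = _relu_forward(c2.forward(h))
            caches["relu"].append((m1, m2))
            skips.append(h)
            shape = h.shape
            h, idx = _pool_forward(h)
            caches["pool"].append((idx, shape))
        h, m1 = _relu_forward(self.mid[0].forward(h))
        h, m2 = _relu_forward(self.mid[1].forward(h))
        caches["mid_relu"] = (m1, m2)
        for (c1, c2), skip in zip(self.dec, reversed(skips)):
            h = _upsample_forward(h)
            caches["skip_ch"].append((h.shape[1], skip.shape[1]))
            h = np.concatenate([h, skip], axis=1)
            h, m1 = _relu_forward(c1.forward(h))
            h, m2 = _relu_forward(c2.forward(h))
            caches["relu"].append((m1, m2))
        z = self.head.forward(h)
        self._caches = caches
        return z

    def backward(self, dz: np.ndarray) -> None:
        """Backprop from d(loss)/d(logits); leaves gradients on each conv."""
        caches = self._caches
        g = self.head.backward(dz.astype(np.float32))
        n_enc = len(self.enc)
        dskips = [None] * n_enc
        for i, (c1, c2) in enumerate(reversed(self.dec)):
            m1, m2 = caches["relu"][-1 - i]
            g = c1.backward(c2.backward(g * m2) * m1)
            # decoder block j (forward order) consumed encoder skip n_enc-1-j,
            # so reversed iteration i pairs with encoder skip index i
            up_ch, skip_ch = caches["skip_ch"][len(self.dec) - 1 - i]
            dskips[i] = g[:, up_ch:]
            g = _upsample_backward(g[:, :up_ch])
        m1, m2 = caches["mid_relu"]
        g = self.mid[0].backward(self.mid[1].backward(g * m2) * m1)
        for i, (c1, c2) in enumerate(reversed(self.enc)):
            d = n_enc - 1 - i
            idx, shape = caches["pool"][d]
            g = _pool_backward(g, idx, shape) + dskips[d]
            m1, m2 = caches["relu"][d]
            g = c1.backward(c2.backward(g * m2) * m1)

    def predict_proba_patch(self, patch: np.ndarray) -> np.ndarray:
        """Per-pixel tissue probability for one 2-D patch in [0,1] intensity."""
        x = patch.astype(np.float32)[None, None]
        z = self.forward(x)
        return _sigmoid(z)[0, 0]

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        for i, c in enumerate(self._convs()):
            arrays[f"W{i}"] = c.W
            arrays[f"b{i}"] = c.b
        np.savez(path, config=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path) -> "SegmentationModel":
        data = np.load(path, allow_pickle=False)
        config = TrainConfig(**json.loads(str(data["config"])))
        model = cls(config)
        for i, c in enumerate(model._convs()):
            c.W = data[f"W{i}"].astype(np.float32)
            c.b = data[f"b{i}"].astype(np.float32)
        return model


def build_model(config: TrainConfig) -> SegmentationModel:
    """Instantiate the encoder-decoder with seeded weight initialisation."""
    return SegmentationModel(config)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(z: np.ndarray, y: np.ndarray) -> float:
    # stable mean binary cross-entropy on logits
    return float(np.mean(np.logaddexp(0.0, z) - z * y))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, convs: Sequence[_Conv], lr: float):
        self.convs = convs
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [
            (np.zeros_like(c.W), np.zeros_like(c.b)) for c in convs
        ]
        self.v = [
            (np.zeros_like(c.W), np.zeros_like(c.b)) for c in convs
        ]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for c, m, v in zip(self.convs, self.m, self.v):
            for g, p, mm, vv in ((c.dW, c.W, m[0], v[0]), (c.db, c.b, m[1], v[1])):
                mm *= self.beta1
                mm += (1 - self.beta1) * g
                vv *= self.beta2
                vv += (1 - self.beta2) * g * g
                p -= self.lr * (mm / b1t) / (np.sqrt(vv / b2t) + self.eps)


def _to_batch(patches: Sequence[np.ndarray]) -> np.ndarray:
    return np.stack([p.astype(np.float32) for p in patches])[:, None]


def _tissue_iou(pred: np.ndarray, truth: np.ndarray) -> float:
    inter = np.logical_and(pred, truth).sum()
    union = np.logical_or(pred, truth).sum()
    return float(inter / union) if union else 1.0


def train(
    model: SegmentationModel,
    train_set: Sequence[tuple[np.ndarray, np.ndarray]],
    val_set: Sequence[tuple[np.ndarray, np.ndarray]] = (),
    config: TrainConfig | None = None,
):
    """Fit the model on (image_patch, label_patch) pairs.

    Image patches are greyscale rasters scaled to [0,1]; label patches are
    binary tissue masks.  Optimises mean per-pixel binary cross-entropy with
    Adam; each epoch records train loss and, when a validation set is given,
    validation loss and validation tissue IoU at threshold 0.5.

    Returns ``(model, history)`` where history is a list of per-epoch dicts.
    """
    config = config or model.config
    if len(train_set) == 0:
        raise NoDataError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = _Adam(model._convs(), config.learning_rate)
    xs = [np.asarray(img, dtype=np.float32) for img, _ in train_set]
    ys = [np.asarray(lbl, dtype=np.float32) for _, lbl in train_set]
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(xs))
        losses = []
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            xb = _to_batch([xs[i] for i in sel])
            yb = _to_batch([ys[i] for i in sel])
            z = model.forward(xb)
            losses.append(_bce(z, yb))
            dz = (_sigmoid(z) - yb) / z.size
            model.backward(dz)
            opt.step()
        rec = {"epoch": epoch + 1, "train_loss": float(np.mean(losses))}
        if len(val_set):
            vl, vi = _evaluate(model, val_set, config.batch_size)
            rec["val_loss"] = vl
            rec["val_iou"] = vi
        history.append(rec)
    return model, history


def _evaluate(model, pairs, batch_size) -> tuple[float, float]:
    losses, inter, union = [], 0, 0
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start : start + batch_size]
        xb = _to_batch([np.asarray(img, dtype=np.float32) for img, _ in chunk])
        yb = _to_batch([np.asarray(lbl, dtype=np.float32) for _, lbl in chunk])
        z = model.forward(xb)
        losses.append(_bce(z, yb) * len(chunk))
        pred = _sigmoid(z) > 0.5
        truth = yb > 0.5
        inter += np.logical_and(pred, truth).sum()
        union += np.logical_or(pred, truth).sum()
    iou = float(inter / union) if union else 1.0
    return float(np.sum(losses) / len(pairs)), iou


# ---------------------------------------------------------------------------
# Full-image inference through the patchwork
# ---------------------------------------------------------------------------


def predict_proba(model: SegmentationModel, gray: np.ndarray, config: TrainConfig | None = None) -> np.ndarray:
    """Per-pixel tissue probability for a full greyscale image.

    The image is scaled to [0,1], tiled with the configured patch/stride
    geometry, passed through the network patch by patch, and the overlapping
    probability tiles are averaged back to the original size.
    """
    config = config or model.config
    x = gray.astype(np.float32) / 255.0
    ps = extract_patches(x, config.patch_size, config.stride)
    probs = ps.map(lambda t: _sigmoid(model.forward(t[None, None]))[0, 0])
    return stitch(probs)


def predict_image(model: SegmentationModel, image: np.ndarray, config: TrainConfig | None = None) -> np.ndarray:
    """Binary tissue mask for a full image: probabilities thresholded at 0.5."""
    from .classical import to_grayscale

    gray = to_grayscale(image)
    proba = predict_proba(model, gray, config)
    return (proba > 0.5).astype(np.uint8)
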