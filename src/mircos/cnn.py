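"""A compact residual convolutional network for correlation-map images.

The classifier is a small residual network written directly on NumPy:
stacked 3x3 convolution + batch-norm blocks with identity shortcuts
(1x1 strided projection where the width or resolution changes), global
average pooling and a two-way softmax head, trained with mini-batch Adam
on cross-entropy. Three stages of configurable width (default 16/32/64,
two blocks per stage) keep the parameter count proportionate to a few
hundred small images, and everything runs single-threaded CPU in minutes.

Convolutions are evaluated as matrix products over im2col patch matrices;
the backward pass folds patch gradients back with a k*k strided
accumulation, so the whole network is a handful of dense GEMMs per batch.

Training is deterministic for a fixed seed: weight initialization, batch
shuffling and batch-norm statistics all derive from one generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from PIL import Image

from .metrics import ClassifierMetrics, ConfusionCounts, confusion_metrics, count_confusion
from .render import ImageDataset, ImageRecord

__all__ = [
    "ResNetSpec",
    "OptimizerConfig",
    "TrainRun",
    "ResNetClassifier",
    "DivergenceError",
    "load_images",
    "train_classifier",
    "evaluate_classifier",
]


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


# ---------------------------------------------------------------------- #
# Low-level layers


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    sw = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = sw.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    g = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += g[
                :, :, i, j
            ]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class _Conv:
    def __init__(self, rng, c_in, c_out, k=3, stride=1, pad=1):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * k * k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        out = cols @ self.W.T + self.b
        n = x.shape[0]
        self._cache = (cols, x.shape, ho, wo) if train else None
        return out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, x_shape, ho, wo = self._cache
        n = dout.shape[0]
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.c_out)
        dW = dmat.T @ cols
        db = dmat.sum(axis=0)
        dcols = dmat @ self.W
        dx = _col2im(dcols, x_shape, self.k, self.stride, self.pad, ho, wo)
        self._cache = None
        return dx, [dW, db]


class _BatchNorm:
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        xhat, inv = self._cache
        n_elem = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        dbeta = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / n_elem
        ) * inv[None, :, None, None]
        self._cache = None
        return dx, [dgamma, dbeta]


class _ResBlock:
    """conv-BN-ReLU-conv-BN with identity (or projected) shortcut."""

    def __init__(self, rng, c_in, c_out, stride):
        self.conv1 = _Conv(rng, c_in, c_out, 3, stride, 1)
        self.bn1 = _BatchNorm(c_out)
        self.conv2 = _Conv(rng, c_out, c_out, 3, 1, 1)
        self.bn2 = _BatchNorm(c_out)
        self.project = c_in != c_out or stride != 1
        if self.project:
            self.conv_s = _Conv(rng, c_in, c_out, 1, stride, 0)
            self.bn_s = _BatchNorm(c_out)

    def layers(self):
        out = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.project:
            out += [self.conv_s, self.bn_s]
        return out

    def forward(self, x, train):
        h = self.bn1.forward(self.conv1.forward(x, train), train)
        m1 = h > 0
        h = h * m1
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        s = (
            self.bn_s.forward(self.conv_s.forward(x, train), train)
            if self.project
            else x
        )
        out = h + s
        m2 = out > 0
        if train:
            self._masks = (m1, m2)
        return out * m2

    def backward(self, dout):
        m1, m2 = self._masks
        d = dout * m2
        grads = []
        dh, g = self.bn2.backward(d)
        grads = g + grads
        dh, g = self.conv2.backward(dh)
        grads = g + grads
        dh = dh * m1
        dh, g = self.bn1.backward(dh)
        grads = g + grads
        dh, g = self.conv1.backward(dh)
        grads = g + grads
        if self.project:
            ds, gs = self.bn_s.backward(d)
            ds, gc = self.conv_s.backward(ds)
            grads = grads + gc + gs
            dx = dh + ds
        else:
            dx = dh + d
        self._masks = None
        return dx, grads


# ---------------------------------------------------------------------- #
# Network


@dataclass(frozen=True)
class ResNetSpec:
    """Architecture descriptor: stage widths, blocks per stage, input."""

    stage_widths: tuple[int, ...] = (16, 32, 64)
    blocks_per_stage: int = 2
    in_channels: int = 3
    n_classes: int = 2

    def describe(self) -> str:
        return (
            f"resnet-{len(self.stage_widths)}x{self.blocks_per_stage}-"
            + "/".join(map(str, self.stage_widths))
        )


TINY = ResNetSpec(stage_widths=(8, 16, 32), blocks_per_stage=1)


@dataclass(frozen=True)
class OptimizerConfig:
    learning_rate: float = 1e-3
    batch_size: int = 16
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weight_decay: float = 0.0


class ResNetClassifier:
    """The network plus its preprocessing constants and class order."""

    def __init__(self, spec: ResNetSpec, classes: tuple[str, ...], seed: int = 0):
        if len(classes) != spec.n_classes:
            raise ValueError("class list does not match the architecture head")
        self.spec = spec
        self.classes = tuple(classes)
        self.seed = seed
        rng = np.random.default_rng(seed)
        w0 = spec.stage_widths[0]
        self.stem = _Conv(rng, spec.in_channels, w0, 3, 2, 1)
        self.stem_bn = _BatchNorm(w0)
        self.blocks: list[_ResBlock] = []
        c_in = w0
        for si, width in enumerate(spec.stage_widths):
            for bi in range(spec.blocks_per_stage):
                stride = 2 if (si > 0 and bi == 0) else 1
                self.blocks.append(_ResBlock(rng, c_in, width, stride))
                c_in = width
        self.fc_W = rng.normal(0.0, 1.0 / np.sqrt(c_in), size=(c_in, spec.n_classes)).astype(
            np.float32
        )
        self.fc_b = np.zeros(spec.n_classes, dtype=np.float32)
        # per-channel normalization constants, set from the training role
        self.norm_mean = np.zeros(spec.in_channels, dtype=np.float32)
        self.norm_sd = np.ones(spec.in_channels, dtype=np.float32)
        self.train_sample_ids: tuple[str, ...] = ()

    # -------------------------------------------------------------- #

    def _layers(self):
        out = [self.stem, self.stem_bn]
        for b in self.blocks:
            out += b.layers()
        return out

    def parameters(self) -> list[np.ndarray]:
        params = []
        for layer in self._layers():
            params += layer.params()
        return params + [self.fc_W, self.fc_b]

    def set_normalization(self, images: np.ndarray) -> None:
        self.norm_mean = images.mean(axis=(0, 2, 3)).astype(np.float32)
        sd = images.std(axis=(0, 2, 3))
        sd[sd == 0] = 1.0
        self.norm_sd = sd.astype(np.float32)

    def _normalize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.norm_mean[None, :, None, None]) / self.norm_sd[None, :, None, None]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of raw [0,1] images, NCHW."""
        h = self._normalize(x.astype(np.float32))
        h = self.stem_bn.forward(self.stem.forward(h, train), train)
        mask = h > 0
        h = h * mask
        if train:
            self._stem_mask = mask
        for b in self.blocks:
            h = b.forward(h, train)
        if train:
            self._gap_shape = h.shape
        pooled = h.mean(axis=(2, 3))
        if train:
            self._pooled = pooled
        return pooled @ self.fc_W + self.fc_b

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        d_fc_W = self._pooled.T @ dlogits
        d_fc_b = dlogits.sum(axis=0)
        dpool = dlogits @ self.fc_W.T
        n, c, hh, ww = self._gap_shape
        dh = np.broadcast_to(
            dpool[:, :, None, None] / (hh * ww), self._gap_shape
        ).astype(np.float32)
        grads_rev: list[np.ndarray] = []
        for b in reversed(self.blocks):
            dh, g = b.backward(dh)
            grads_rev = g + grads_rev
        dh = dh * self._stem_mask
        dh, g_bn = self.stem_bn.backward(dh)
        _, g_conv = self.stem.backward(dh)
        return g_conv + g_bn + grads_rev + [d_fc_W, d_fc_b]

    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch):
            logits = self.forward(x[i : i + batch], train=False)
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.vstack(out)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.classes)[np.argmax(self.predict_proba(x), axis=1)]


def _softmax_ce(logits: np.ndarray, y_idx: np.ndarray):
    logits = logits - logits.max(axis=1, keepdims=True)
    logz = np.log(np.exp(logits).sum(axis=1))
    n = logits.shape[0]
    loss = float(np.mean(logz - logits[np.arange(n), y_idx]))
    p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
    p[np.arange(n), y_idx] -= 1.0
    return loss, (p / n).astype(np.float32)


# ---------------------------------------------------------------------- #
# Data plumbing


def load_images(records: list[ImageRecord], size: int | None = None):
    """Decode image files into an NCHW float array in [0, 1] plus labels/ids."""
    mats, labels, ids = [], [], []
    for rec in records:
        img = Image.open(rec.path).convert("RGB")
        if size is not None and img.size != (size, size):
            img = img.resize((size, size), Image.BILINEAR)
        mats.append(np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0)
        labels.append(rec.label)
        ids.append(rec.sample_id)
    return np.stack(mats), np.asarray(labels), ids


# ---------------------------------------------------------------------- #
# Training / evaluation


@dataclass
class TrainRun:
    epochs: int
    loss: list[float] = field(default_factory=list)
    acc_train: list[float] = field(default_factory=list)
    acc_test: list[float] = field(default_factory=list)
    seed: int = 0
    architecture: str = ""
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)

    @property
    def final_loss(self) -> float:
        return self.loss[-1]


def train_classifier(
    dataset: ImageDataset,
    category: str = "synchronous",
    epochs: int = 46,
    seed: int = 0,
    arch: ResNetSpec = ResNetSpec(),
    optimizer: OptimizerConfig = OptimizerConfig(),
    image_size: int | None = None,
) -> tuple[ResNetClassifier, TrainRun]:
    """Train the residual network on one image category.

    Uses the manifest's ``train`` role for gradient steps and tracks
    accuracy on the ``train`` and ``test`` roles each epoch; the external
    validation role is never touched here. Per-channel normalization
    constants come from the train role only.
    """
    train_recs = dataset.by_role(category, "train")
    test_recs = dataset.by_role(category, "test")
    if not train_recs or not test_recs:
        raise ValueError(f"category {category!r} has an empty train or test role")
    X_tr, y_tr, ids_tr = load_images(train_recs, image_size)
    X_te, y_te, _ = load_images(test_recs, image_size)
    classes = tuple(sorted(set(y_tr)))
    model = ResNetClassifier(arch, classes, seed)
    model.set_normalization(X_tr)
    model.train_sample_ids = tuple(ids_tr)
    y_idx = np.searchsorted(np.asarray(classes), y_tr)

    params = model.parameters()
    m_state = [np.zeros_like(p, dtype=np.float64) for p in params]
    v_state = [np.zeros_like(p, dtype=np.float64) for p in params]
    t = 0
    rng = np.random.default_rng(seed + 1)
    run = TrainRun(
        epochs=epochs, seed=seed, architecture=arch.describe(), optimizer=optimizer
    )
    n = X_tr.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, optimizer.batch_size):
            idx = order[start : start + optimizer.batch_size]
            logits = model.forward(X_tr[idx], train=True)
            loss, dlogits = _softmax_ce(logits, y_idx[idx])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch + 1}")
            epoch_loss += loss * len(idx)
            grads = model.backward(dlogits)
            t += 1
            lr_t = (
                optimizer.learning_rate
                * np.sqrt(1 - optimizer.beta2**t)
                / (1 - optimizer.beta1**t)
            )
            for p, g, ms, vs in zip(params, grads, m_state, v_state):
                if optimizer.weight_decay:
                    g = g + optimizer.weight_decay * p
                ms *= optimizer.beta1
                ms += (1 - optimizer.beta1) * g
                vs *= optimizer.beta2
                vs += (1 - optimizer.beta2) * g * g
                p -= (lr_t * ms / (np.sqrt(vs) + optimizer.eps)).astype(p.dtype)
        run.loss.append(epoch_loss / n)
        run.acc_train.append(100.0 * float(np.mean(model.predict(X_tr) == y_tr)))
        run.acc_test.append(100.0 * float(np.mean(model.predict(X_te) == y_te)))
    return model, run


def evaluate_classifier(
    model: ResNetClassifier,
    dataset: ImageDataset,
    category: str = "synchronous",
    role: str = "ev",
    image_size: int | None = None,
) -> tuple[ConfusionCounts, ClassifierMetrics, float]:
    """Score a manifest role: confusion counts, Eq-style metrics, mean loss.

    Refuses to score records whose sample ids overlap the model's training
    role (leakage guard), except when scoring the training role itself.
    """
    recs = dataset.by_role(category, role)
    if not recs:
        raise ValueError(f"role {role!r} is empty for category {category!r}")
    X, y, ids = load_images(recs, image_size)
    if role != "train":
        overlap = set(ids) & set(model.train_sample_ids)
        if overlap:
            raise ValueError(f"role {role!r} overlaps the training samples: {sorted(overlap)[:3]}")
    proba = model.predict_proba(X)
    pred = np.asarray(model.classes)[np.argmax(proba, axis=1)]
    y_idx = np.searchsorted(np.asarray(model.classes), y)
    eps = 1e-12
    mean_loss = float(-np.mean(np.log(proba[np.arange(len(y)), y_idx] + eps)))
    counts = count_confusion(y, pred)
    return counts, confusion_metrics(counts), mean_loss
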