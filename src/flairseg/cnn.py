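"""The 18-layer binary tumor/not-tumor CNN, implemented on numpy.

Architecture (single-channel 128x128 input):

    conv 512 -> ReLU -> pool | conv 256 -> ReLU | conv 128 -> ReLU -> pool
    | conv 64 -> ReLU | conv 32 -> ReLU -> pool | flatten 8192
    | FC 32 -> ReLU | FC 2 -> softmax

All convolutions are 3x3, stride 1, SAME padding; all pools are 2x2 max,
stride 2.  The last convolution's post-ReLU maps (32 maps, 32x32, taken
before the final pool) are the feature stack the segmentation stage
consumes.

Training minimizes the two-output binary cross-entropy with Adam under a
polynomial learning-rate decay alpha0 * (1 - e/Ne)^0.9.  A ``scale``
divisor shrinks every filter count uniformly (512/scale ... 32/scale) so the
identical topology trains in seconds on a laptop; spatial shapes are
unchanged.

Everything here — forward, backward, optimizer — is plain numpy so the whole
pipeline runs with no deep-learning framework; the heavy lifting is im2col
+ BLAS matrix multiplication in float32.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import (
    BoundsError,
    ConfigurationError,
    DivergenceError,
    ValidationError,
)
from .io_slices import Slice2D

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "Network",
    "build_network",
    "bce_loss",
    "lr_schedule",
    "derive_labels",
    "train",
    "classify",
    "classification_metrics",
    "roc_points",
]

LABEL_NAMES = ("not tumor", "tumor")  # class index 0, 1


# --------------------------------------------------------------------------
# architecture description and shape arithmetic
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative layer stack; shapes are derived, never stored.

    ``pool_after_conv`` lists 1-based convolution indices followed by a max
    pool.  The default values are the published table: five convolutions of
    512/256/128/64/32 filters with pools after convs 1, 3 and 5, then
    FC 32 and FC 2.
    """

    filters: tuple[int, ...] = (512, 256, 128, 64, 32)
    kernel: int = 3
    pool_after_conv: tuple[int, ...] = (1, 3, 5)
    fc_units: tuple[int, ...] = (32, 2)
    input_side: int = 128

    def layer_table(self, scale: int = 1) -> list[tuple[str, tuple[int, ...]]]:
        """(layer type, output shape) for all 18 layers, channels first."""
        side = self.input_side
        rows: list[tuple[str, tuple[int, ...]]] = []
        for i, f in enumerate(self.filters, start=1):
            f = f // scale
            rows.append(("conv", (f, side, side)))
            rows.append(("activation", (f, side, side)))
            if i in self.pool_after_conv:
                side = -(-side // 2)  # SAME pooling: ceil(side / 2)
                rows.append(("maxpool", (f, side, side)))
        flat = rows[-1][1][0] * side * side
        rows.append(("flatten", (flat,)))
        for u in self.fc_units:
            rows.append(("fc", (u,)))
            rows.append(("activation", (u,)))
        return rows

    def flatten_width(self, scale: int = 1) -> int:
        return next(s[0] for t, s in self.layer_table(scale) if t == "flatten")

    def final_pool_side(self, scale: int = 1) -> int:
        return [s for t, s in self.layer_table(scale) if t == "maxpool"][-1][1]

    def feature_map_geometry(self, scale: int = 1) -> tuple[int, int]:
        """(n_maps, side) of the last convolution's pre-pool output."""
        convs = [s for t, s in self.layer_table(scale) if t == "conv"]
        return convs[-1][0], convs[-1][1]

    def to_dict(self) -> dict:
        return {
            "filters": list(self.filters),
            "kernel": self.kernel,
            "pool_after_conv": list(self.pool_after_conv),
            "fc_units": list(self.fc_units),
            "input_side": self.input_side,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(
            filters=tuple(d["filters"]),
            kernel=int(d["kernel"]),
            pool_after_conv=tuple(d["pool_after_conv"]),
            fc_units=tuple(d["fc_units"]),
            input_side=int(d["input_side"]),
        )


@dataclass
class TrainConfig:
    epochs: int = 45
    batch_size: int = 20
    alpha0: float = 1e-4
    split_ratio: float = 0.70
    seed: int = 0
    tumor_pixel_min: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ValidationError("split_ratio must be in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")

    def to_dict(self) -> dict:
        return {
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "alpha0": self.alpha0,
            "split_ratio": self.split_ratio,
            "seed": self.seed,
            "tumor_pixel_min": self.tumor_pixel_min,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

class _Conv3x3:
    """3x3 convolution, stride 1, SAME (zero) padding, via im2col.

    Activations flow through the network channels-last, (N, H, W, C): the
    im2col gather and the output reshape are then contiguous copies, which
    is what makes a pure-numpy conv net fast enough to train.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        k = 3
        # He-uniform: keeps signal variance stable through deep ReLU stacks
        limit = np.sqrt(6.0 / (c_in * k * k))
        self.W = rng.uniform(-limit, limit, (c_out, c_in, k, k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)  # biases start at zero
        self._col: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _w_mat(self) -> np.ndarray:
        # (C*9, F) with column order (c, ki, kj), matching the im2col layout
        return self.W.reshape(self.W.shape[0], -1).T

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (n,h,w,c,3,3)
        col = np.ascontiguousarray(win).reshape(n * h * w, c * 9)
        if keep:
            self._col = col
            self._in_shape = x.shape
        out = col @ self._w_mat() + self.b
        return out.reshape(n, h, w, -1)

    def backward(self, dout: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        n, h, w, f = dout.shape
        c = self._in_shape[3]
        dr = dout.reshape(n * h * w, f)
        # write into the preallocated buffers: the optimizer holds
        # references to these arrays
        self.dW[...] = (dr.T @ self._col).reshape(self.W.shape)
        self.db[...] = dr.sum(axis=0)
        self._col = None
        if not need_dx:  # first layer: nothing upstream consumes dx
            return None
        dcol = (dr @ self._w_mat().T).reshape(n, h, w, c, 3, 3)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=dout.dtype)
        for ki in range(3):
            for kj in range(3):
                dxp[:, ki : ki + h, kj : kj + w, :] += dcol[:, :, :, :, ki, kj]
        return dxp[:, 1 : h + 1, 1 : w + 1, :]


class _ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        out = np.maximum(x, 0)
        if keep:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool2:
    """2x2 max pool, stride 2, channels-last; spatial sizes here are even.

    The four window corners are compared as strided slices (no window
    gather); the winning corner index is kept for exact gradient routing,
    ties resolved toward the lowest corner index.
    """

    def params(self):
        return []

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        corners = (
            x[:, 0::2, 0::2, :],
            x[:, 0::2, 1::2, :],
            x[:, 1::2, 0::2, :],
            x[:, 1::2, 1::2, :],
        )
        out = np.maximum(np.maximum(corners[0], corners[1]),
                         np.maximum(corners[2], corners[3]))
        if keep:
            idx = np.zeros(out.shape, dtype=np.uint8)
            for k in (3, 2, 1):
                np.copyto(idx, k, where=(corners[k] == out) & (idx == 0))
            np.copyto(idx, 0, where=corners[0] == out)
            self._idx = idx
            self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        for k, (oi, oj) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
            np.copyto(dx[:, oi::2, oj::2, :], dout, where=self._idx == k)
        return dx


class _Flatten:
    def params(self):
        return []

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        if keep:
            self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / n_in)  # He-uniform (ReLU hidden layer)
        self.W = rng.uniform(-limit, limit, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        if keep:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        self._x = None
        return dout @ self.W.T


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# network
# --------------------------------------------------------------------------

@dataclass
class Network:
    """A realized, trainable instance of :class:`ArchitectureSpec`."""

    spec: ArchitectureSpec
    scale: int
    seed: int
    layers: list = field(repr=False, default_factory=list)
    #: index (into ``layers``) of the last conv's ReLU — the feature tap
    feature_layer: int = 0
    history: dict = field(default_factory=dict)

    def forward(
        self, x: np.ndarray, keep: bool = False, return_features: bool = False,
        post_pool_features: bool = False,
    ):
        """Class probabilities for a (N, 1, S, S) batch.

        With ``return_features`` also returns the post-ReLU maps of the last
        convolution, pre-pool by default (``post_pool_features`` flips to the
        pooled 16x16 variant).
        """
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2:] != (
            self.spec.input_side,
            self.spec.input_side,
        ):
            raise ValidationError(
                f"expected input of shape (N, 1, {self.spec.input_side}, "
                f"{self.spec.input_side}), got {x.shape}"
            )
        x = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # to channels-last
        feats = None
        for i, layer in enumerate(self.layers[:-1]):
            x = layer.forward(x, keep=keep)
            if return_features:
                if not post_pool_features and i == self.feature_layer:
                    feats = x
                elif post_pool_features and i == self.feature_layer + 1:
                    feats = x
        logits = self.layers[-1].forward(x, keep=keep)
        probs = _softmax(logits)
        if return_features:
            # back to (N, C, H, W) for the segmentation stage
            return probs, np.ascontiguousarray(feats.transpose(0, 3, 1, 2))
        return probs

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for i, layer in enumerate(reversed(self.layers)):
            if i == len(self.layers) - 1 and isinstance(layer, _Conv3x3):
                layer.backward(g, need_dx=False)
            else:
                g = layer.backward(g)

    def parameters(self):
        for layer in self.layers:
            yield from layer.params()

    # ---- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Write weights (.npz) plus a JSON sidecar with spec/scale/seed."""
        path = Path(path)
        arrays = {}
        for i, (p, _) in enumerate(self.parameters()):
            arrays[f"p{i}"] = p
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "spec": self.spec.to_dict(),
            "scale": self.scale,
            "seed": self.seed,
            "history": self.history,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        net = build_network(
            ArchitectureSpec.from_dict(sidecar["spec"]),
            scale=sidecar["scale"],
            seed=sidecar["seed"],
        )
        net.history = sidecar.get("history", {})
        with np.load(path.with_suffix(".npz")) as data:
            for i, (p, _) in enumerate(net.parameters()):
                p[...] = data[f"p{i}"]
        return net


def build_network(
    spec: ArchitectureSpec | None = None, scale: int = 1, seed: int = 0
) -> Network:
    """Instantiate the layer stack with filter counts divided by ``scale``.

    ``scale`` must be a power-of-two divisor of every filter count (1, 2, 4
    or 8 for the default stack); scale 8 is the desk-scale variant used in
    tests.  Weights are Glorot-uniform from ``seed``; biases start at zero.
    """
    spec = spec or ArchitectureSpec()
    if scale < 1 or any(f % scale for f in spec.filters):
        raise ConfigurationError(
            f"scale {scale} does not divide all filter counts {spec.filters}"
        )
    rng = np.random.default_rng(seed)
    layers: list = []
    c_in = 1
    feature_layer = 0
    for i, f in enumerate(spec.filters, start=1):
        f //= scale
        layers.append(_Conv3x3(c_in, f, rng))
        layers.append(_ReLU())
        feature_layer = len(layers) - 1  # ReLU after the (so far) last conv
        if i in spec.pool_after_conv:
            layers.append(_MaxPool2())
        c_in = f
    layers.append(_Flatten())
    # the scale divisor shrinks convolution filter counts only; the FC
    # head keeps its published widths
    n_in = spec.flatten_width(scale)
    for j, u in enumerate(spec.fc_units):
        layers.append(_Dense(n_in, u, rng))
        if j < len(spec.fc_units) - 1:
            layers.append(_ReLU())
        n_in = u
    return Network(spec=spec, scale=scale, seed=seed, layers=layers,
                   feature_layer=feature_layer)


# --------------------------------------------------------------------------
# loss, schedule, labels
# --------------------------------------------------------------------------

_EPS = 1e-7


def bce_loss(y: np.ndarray, yhat: np.ndarray) -> float:
    """Binary cross-entropy averaged over every scalar output.

    ``y`` are one-hot targets and ``yhat`` predicted scores, both (N, 2) or
    (2,).  Predictions are clipped to [1e-7, 1 - 1e-7] before the logs.
    """
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    yhat = np.atleast_2d(np.asarray(yhat, dtype=np.float64))
    if y.shape != yhat.shape:
        raise ValidationError(f"target shape {y.shape} != prediction shape {yhat.shape}")
    yhat = np.clip(yhat, _EPS, 1.0 - _EPS)
    per_sample = -(y * np.log(yhat) + (1 - y) * np.log(1 - yhat)).mean(axis=1)
    return float(per_sample.mean())


def lr_schedule(e: int, Ne: int, alpha0: float) -> float:
    """Polynomial decay alpha0 * (1 - e/Ne)^0.9; strictly decreasing, 0 at Ne."""
    if not 0 <= e <= Ne:
        raise BoundsError(f"epoch counter {e} outside 0..{Ne}")
    return float(alpha0 * (1.0 - e / Ne) ** 0.9)


def derive_labels(
    masks: Sequence[np.ndarray], tumor_pixel_min: int = 1
) -> np.ndarray:
    """Slice-level weak labels from ground-truth masks.

    label = 1 (tumor) iff the mask has at least ``tumor_pixel_min`` nonzero
    pixels — mirroring how per-slice labels are read off expert whole-tumor
    segmentations.
    """
    return np.asarray(
        [int(np.count_nonzero(m) >= tumor_pixel_min) for m in masks], dtype=int
    )


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

class _Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def stratified_split(
    labels: np.ndarray, split_ratio: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random per-class split into (train indices, held-out indices).

    Stratifying keeps both classes present in both folds even at small n,
    which a plain random 70:30 split does not guarantee.
    """
    labels = np.asarray(labels)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        k = int(round(split_ratio * len(idx)))
        train_idx.extend(idx[:k])
        test_idx.extend(idx[k:])
    return (
        rng.permutation(np.asarray(train_idx, dtype=int)),
        np.sort(np.asarray(test_idx, dtype=int)),
    )


def _one_hot(labels: np.ndarray) -> np.ndarray:
    out = np.zeros((len(labels), 2), dtype=np.float32)
    out[np.arange(len(labels)), labels] = 1.0
    return out


def _eval_in_batches(net: Network, X: np.ndarray, batch: int = 32) -> np.ndarray:
    probs = [net.forward(X[i : i + batch]) for i in range(0, len(X), batch)]
    return np.concatenate(probs, axis=0)


def train(
    net: Network,
    dataset: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
) -> Network:
    """Adam-train ``net`` on (X, labels); returns it with history attached.

    ``X`` is (N, 1, S, S) of z-scored slices, ``labels`` binary ints.  The
    data are split ``split_ratio`` : rest (stratified, seeded); each epoch
    uses the learning rate ``lr_schedule(e, epochs, alpha0)`` and reshuffled
    mini-batches of ``batch_size``.  History records per-epoch lr and
    train/validation loss and accuracy.  Deterministic given cfg.seed.
    """
    X, labels = dataset
    X = np.asarray(X, dtype=np.float32)
    labels = np.asarray(labels, dtype=int)
    if len(X) != len(labels):
        raise ValidationError("X and labels length mismatch")
    if len(np.unique(labels)) < 2:
        raise ValidationError("training requires both classes present")

    rng = np.random.default_rng(cfg.seed)
    tr_idx, va_idx = stratified_split(labels, cfg.split_ratio, rng)
    Xtr, ytr = X[tr_idx], labels[tr_idx]
    Xva, yva = X[va_idx], labels[va_idx]
    Ytr = _one_hot(ytr)

    opt = _Adam(net.parameters())
    hist = {k: [] for k in
            ("epoch", "lr", "train_loss", "train_acc", "val_loss", "val_acc")}

    for e in range(cfg.epochs):
        lr = lr_schedule(e, cfg.epochs, cfg.alpha0)
        order = rng.permutation(len(Xtr))
        losses, hits, seen = [], 0, 0
        for start in range(0, len(Xtr), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb, yb = Xtr[sel], Ytr[sel]
            probs = net.forward(xb, keep=True)
            loss = bce_loss(yb, probs)
            if not np.isfinite(loss):
                raise DivergenceError(e)
            losses.append(loss * len(sel))
            hits += int((probs.argmax(axis=1) == yb.argmax(axis=1)).sum())
            seen += len(sel)
            # two-class BCE of a softmax pair reduces to categorical CE,
            # so d loss / d logits = (probs - targets) / batch
            net.backward((probs - yb).astype(np.float32) / len(sel))
            opt.step(lr)
        va_probs = _eval_in_batches(net, Xva)
        hist["epoch"].append(e)
        hist["lr"].append(lr)
        hist["train_loss"].append(sum(losses) / seen)
        hist["train_acc"].append(hits / seen)
        hist["val_loss"].append(bce_loss(_one_hot(yva), va_probs))
        hist["val_acc"].append(float((va_probs.argmax(axis=1) == yva).mean()))
    net.history = hist
    net.split_indices = {"train": tr_idx.tolist(), "val": va_idx.tolist()}
    return net


# --------------------------------------------------------------------------
# inference and scoring
# --------------------------------------------------------------------------

@dataclass
class FeatureStack:
    """Post-ReLU maps of the last convolution layer (32 x 32x32 at scale 1)."""

    maps: np.ndarray  # (n_maps, side, side), values >= 0

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 3 or self.maps.shape[1] != self.maps.shape[2]:
            raise ValidationError(
                f"feature stack must be (n, s, s), got {self.maps.shape}"
            )
        if (self.maps < 0).any():
            raise ValidationError("feature maps must be non-negative (post-ReLU)")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    @property
    def side(self) -> int:
        return self.maps.shape[1]


def classify(
    net: Network, s: Slice2D, post_pool_features: bool = False
) -> tuple[str, float, FeatureStack]:
    """(label, winning score, feature stack) for one prepared slice.

    The slice must already be resized to the network input side and
    z-scored.  The feature stack defaults to the pre-pool 32x32 maps; set
    ``post_pool_features`` for the pooled 16x16 variant.
    """
    x = s.pixels[None, None, :, :]
    probs, feats = net.forward(
        x, return_features=True, post_pool_features=post_pool_features
    )
    cls = int(probs[0].argmax())
    return LABEL_NAMES[cls], float(probs[0, cls]), FeatureStack(maps=feats[0])


def classification_metrics(
    preds: Sequence[int], labels: Sequence[int]
) -> tuple[float | None, float | None, float]:
    """(precision, recall, accuracy) over binary predictions.

    A zero denominator (e.g. no positive predictions) yields ``None`` for
    that ratio rather than a silent 0.
    """
    preds = np.asarray(preds, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if preds.size == 0:
        raise ValidationError("empty prediction list")
    if preds.shape != labels.shape:
        raise ValidationError("preds and labels length mismatch")
    tp = int(((preds == 1) & (labels == 1)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    accuracy = (tp + tn) / len(preds)
    return precision, recall, accuracy


def roc_points(
    scores: Sequence[float], labels: Sequence[int]
) -> list[tuple[float, float]]:
    """(FPR, TPR) staircase over every distinct score threshold.

    Points run from (0, 0) (threshold above every score) to (1, 1)
    (everything predicted positive), sorted by FPR then TPR.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    points = [(0.0, 0.0)]
    for t in np.unique(scores)[::-1]:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        points.append(
            (fp / n_neg if n_neg else 0.0, tp / n_pos if n_pos else 0.0)
        )
    return sorted(set(points))
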