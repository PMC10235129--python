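"""The phase-classification CNN and its loss functions.

The classifier is a deliberately compact 9-layer network: an input layer,
three 3x3 valid convolutions each followed by a 2x2 max-pool, one hidden
dense layer and an output layer (sigmoid for the binary task, softmax for
the 3-class task). ReLU follows every convolution and the hidden dense
layer; there is no dropout — regularisation comes from the loss and from
data augmentation. On the default 150x150x1 input the spatial trace is
150 -> 148 -> 74 -> 72 -> 36 -> 34 -> 17, and every 2x2 pool discards 75%
of the activations of an even-dimensioned feature map.

The training objective is a regularised mean squared error

    L(chi, M) = MSE(chi, M) + beta * mean(chi, M)

where ``MSE = (1/n) sum (tau(x_i) - M(x_i))^2`` and ``mean`` is the signed
mean residual ``(1/n) sum (tau(x_i) - M(x_i))``, scaled by a hyperparameter
``beta > 0``. The signed second term rewards over-prediction and penalises
under-prediction relative to plain MSE; it is implemented exactly as
defined (the loss may be negative under systematic over-prediction), with
an optional absolute-mean variant for ablations. Baselines (MSE, MAE,
cross-entropy, L1/L2 weight regularisers) are provided for the loss
comparison harness.

Everything here — forward pass, analytic gradients, Adam — is implemented
directly on NumPy arrays with im2col/GEMM convolutions, which keeps runs
bit-reproducible on CPU for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .errors import ConfigError, DomainError

__all__ = [
    "ModelConfig", "LossConfig", "LabeledBatch", "PhaseNet", "build_model",
    "mse", "mean_error", "custom_loss", "baseline_loss", "loss_and_grad",
    "average_abs_weight", "layer_average_abs_weights", "save_model",
    "load_model", "Adam", "LAYER_NAMES",
]

LAYER_NAMES = ("input", "conv1", "pool1", "conv2", "pool2", "conv3", "pool3",
               "dense", "output")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``n_classes=2`` yields a single sigmoid output unit scored against 0/1
    labels; ``n_classes=3`` yields a 3-way softmax scored against one-hot
    rows. Filter counts default to a doubling ladder (32/64/128) with a
    128-wide hidden dense layer.
    """

    input_shape: tuple[int, int, int] = (150, 150, 1)
    conv_filters: tuple[int, int, int] = (32, 64, 128)
    kernel: tuple[int, int] = (3, 3)
    pool: tuple[int, int] = (2, 2)
    dense_width: int = 128
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 3):
            raise ConfigError(f"n_classes must be 2 or 3, got {self.n_classes}")
        if len(self.conv_filters) != 3 or any(f < 1 for f in self.conv_filters):
            raise ConfigError("conv_filters must list 3 positive counts")
        if self.dense_width < 1:
            raise ConfigError("dense_width must be >= 1")
        h, w, c = self.input_shape
        if h <= 0 or w <= 0 or c <= 0:
            raise ConfigError("input_shape entries must be positive")
        # verify the valid-conv / pool shape arithmetic stays positive
        for _ in self.spatial_trace():
            pass

    @property
    def output_activation(self) -> str:
        return "sigmoid" if self.n_classes == 2 else "softmax"

    @property
    def n_output_units(self) -> int:
        return 1 if self.n_classes == 2 else self.n_classes

    def spatial_trace(self) -> list[tuple[int, int]]:
        """Feature-map sizes after each conv and pool stage."""
        kh, kw = self.kernel
        ph, pw = self.pool
        h, w, _ = self.input_shape
        trace = []
        for _ in range(3):
            h, w = h - kh + 1, w - kw + 1
            if h <= 0 or w <= 0:
                raise ConfigError("input too small for three conv/pool stages")
            trace.append((h, w))
            h, w = h // ph, w // pw
            if h <= 0 or w <= 0:
                raise ConfigError("input too small for three conv/pool stages")
            trace.append((h, w))
        return trace


@dataclass(frozen=True)
class LossConfig:
    """Choice of training objective.

    ``kind="custom"`` is the regularised MSE with hyperparameter ``beta``;
    the others are the ablation baselines. ``weight_regularizer`` adds an
    L1 or L2 penalty of the given strength on all conv/dense kernels
    (biases excluded) to whichever data term is configured.
    """

    kind: str = "custom"
    beta: float = 0.1
    weight_regularizer: str = "none"
    regularizer_strength: float = 0.1
    mean_mode: str = "signed"

    def __post_init__(self) -> None:
        if self.kind not in ("custom", "mse", "mae", "cross_entropy"):
            raise ConfigError(f"unknown loss kind {self.kind!r}")
        if self.kind == "custom" and not self.beta > 0:
            raise ConfigError("custom loss requires beta > 0")
        if self.weight_regularizer not in ("none", "L1", "L2"):
            raise ConfigError("weight_regularizer must be none, L1 or L2")
        if self.mean_mode not in ("signed", "abs"):
            raise ConfigError("mean_mode must be 'signed' or 'abs'")


@dataclass(frozen=True)
class LabeledBatch:
    """True labels and model scores for ``n`` instances.

    ``y_true`` holds 0/1 labels (or one-hot rows for the 3-class task) and
    ``y_pred`` the model outputs in [0, 1], with matching shapes.
    """

    y_true: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.y_true, dtype=np.float64)
        p = np.asarray(self.y_pred, dtype=np.float64)
        if t.shape != p.shape:
            raise DomainError(f"shape mismatch {t.shape} vs {p.shape}")
        if t.size == 0:
            raise DomainError("empty batch")
        if p.min() < 0 or p.max() > 1:
            raise DomainError("predictions must lie in [0, 1]")
        object.__setattr__(self, "y_true", t)
        object.__setattr__(self, "y_pred", p)

    @property
    def n(self) -> int:
        return self.y_true.shape[0]


def _batch(y_true, y_pred=None) -> LabeledBatch:
    if isinstance(y_true, LabeledBatch):
        return y_true
    return LabeledBatch(y_true, y_pred)


# ---------------------------------------------------------------------------
# loss functions (values averaged over every label element: over classes
# first, then instances, which for one-hot rows equals a flat mean)


def mse(y_true, y_pred=None) -> float:
    """Mean squared error ``(1/n) sum (tau(x_i) - M(x_i))^2``."""
    b = _batch(y_true, y_pred)
    return float(np.mean((b.y_true - b.y_pred) ** 2))


def mean_error(y_true, y_pred=None) -> float:
    """Signed mean residual ``(1/n) sum (tau(x_i) - M(x_i))``; may be negative."""
    b = _batch(y_true, y_pred)
    return float(np.mean(b.y_true - b.y_pred))


def custom_loss(y_true, y_pred=None, *, beta: float = 0.1,
                mean_mode: str = "signed") -> float:
    """Regularised MSE: ``mse + beta * mean_error`` (beta > 0 required)."""
    if not beta > 0:
        raise ConfigError(f"beta must be > 0, got {beta}")
    b = _batch(y_true, y_pred)
    m = mean_error(b)
    if mean_mode == "abs":
        m = abs(m)
    return mse(b) + beta * m


def baseline_loss(y_true, y_pred=None, *, kind: str = "mse",
                  eps: float = 1e-7) -> float:
    """Standard comparison losses: ``mse``, ``mae`` or ``cross_entropy``.

    Cross-entropy clips predictions to ``(eps, 1-eps)`` before the log;
    for one-hot rows it is the categorical form averaged over instances,
    otherwise the binary form.
    """
    b = _batch(y_true, y_pred)
    t, p = b.y_true, b.y_pred
    if kind == "mse":
        return mse(b)
    if kind == "mae":
        return float(np.mean(np.abs(t - p)))
    if kind == "cross_entropy":
        p = np.clip(p, eps, 1.0 - eps)
        if t.ndim == 2 and t.shape[1] > 1:
            return float(np.mean(-np.sum(t * np.log(p), axis=1)))
        return float(np.mean(-(t * np.log(p) + (1 - t) * np.log(1 - p))))
    raise ConfigError(f"unknown baseline loss kind {kind!r}")


def loss_and_grad(cfg: LossConfig, y_true: np.ndarray,
                  y_pred: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss value and its analytic gradient with respect to ``y_pred``.

    For the custom loss the per-element gradient is
    ``-2 (tau - M) / size - beta / size`` with ``size`` the number of label
    elements. The weight-regularizer term (if any) is handled by the
    trainer, not here.
    """
    t = np.asarray(y_true, dtype=y_pred.dtype)
    p = y_pred
    size = p.size
    if cfg.kind == "custom":
        resid = t - p
        m = float(resid.mean())
        if cfg.mean_mode == "abs":
            value = float(np.mean(resid ** 2)) + cfg.beta * abs(m)
            grad = (-2.0 * resid - cfg.beta * np.sign(m)) / size
        else:
            value = float(np.mean(resid ** 2)) + cfg.beta * m
            grad = (-2.0 * resid - cfg.beta) / size
        return value, grad
    if cfg.kind == "mse":
        resid = t - p
        return float(np.mean(resid ** 2)), -2.0 * resid / size
    if cfg.kind == "mae":
        resid = t - p
        return float(np.mean(np.abs(resid))), -np.sign(resid) / size
    if cfg.kind == "cross_entropy":
        eps = 1e-7
        pc = np.clip(p, eps, 1.0 - eps)
        if t.ndim == 2 and t.shape[1] > 1:
            value = float(np.mean(-np.sum(t * np.log(pc), axis=1)))
            grad = -(t / pc) / t.shape[0]
        else:
            value = float(np.mean(-(t * np.log(pc) + (1 - t) * np.log(1 - pc))))
            grad = (-(t / pc) + (1 - t) / (1 - pc)) / size
        return value, grad.astype(p.dtype)
    raise ConfigError(f"unknown loss kind {cfg.kind!r}")


# ---------------------------------------------------------------------------
# layers


class _Conv2D:
    """3x3 valid convolution + ReLU, via im2col and a single GEMM.

    The im2col buffer is laid out ``(kh, kw, channel)`` per output pixel so
    the gather (forward) and scatter-add (backward) move contiguous
    channel blocks, which keeps the layer memory-bandwidth friendly.
    """

    def __init__(self, name: str, in_ch: int, out_ch: int,
                 kernel: tuple[int, int], rng: np.random.Generator,
                 need_input_grad: bool = True):
        self.name = name
        kh, kw = kernel
        self.kernel = kernel
        self.need_input_grad = need_input_grad
        fan_in, fan_out = kh * kw * in_ch, kh * kw * out_ch
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit, (kh * kw * in_ch, out_ch)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        kh, kw = self.kernel
        n, h, w, c = x.shape
        ho, wo = h - kh + 1, w - kw + 1
        if c == 1:
            win = np.lib.stride_tricks.sliding_window_view(
                x[..., 0], (kh, kw), axis=(1, 2))
            col = np.ascontiguousarray(win)
        else:
            col = np.empty((n, ho, wo, kh, kw, c), dtype=x.dtype)
            for i in range(kh):
                for j in range(kw):
                    col[:, :, :, i, j, :] = x[:, i:i + ho, j:j + wo, :]
        col = col.reshape(n * ho * wo, kh * kw * c)
        z = col @ self.W + self.b
        out = np.maximum(z, 0.0)
        if train:
            self._cache = (col, z > 0, (n, h, w, c, ho, wo))
        return out.reshape(n, ho, wo, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        col, mask, (n, h, w, c, ho, wo) = self._cache
        kh, kw = self.kernel
        dz = dout.reshape(n * ho * wo, -1) * mask
        self.dW = col.T @ dz
        self.db = dz.sum(axis=0)
        self._cache = None
        if not self.need_input_grad:
            return np.zeros((n, h, w, c), dtype=dout.dtype)
        dcol = (dz @ self.W.T).reshape(n, ho, wo, kh, kw, c)
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        for i in range(kh):
            for j in range(kw):
                dx[:, i:i + ho, j:j + wo, :] += dcol[:, :, :, i, j, :]
        return dx

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class _MaxPool2D:
    """Non-overlapping max pooling; a (2,2) window keeps 1 of 4 activations."""

    def __init__(self, name: str, pool: tuple[int, int]):
        self.name = name
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        ph, pw = self.pool
        n, h, w, c = x.shape
        hp, wp = h // ph, w // pw
        out = x[:, 0:hp * ph:ph, 0:wp * pw:pw, :].copy()
        for i in range(ph):
            for j in range(pw):
                if i == 0 and j == 0:
                    continue
                np.maximum(out, x[:, i:hp * ph:ph, j:wp * pw:pw, :], out=out)
        if train:
            self._cache = (x, out, (n, h, w, c, hp, wp))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, out, (n, h, w, c, hp, wp) = self._cache
        ph, pw = self.pool
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        # route each cell's gradient to the first position attaining the max
        taken = np.zeros(out.shape, dtype=bool)
        for i in range(ph):
            for j in range(pw):
                hit = (x[:, i:hp * ph:ph, j:wp * pw:pw, :] == out) & ~taken
                dx[:, i:hp * ph:ph, j:wp * pw:pw, :] = np.where(hit, dout, 0.0)
                taken |= hit
        self._cache = None
        return dx

    def params(self):
        return {}

    def grads(self):
        return {}


class _Dense:
    def __init__(self, name: str, n_in: int, n_out: int, relu: bool,
                 rng: np.random.Generator):
        self.name = name
        self.relu = relu
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        z = x @ self.W + self.b
        out = np.maximum(z, 0.0) if self.relu else z
        if train:
            self._cache = (x, (z > 0) if self.relu else None)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, mask = self._cache
        dz = dout * mask if mask is not None else dout
        self.dW = x.T @ dz
        self.db = dz.sum(axis=0)
        self._cache = None
        return dz @ self.W.T

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


# ---------------------------------------------------------------------------
# the model


class PhaseNet:
    """The 9-layer phase classifier (see module docstring).

    Named layers: input, conv1, pool1, conv2, pool2, conv3, pool3, dense,
    output. Flatten between pool3 and dense is index plumbing, not a layer.
    Weights are Glorot-uniform initialised from ``seed``.
    """

    layer_names = LAYER_NAMES

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        h, w, c = cfg.input_shape
        f1, f2, f3 = cfg.conv_filters
        trace = cfg.spatial_trace()
        flat = trace[-1][0] * trace[-1][1] * f3
        self.conv1 = _Conv2D("conv1", c, f1, cfg.kernel, rng,
                             need_input_grad=False)
        self.pool1 = _MaxPool2D("pool1", cfg.pool)
        self.conv2 = _Conv2D("conv2", f1, f2, cfg.kernel, rng)
        self.pool2 = _MaxPool2D("pool2", cfg.pool)
        self.conv3 = _Conv2D("conv3", f2, f3, cfg.kernel, rng)
        self.pool3 = _MaxPool2D("pool3", cfg.pool)
        self.dense = _Dense("dense", flat, cfg.dense_width, relu=True, rng=rng)
        self.output = _Dense("output", cfg.dense_width, cfg.n_output_units,
                             relu=False, rng=rng)
        self._stack = [self.conv1, self.pool1, self.conv2, self.pool2,
                       self.conv3, self.pool3, self.dense, self.output]

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Class probabilities for a batch ``(N, H, W, C)`` in [0, 1]."""
        h, w, c = self.cfg.input_shape
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1:] != (h, w, c):
            raise DomainError(f"expected input {(h, w, c)}, got {x.shape[1:]}")
        out = x
        for layer in self._stack[:-2]:
            out = layer.forward(out, train)
        out = out.reshape(out.shape[0], -1)
        out = self.dense.forward(out, train)
        logits = self.output.forward(out, train)
        if self.cfg.output_activation == "sigmoid":
            probs = 1.0 / (1.0 + np.exp(-logits))
        else:
            shifted = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(shifted)
            probs = e / e.sum(axis=1, keepdims=True)
        if train:
            self._probs = probs
            self._pool3_shape = self.pool3_out_shape
        return probs

    @property
    def pool3_out_shape(self) -> tuple[int, int, int]:
        (h, w) = self.cfg.spatial_trace()[-1]
        return (h, w, self.cfg.conv_filters[-1])

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probabilities."""
        p = self._probs
        if self.cfg.output_activation == "sigmoid":
            dlogits = dprobs * p * (1.0 - p)
        else:
            dot = np.sum(dprobs * p, axis=1, keepdims=True)
            dlogits = p * (dprobs - dot)
        d = self.output.backward(dlogits.astype(np.float32))
        d = self.dense.backward(d)
        d = d.reshape(d.shape[0], *self._pool3_shape)
        for layer in reversed(self._stack[:-2]):
            d = layer.backward(d)

    # -- parameter access ---------------------------------------------------

    def parameters(self) -> Iterator[tuple[str, str, np.ndarray]]:
        for layer in self._stack:
            for key, arr in layer.params().items():
                yield layer.name, key, arr

    def gradients(self) -> Iterator[tuple[str, str, np.ndarray]]:
        for layer in self._stack:
            for key, arr in layer.grads().items():
                yield layer.name, key, arr

    def kernels(self) -> Iterator[tuple[str, np.ndarray]]:
        """Conv/dense weight matrices (no biases), for weight regularizers."""
        for layer in self._stack:
            p = layer.params()
            if "W" in p:
                yield layer.name, p["W"]

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [self.forward(x[i:i + batch_size])
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def n_parameters(self) -> int:
        return sum(arr.size for _, _, arr in self.parameters())


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> PhaseNet:
    """Construct a freshly initialised classifier from ``cfg`` (defaults
    to the standard 150x150x1, 32/64/128-filter configuration)."""
    return PhaseNet(cfg or ModelConfig(), seed=seed)


def average_abs_weight(model: PhaseNet) -> float:
    """Mean absolute value over every trainable weight of the model, the
    convergence diagnostic tracked across epochs."""
    total, count = 0.0, 0
    for _, _, arr in model.parameters():
        total += float(np.abs(arr).sum())
        count += arr.size
    return total / count


def layer_average_abs_weights(model: PhaseNet) -> dict[str, float]:
    """Per-layer mean |weight| (kernel + bias), for convergence exports."""
    out = {}
    for layer in model._stack:
        arrs = list(layer.params().values())
        if arrs:
            total = sum(float(np.abs(a).sum()) for a in arrs)
            count = sum(a.size for a in arrs)
            out[layer.name] = total / count
    return out


def save_model(model: PhaseNet, path) -> None:
    """Save weights and architecture to an ``.npz`` checkpoint."""
    import json

    arrays = {f"{ln}__{k}": a for ln, k, a in model.parameters()}
    cfg = model.cfg
    meta = json.dumps({
        "input_shape": list(cfg.input_shape),
        "conv_filters": list(cfg.conv_filters),
        "kernel": list(cfg.kernel), "pool": list(cfg.pool),
        "dense_width": cfg.dense_width, "n_classes": cfg.n_classes,
    })
    np.savez(path, __config__=np.array(meta), **arrays)


def load_model(path) -> PhaseNet:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    import json

    with np.load(path) as data:
        meta = json.loads(str(data["__config__"]))
        cfg = ModelConfig(
            input_shape=tuple(meta["input_shape"]),
            conv_filters=tuple(meta["conv_filters"]),
            kernel=tuple(meta["kernel"]), pool=tuple(meta["pool"]),
            dense_width=meta["dense_width"], n_classes=meta["n_classes"])
        model = PhaseNet(cfg, seed=0)
        for layer in model._stack:
            for k in list(layer.params()):
                setattr(layer, k, data[f"{layer.name}__{k}"].copy())
    return model


class Adam:
    """Adam optimiser with the standard bias-corrected moments."""

    def __init__(self, model: PhaseNet, learning_rate: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = {(ln, k): np.zeros_like(a) for ln, k, a in model.parameters()}
        self._v = {(ln, k): np.zeros_like(a) for ln, k, a in model.parameters()}

    def step(self, model: PhaseNet) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        params = {(ln, k): a for ln, k, a in model.parameters()}
        for (ln, k), g in (((ln, k), a) for ln, k, a in model.gradients()):
            key = (ln, k)
            m = self._m[key] = b1 * self._m[key] + (1 - b1) * g
            v = self._v[key] = b2 * self._v[key] + (1 - b2) * (g * g)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            params[key] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                params[key].dtype)
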