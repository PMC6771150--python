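"""Convolutional-network model selection and parameter estimation.

The network is a small Flagel-style image classifier implemented directly
on NumPy: two 3x3 convolution layers with rectified-linear activations,
each followed by 2x2 max-pooling, a dense hidden layer, and a softmax
(classification) or linear (regression) head, trained with Adam on
mini-batches.  All randomness (weight initialization, shuffling) is
driven by a single seed, so training is bit-reproducible on a fixed BLAS
configuration.

Regression targets (Ne, DT, founder ratio, growth ratio) are min-max
normalized to [0, 1] over their prior ranges, so RMSE values are
scale-comparable across parameters; predictions are de-normalized back
to natural units for reporting.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import spearmanr

from .simulate import PriorConfig

__all__ = [
    "NetConfig",
    "ConvNet",
    "ModelSelectionResult",
    "ParamEstimate",
    "ParamNormalizer",
    "PARAM_NAMES",
    "train_classifier",
    "evaluate_classifier",
    "select_model",
    "train_regressor",
    "score_regression",
    "estimate_params",
]

PARAM_NAMES = ("ne", "dt", "founder_ratio", "growth_ratio")


@dataclass(frozen=True)
class NetConfig:
    """Training protocol and architecture record."""

    epochs: int = 25
    batch_size: int = 250
    architecture: str = "conv1d"         # or "conv2d"
    conv_filters: tuple[int, int] = (64, 64)
    kernel_size: int = 3
    pool_sizes: tuple[tuple[int, int], tuple[int, int]] = ((1, 2), (1, 2))
    pool_type: str = "max"               # or "avg" (conv1d only)
    readout: str = "flatten"             # or "gap" (conv1d only): global
                                         # average pool over sites before the
                                         # dense head (site-order invariant)
    dense_units: int = 128
    dropout: float = 0.5                 # dense-layer dropout rate
    conv_dropout: float = 0.25           # after-pool dropout rate
    learning_rate: float = 1e-3
    lr_schedule: str = "cosine"          # or "constant"
    loss_weights: tuple[float, ...] | None = None   # per-output (regression)
    weight_decay: float = 0.0            # decoupled (AdamW-style)
    task: str = "classify"               # or "regress"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.task not in ("classify", "regress"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.architecture not in ("conv1d", "conv2d"):
            raise ValueError(f"unknown architecture {self.architecture!r}")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Conv:
    """kxk same-padding convolution, stride 1.

    Implemented as a sum of k*k shifted (N*H*W, C_in) @ (C_in, C_out)
    matmuls rather than one big im2col product: with the few channels used
    here this keeps memory traffic k*k times smaller and is markedly
    faster on one CPU.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, dtype):
        fan_in = k * k * c_in
        self.w = (rng.standard_normal((k, k, c_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.k = k

    @staticmethod
    def _offsets(k: int):
        p = k // 2
        for di in range(k):
            for dj in range(k):
                yield di, dj, di - p, dj - p

    @staticmethod
    def _shift_slices(oi: int, oj: int, h: int, w: int):
        """Slices s.t. out[dst] += in[src] realises a shift by (oi, oj)."""
        src_i = slice(max(0, oi), min(h, h + oi))
        dst_i = slice(max(0, -oi), min(h, h - oi))
        src_j = slice(max(0, oj), min(w, w + oj))
        dst_j = slice(max(0, -oj), min(w, w - oj))
        return (src_i, src_j), (dst_i, dst_j)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        self._x = x
        y = np.empty((n, h, w, self.w.shape[-1]), dtype=x.dtype)
        y[...] = self.b
        for di, dj, oi, oj in self._offsets(self.k):
            (si, sj), (ti, tj) = self._shift_slices(oi, oj, h, w)
            y[:, ti, tj] += x[:, si, sj] @ self.w[di, dj]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, h, w, c = x.shape
        self.dw = np.empty_like(self.w)
        self.db = dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        dx = np.zeros_like(x)
        for di, dj, oi, oj in self._offsets(self.k):
            (si, sj), (ti, tj) = self._shift_slices(oi, oj, h, w)
            xs = x[:, si, sj].reshape(-1, c)
            dys = dy[:, ti, tj].reshape(-1, dy.shape[-1])
            self.dw[di, dj] = xs.T @ dys
            dx[:, si, sj] += (dys @ self.w[di, dj].T).reshape(x[:, si, sj].shape)
        return dx

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class _MaxPool:
    """ph x pw max pooling (floor semantics: trailing remainder dropped).

    Ties resolve to the first maximum, which keeps the backward pass a
    single scatter.
    """

    def __init__(self, ph: int = 2, pw: int = 2):
        self.ph, self.pw = ph, pw

    def forward(self, x):
        n, h, w, c = x.shape
        ph, pw = self.ph, self.pw
        h2, w2 = h // ph, w // pw
        self._in_shape = x.shape
        xc = x[:, : ph * h2, : pw * w2, :]
        xc = xc.reshape(n, h2, ph, w2, pw, c).transpose(0, 1, 3, 2, 4, 5)
        xc = xc.reshape(n, h2, w2, ph * pw, c)
        self._idx = xc.argmax(axis=3)
        return np.take_along_axis(xc, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dy):
        n, h, w, c = self._in_shape
        ph, pw = self.ph, self.pw
        h2, w2 = h // ph, w // pw
        dxc = np.zeros((n, h2, w2, ph * pw, c), dtype=dy.dtype)
        np.put_along_axis(dxc, self._idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dxc = dxc.reshape(n, h2, w2, ph, pw, c).transpose(0, 1, 3, 2, 4, 5)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : ph * h2, : pw * w2, :] = dxc.reshape(n, ph * h2, pw * w2, c)
        return dx

    def params(self):
        return []


class _AvgPool1D:
    """Width-p mean pooling along the site axis; preserves composition
    (count-type) information that max pooling discards."""

    def __init__(self, p: int = 2):
        self.p = p

    def forward(self, x):
        n, length, c = x.shape
        l2 = length // self.p
        self._in_shape = x.shape
        return x[:, : l2 * self.p].reshape(n, l2, self.p, c).mean(axis=2)

    def backward(self, dy):
        n, length, c = self._in_shape
        l2 = length // self.p
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : l2 * self.p] = np.repeat(dy / self.p, self.p, axis=1)
        return dx

    def params(self):
        return []


class _GlobalAvgPool1D:
    """Mean over the whole site axis: (N, L, C) -> (N, C).

    Makes the head invariant to site order, matching the exchangeability
    of unlinked SNPs."""

    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=1)

    def backward(self, dy):
        n, length, c = self._in_shape
        return np.broadcast_to(dy[:, None, :] / length, self._in_shape).astype(dy.dtype)

    def params(self):
        return []


class _ToSequence:
    """(N, H, W, C) image -> (N, W, H*C) sequence: individuals (and any
    extra channels) become per-site channels for 1-D convolution along
    the SNP axis."""

    def forward(self, x):
        n, h, w, c = x.shape
        self._shape = x.shape
        return np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(n, w, h * c)

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.ascontiguousarray(dy.reshape(n, w, h, c).transpose(0, 2, 1, 3))

    def params(self):
        return []


class _Conv1D:
    """k-wide same-padding 1-D convolution along the site axis."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, dtype):
        fan_in = k * c_in
        self.w = (rng.standard_normal((k, c_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.k = k

    def forward(self, x):
        n, length, c = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        # k-major patch matrix built from shifted views; one copy total
        cols = np.concatenate([xp[:, o: o + length] for o in range(k)], axis=2)
        cols = cols.reshape(n * length, k * c)
        self._cols = cols
        self._in_shape = x.shape
        y = cols @ self.w.reshape(k * c, -1) + self.b
        return y.reshape(n, length, -1)

    def backward(self, dy):
        n, length, c = self._in_shape
        k, p = self.k, self.k // 2
        f = dy.shape[-1]
        dyf = dy.reshape(-1, f)
        self.dw = (self._cols.T @ dyf).reshape(self.w.shape)
        self.db = dyf.sum(axis=0)
        dcols = (dyf @ self.w.reshape(k * c, f).T).reshape(n, length, k, c)
        dxp = np.zeros((n, length + 2 * p, c), dtype=dy.dtype)
        for o in range(k):
            dxp[:, o: o + length] += dcols[:, :, o]
        return dxp[:, p: p + length]

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class _MaxPool1D:
    """Width-p max pooling along the site axis (first-max tie-break)."""

    def __init__(self, p: int = 2):
        self.p = p

    def forward(self, x):
        n, length, c = x.shape
        l2 = length // self.p
        self._in_shape = x.shape
        xc = x[:, : l2 * self.p].reshape(n, l2, self.p, c)
        if self.p == 2:
            m0, m1 = xc[:, :, 0], xc[:, :, 1]
            self._mask1 = m1 > m0
            return np.where(self._mask1, m1, m0)
        self._idx = xc.argmax(axis=2)
        return np.take_along_axis(xc, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        n, length, c = self._in_shape
        l2 = length // self.p
        dxc = np.zeros((n, l2, self.p, c), dtype=dy.dtype)
        if self.p == 2:
            dxc[:, :, 1] = dy * self._mask1
            dxc[:, :, 0] = dy - dxc[:, :, 1]
        else:
            np.put_along_axis(dxc, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : l2 * self.p] = dxc.reshape(n, l2 * self.p, c)
        return dx

    def params(self):
        return []


class _Dropout:
    """Inverted dropout; active only while the owning net is training."""

    def __init__(self, rate: float, rng: np.random.Generator, mode_flag: dict):
        self.rate = rate
        self.rng = rng
        self._mode = mode_flag

    def forward(self, x):
        if not self._mode["training"] or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def params(self):
        return []


class _Flatten:
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype):
        self.w = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ConvNet:
    """conv-pool-conv-pool-dense network with a softmax or linear head."""

    def __init__(self, input_shape: tuple[int, int, int], n_outputs: int,
                 config: NetConfig, dtype=np.float32):
        self.config = config
        self.input_shape = tuple(input_shape)
        self.n_outputs = n_outputs
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(config.rng_seed)
        h, w, c = input_shape
        f1, f2 = config.conv_filters
        k = config.kernel_size
        (p1h, p1w), (p2h, p2w) = config.pool_sizes
        self._mode = {"training": False}
        drop_rng = np.random.default_rng(config.rng_seed + 2)

        def drop(rate):
            return _Dropout(rate, drop_rng, self._mode)

        if config.architecture == "conv1d":
            w_out = (w // p1w) // p2w
            if w_out < 1:
                raise ValueError("input too narrow for the configured pooling")
            pool_cls = _AvgPool1D if config.pool_type == "avg" else _MaxPool1D
            if config.readout == "gap":
                readout_layers = [_GlobalAvgPool1D()]
                dense_in = f2
            else:
                readout_layers = [_Flatten()]
                dense_in = w_out * f2
            self.layers = [
                _ToSequence(),
                _Conv1D(h * c, f1, k, rng, self.dtype), _ReLU(), pool_cls(p1w),
                drop(config.conv_dropout),
                _Conv1D(f1, f2, k, rng, self.dtype), _ReLU(), pool_cls(p2w),
                drop(config.conv_dropout),
                *readout_layers,
                _Dense(dense_in, config.dense_units, rng, self.dtype),
                _ReLU(),
                drop(config.dropout),
                _Dense(config.dense_units, n_outputs, rng, self.dtype),
            ]
        else:
            h_out = (h // p1h) // p2h
            w_out = (w // p1w) // p2w
            if h_out < 1 or w_out < 1:
                raise ValueError("input too small for the configured pooling")
            self.layers = [
                _Conv(c, f1, k, rng, self.dtype), _ReLU(), _MaxPool(p1h, p1w),
                drop(config.conv_dropout),
                _Conv(f1, f2, k, rng, self.dtype), _ReLU(), _MaxPool(p2h, p2w),
                drop(config.conv_dropout),
                _Flatten(),
                _Dense(h_out * w_out * f2, config.dense_units, rng, self.dtype),
                _ReLU(),
                drop(config.dropout),
                _Dense(config.dense_units, n_outputs, rng, self.dtype),
            ]
        self._adam_state: dict[int, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        self._adam_t = 0

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x.astype(self.dtype, copy=False)
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def predict(self, x: np.ndarray, batch_size: int = 250) -> np.ndarray:
        """Head outputs (softmax probabilities or raw regression values)."""
        outs = []
        for i in range(0, x.shape[0], batch_size):
            z = self.forward(x[i: i + batch_size])
            outs.append(_softmax(z) if self.config.task == "classify" else z)
        return np.concatenate(outs, axis=0)

    def _loss_grad(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """One forward/backward pass; returns (loss, accuracy-or-0)."""
        z = self.forward(x)
        n = x.shape[0]
        if self.config.task == "classify":
            p = _softmax(z)
            loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
            acc = float((p.argmax(axis=1) == y).mean())
            dz = (p - np.eye(self.n_outputs, dtype=self.dtype)[y]) / n
        else:
            diff = z - y
            if self.config.loss_weights is not None:
                w = np.asarray(self.config.loss_weights, dtype=self.dtype)
                loss = float((w * diff ** 2).mean())
                dz = 2.0 * w * diff / diff.size
            else:
                loss = float((diff ** 2).mean())
                dz = 2.0 * diff / diff.size
            acc = 0.0
        dz = dz.astype(self.dtype)
        for layer in reversed(self.layers):
            dz = layer.backward(dz)
        return loss, acc

    def _adam_step(self, lr_scale: float = 1.0) -> None:
        cfg = self.config
        self._adam_t += 1
        t = self._adam_t
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr = lr_scale * cfg.learning_rate * np.sqrt(1 - b2 ** t) / (1 - b1 ** t)
        for li, layer in enumerate(self.layers):
            for name, value, gname in layer.params():
                g = getattr(layer, gname)
                state = self._adam_state.setdefault(li, {})
                if name not in state:
                    state[name] = (np.zeros_like(value), np.zeros_like(value))
                m, v = state[name]
                m *= b1; m += (1 - b1) * g
                v *= b2; v += (1 - b2) * g * g
                value -= lr * m / (np.sqrt(v) + eps)
                if cfg.weight_decay and name == "w":
                    value -= cfg.learning_rate * cfg.weight_decay * value

    def fit(self, x: np.ndarray, y: np.ndarray) -> list[dict]:
        """Mini-batch Adam training; returns per-epoch history."""
        cfg = self.config
        rng = np.random.default_rng(cfg.rng_seed + 1)
        n = x.shape[0]
        history = []
        self._mode["training"] = True
        for epoch in range(cfg.epochs):
            if cfg.lr_schedule == "cosine":
                lr_scale = 0.5 * (1.0 + np.cos(np.pi * epoch / cfg.epochs))
            else:
                lr_scale = 1.0
            order = rng.permutation(n)
            losses, accs, sizes = [], [], []
            for i in range(0, n, cfg.batch_size):
                idx = order[i: i + cfg.batch_size]
                loss, acc = self._loss_grad(x[idx], y[idx])
                self._adam_step(lr_scale)
                losses.append(loss); accs.append(acc); sizes.append(len(idx))
            w = np.asarray(sizes, dtype=float)
            history.append({
                "epoch": epoch + 1,
                "loss": float(np.average(losses, weights=w)),
                "accuracy": float(np.average(accs, weights=w)),
            })
        self._mode["training"] = False
        self.history = history
        return history

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Weights to <path>.npz plus a JSON sidecar with the config."""
        path = Path(path)
        arrays = {}
        for li, layer in enumerate(self.layers):
            for name, value, _ in layer.params():
                arrays[f"{li}.{name}"] = value
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "config": asdict(self.config),
            "input_shape": list(self.input_shape),
            "n_outputs": self.n_outputs,
            "dtype": self.dtype.name,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ConvNet":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg_d = sidecar["config"]
        cfg_d["conv_filters"] = tuple(cfg_d["conv_filters"])
        cfg_d["pool_sizes"] = tuple(tuple(p) for p in cfg_d["pool_sizes"])
        config = NetConfig(**cfg_d)
        net = cls(tuple(sidecar["input_shape"]), sidecar["n_outputs"], config,
                  dtype=np.dtype(sidecar["dtype"]))
        arrays = np.load(path.with_suffix(".npz"))
        for li, layer in enumerate(net.layers):
            for name, value, _ in layer.params():
                value[...] = arrays[f"{li}.{name}"]
        return net


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class ModelSelectionResult:
    confusion: np.ndarray                  # (4, 4) counts, rows = truth
    per_class_accuracy: dict[int, float]
    overall_train_accuracy: float
    overall_test_accuracy: float
    class_ids: tuple[int, ...]
    empirical_posteriors: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "confusion": self.confusion.tolist(),
            "per_class_accuracy": {str(k): v for k, v in self.per_class_accuracy.items()},
            "overall_train_accuracy": self.overall_train_accuracy,
            "overall_test_accuracy": self.overall_test_accuracy,
            "class_ids": list(self.class_ids),
        }
        if self.empirical_posteriors is not None:
            d["empirical_posteriors"] = self.empirical_posteriors.tolist()
        return d


@dataclass
class ParamEstimate:
    """Per-parameter medians and percentile intervals in natural units."""

    median: dict[str, float]
    interval: dict[str, tuple[float, float]]
    rmse: dict[str, float] = field(default_factory=dict)
    spearman_rho: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "median": self.median,
            "interval": {k: list(v) for k, v in self.interval.items()},
            "rmse": self.rmse,
            "spearman_rho": self.spearman_rho,
        }


class ParamNormalizer:
    """Min-max map of (Ne, DT, founder ratio, growth ratio) onto [0, 1]
    over their prior ranges, and its exact inverse."""

    def __init__(self, priors: PriorConfig):
        self.lo = np.array([priors.ne_range[0], priors.dt_range[0],
                            priors.founder_ratio_range[0], priors.growth_ratio_range[0]])
        self.hi = np.array([priors.ne_range[1], priors.dt_range[1],
                            priors.founder_ratio_range[1], priors.growth_ratio_range[1]])

    def normalize(self, natural: np.ndarray) -> np.ndarray:
        return (np.asarray(natural, dtype=np.float64) - self.lo) / (self.hi - self.lo)

    def denormalize(self, unit: np.ndarray) -> np.ndarray:
        return np.asarray(unit, dtype=np.float64) * (self.hi - self.lo) + self.lo


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def train_classifier(
    train: tuple[np.ndarray, np.ndarray], config: NetConfig
) -> tuple[ConvNet, list[dict]]:
    """Train the 4-way (or k-way) scenario classifier.

    ``train`` is (X, y) with X of shape (n, rows, cols, channels) and
    integer labels y; classes need not be {0..k-1} — labels are mapped to
    a dense index recorded on the returned network.
    """
    x, y = train
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("at least two classes are required")
    counts = np.array([(y == c).sum() for c in classes])
    if counts.min() * 2 < counts.max():
        import warnings
        warnings.warn("strongly unbalanced classes; accuracy may be skewed")
    y_idx = np.searchsorted(classes, y)
    cfg = config if config.task == "classify" else NetConfig(**{**asdict(config), "task": "classify"})
    net = ConvNet(x.shape[1:], classes.size, cfg)
    net.class_ids = tuple(int(c) for c in classes)
    history = net.fit(x, y_idx.astype(np.int64))
    return net, history


def evaluate_classifier(
    net: ConvNet, test: tuple[np.ndarray, np.ndarray]
) -> ModelSelectionResult:
    """Confusion matrix and per-class accuracies on a labeled test set."""
    x, y = test
    if x.shape[0] != y.shape[0]:
        raise ValueError("test tensor count does not match label count")
    class_ids = getattr(net, "class_ids", tuple(range(net.n_outputs)))
    y_idx = np.searchsorted(np.asarray(class_ids), y)
    pred = net.predict(x).argmax(axis=1)
    k = len(class_ids)
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (y_idx, pred), 1)
    row_sums = confusion.sum(axis=1)
    per_class = {
        class_ids[i]: float(confusion[i, i] / row_sums[i]) if row_sums[i] else float("nan")
        for i in range(k)
    }
    train_acc = net.history[-1]["accuracy"] if getattr(net, "history", None) else float("nan")
    return ModelSelectionResult(
        confusion=confusion,
        per_class_accuracy=per_class,
        overall_train_accuracy=float(train_acc),
        overall_test_accuracy=float((pred == y_idx).mean()),
        class_ids=class_ids,
    )


def select_model(net: ConvNet, empirical: np.ndarray) -> np.ndarray:
    """Class posterior vector (softmax outputs) for one empirical tensor."""
    if empirical.ndim == 3:
        empirical = empirical[None]
    if empirical.shape[1:] != net.input_shape:
        raise ValueError(
            f"tensor shape {empirical.shape[1:]} does not match "
            f"network input {net.input_shape}"
        )
    return net.predict(empirical)[0]


def train_regressor(
    train: tuple[np.ndarray, np.ndarray], config: NetConfig
) -> ConvNet:
    """Train the multi-output parameter regressor on normalized targets."""
    x, y = train
    y = np.asarray(y, dtype=np.float64)
    if y.ndim == 1:
        y = y[:, None]
    if np.any(y.std(axis=0) == 0):
        raise ValueError("constant regression targets")
    cfg = config if config.task == "regress" else NetConfig(**{**asdict(config), "task": "regress"})
    net = ConvNet(x.shape[1:], y.shape[1], cfg)
    net.fit(x, y.astype(net.dtype))
    return net


def score_regression(
    predictions: np.ndarray, truths: np.ndarray
) -> dict[str, tuple[float, float]]:
    """Per-parameter (RMSE, Spearman's rho) on the given scale.

    A constant prediction column has undefined rank correlation and is
    reported as NaN rather than 0.
    """
    p = np.atleast_2d(np.asarray(predictions, dtype=np.float64).T).T
    t = np.atleast_2d(np.asarray(truths, dtype=np.float64).T).T
    if p.shape != t.shape:
        raise ValueError("predictions and truths must have the same shape")
    if p.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    out = {}
    names = PARAM_NAMES if p.shape[1] == len(PARAM_NAMES) else [str(i) for i in range(p.shape[1])]
    for j, name in enumerate(names):
        rmse = float(np.sqrt(np.mean((p[:, j] - t[:, j]) ** 2)))
        if np.std(p[:, j]) == 0 or np.std(t[:, j]) == 0:
            rho = float("nan")
        else:
            rho = float(spearmanr(p[:, j], t[:, j]).statistic)
        out[name] = (rmse, rho)
    return out


def estimate_params(
    regressor: ConvNet,
    empirical_matrix: np.ndarray,
    deme_labels: np.ndarray,
    encoder_config,
    normalizer: ParamNormalizer,
    n_bootstrap: int,
    rng_seed: int,
) -> ParamEstimate:
    """Point estimates with bootstrap percentile intervals.

    The empirical matrix (rows = samples, NaN = missing) is re-encoded
    ``n_bootstrap`` times with columns resampled with replacement; each
    re-encoding is pushed through the regressor and de-normalized.  The
    report carries the median and the (2.5%, 97.5%) percentile interval
    per parameter in natural units.
    """
    from .encode import matrix_to_image

    if n_bootstrap < 2:
        raise ValueError("n_bootstrap must be >= 2")
    rng = np.random.default_rng(rng_seed)
    n_cols = empirical_matrix.shape[1]
    tensors = []
    for _ in range(n_bootstrap):
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = empirical_matrix[:, cols]
        tensors.append(matrix_to_image(resampled, encoder_config,
                                       deme_labels=deme_labels).values)
    preds_unit = regressor.predict(np.stack(tensors))
    preds = np.stack([normalizer.denormalize(u) for u in preds_unit])
    med = np.median(preds, axis=0)
    lo = np.percentile(preds, 2.5, axis=0)
    hi = np.percentile(preds, 97.5, axis=0)
    return ParamEstimate(
        median={n: float(m) for n, m in zip(PARAM_NAMES, med)},
        interval={n: (float(a), float(b)) for n, a, b in zip(PARAM_NAMES, lo, hi)},
    )
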