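"""Binary stressed / non-stressed CNN for 28x28 single-channel images.

The architecture is fixed by contract: 8 convolution layers (3x3 kernels,
size-preserving padding) producing 32, 32, 64, 64, 128, 128, 256, 256
feature maps, a 2x2 max-pool after every second convolution (spatial size
28 -> 14 -> 7 -> 3 -> 1 with floor division), then dense layers of depth
256, 256, 1 with two dropout layers (rate 0.5) between them.  ReLU
activations throughout; the single output unit is the logit of the
"stressed" probability.

Training is plain mini-batch Adam on binary cross-entropy, implemented in
NumPy (im2col convolutions lowered to BLAS matrix products), with a single
seed controlling initialisation, shuffling and dropout so runs are exactly
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

_CONV_CHANNELS = (32, 32, 64, 64, 128, 128, 256, 256)
_FC_DEPTHS = (256, 256, 1)

# Jitted gather/scatter kernels: the strided 9-tap copies around the BLAS
# GEMMs are the hot path of the convolutions, and the 2x2 pooling reduction
# is cheaper as one fused pass than as a reshape/transpose/argmax chain.
# Pure-NumPy fallbacks keep the module importable without numba.
try:
    from numba import njit as _njit

    @_njit(cache=True, fastmath=True)
    def _im2col_k(xp, cols):  # xp (n,h+2,w+2,c) -> cols (n,h,w,9,c)
        n, h, w, _, c = cols.shape
        for b in range(n):
            for i in range(h):
                for j in range(w):
                    for k in range(9):
                        di, dj = k // 3, k % 3
                        for ch in range(c):
                            cols[b, i, j, k, ch] = xp[b, i + di, j + dj, ch]

    @_njit(cache=True, fastmath=True)
    def _col2im_k(dcols, dxp):  # dcols (n,h,w,9,c) accumulated into dxp (n,h+2,w+2,c)
        n, h, w, _, c = dcols.shape
        for b in range(n):
            for i in range(h):
                for j in range(w):
                    for k in range(9):
                        di, dj = k // 3, k % 3
                        for ch in range(c):
                            dxp[b, i + di, j + dj, ch] += dcols[b, i, j, k, ch]

    @_njit(cache=True, fastmath=True)
    def _maxpool_k(x, out, arg):  # x (n,h,w,c) -> out/arg (n,h//2,w//2,c)
        n, oh, ow, c = out.shape
        for b in range(n):
            for i in range(oh):
                for j in range(ow):
                    for ch in range(c):
                        best = x[b, 2 * i, 2 * j, ch]
                        bk = 0
                        for k in range(1, 4):
                            v = x[b, 2 * i + k // 2, 2 * j + k % 2, ch]
                            if v > best:
                                best = v
                                bk = k
                        out[b, i, j, ch] = best
                        arg[b, i, j, ch] = bk

    @_njit(cache=True, fastmath=True)
    def _maxpool_back_k(d, arg, dx):  # scatter d into zeroed dx at argmax positions
        n, oh, ow, c = d.shape
        for b in range(n):
            for i in range(oh):
                for j in range(ow):
                    for ch in range(c):
                        k = arg[b, i, j, ch]
                        dx[b, 2 * i + k // 2, 2 * j + k % 2, ch] += d[b, i, j, ch]

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training hyperparameters.

    The convolutional inventory (8 conv, 4 pool, 2 dropout, 3 dense) is a
    contract and is validated; optimiser settings are free.
    """

    conv_channels: tuple[int, ...] = _CONV_CHANNELS
    kernel: int = 3
    pool: int = 2
    dropout_rate: float = 0.5
    fc_depths: tuple[int, ...] = _FC_DEPTHS
    input_size: int = 28
    epochs: int = 150
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 8 or any(c < 1 for c in self.conv_channels):
            raise ValueError("conv_channels must list 8 positive feature-map counts")
        if self.kernel != 3 or self.pool != 2:
            raise ValueError("the architecture uses 3x3 kernels and 2x2 pools")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if len(self.fc_depths) != 3 or self.fc_depths[-1] != 1:
            raise ValueError("fc_depths must be three dense depths ending in 1")
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training hyperparameters")
        s = self.input_size
        for _ in range(4):
            s //= 2
        if s < 1:
            raise ValueError(f"input_size {self.input_size} collapses below 1x1 under 4 pools")


# ---------------------------------------------------------------------------
# layers (NHWC, float32)


class _Conv3x3:
    """Size-preserving 3x3 convolution via im2col + GEMM.

    Scratch arrays are cached per input shape: repeated fresh multi-MB
    allocations cost more in page faults than the GEMMs themselves.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (9 * cin))  # He initialisation for ReLU stacks
        self.W = (rng.standard_normal((9 * cin, cout)) * std).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None
        self._buf: dict = {}

    def _scratch(self, shape: tuple) -> dict:
        buf = self._buf.get(shape)
        if buf is None:
            n, h, w, c = shape
            cout = self.W.shape[1]
            buf = {
                "xp": np.zeros((n, h + 2, w + 2, c), dtype=np.float32),
                "cols": np.empty((n, h, w, 9, c), dtype=np.float32),
                "out": np.empty((n * h * w, cout), dtype=np.float32),
                "dcols": np.empty((n * h * w, 9 * c), dtype=np.float32),
            }
            self._buf = {shape: buf}  # keep at most one batch shape resident
        return buf

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w, c = x.shape
        buf = self._scratch((n, h, w, c))
        xp = buf["xp"]
        xp[:, 1:-1, 1:-1, :] = x
        cols5 = buf["cols"]
        if _HAVE_NUMBA:
            _im2col_k(xp, cols5)
        else:
            k = 0
            for i in range(3):
                for j in range(3):
                    cols5[:, :, :, k, :] = xp[:, i : i + h, j : j + w, :]
                    k += 1
        cols = cols5.reshape(n * h * w, 9 * c)
        out = np.matmul(cols, self.W, out=buf["out"])
        out += self.b
        self._cache = (cols, (n, h, w, c)) if training else None
        return out.reshape(n, h, w, -1)

    def backward(self, d: np.ndarray) -> np.ndarray:
        cols, (n, h, w, c) = self._cache
        buf = self._scratch((n, h, w, c))
        dflat = np.ascontiguousarray(d.reshape(n * h * w, -1))
        self.dW = cols.T @ dflat
        self.db = dflat.sum(axis=0)
        dcols = np.matmul(dflat, self.W.T, out=buf["dcols"]).reshape(n, h, w, 9, c)
        dxp = buf["xp"]
        dxp.fill(0.0)
        if _HAVE_NUMBA:
            _col2im_k(dcols, dxp)
        else:
            k = 0
            for i in range(3):
                for j in range(3):
                    dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, k, :]
                    k += 1
        self._cache = None
        return dxp[:, 1:-1, 1:-1, :]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class _ReLU:
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, d):
        return d * self._mask


class _MaxPool2:
    """2x2 max pooling with stride 2; an odd trailing row/column is dropped.

    Ties take the first (row-major) maximum, matching ``argmax``.
    """

    def __init__(self):
        self._buf: dict = {}

    def forward(self, x, training):
        n, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        buf = self._buf.get((n, h, w, c))
        if buf is None:
            buf = {
                "out": np.empty((n, oh, ow, c), dtype=np.float32),
                "arg": np.empty((n, oh, ow, c), dtype=np.int8),
                "dx": np.zeros((n, h, w, c), dtype=np.float32),
            }
            self._buf = {(n, h, w, c): buf}
        self._shape = (n, h, w, c)
        if _HAVE_NUMBA:
            _maxpool_k(x, buf["out"], buf["arg"])
            return buf["out"]
        xc = x[:, : oh * 2, : ow * 2, :]
        patches = (
            xc.reshape(n, oh, 2, ow, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, oh, ow, c, 4)
        )
        buf["arg"][...] = patches.argmax(axis=4)
        buf["out"][...] = np.take_along_axis(
            patches, buf["arg"][..., None].astype(np.intp), axis=4
        )[..., 0]
        return buf["out"]

    def backward(self, d):
        n, h, w, c = self._shape
        oh, ow = h // 2, w // 2
        buf = self._buf[(n, h, w, c)]
        dx = buf["dx"]
        dx.fill(0.0)
        if _HAVE_NUMBA:
            _maxpool_back_k(d, buf["arg"], dx)
            return dx
        dp = np.zeros((n, oh, ow, c, 4), dtype=np.float32)
        np.put_along_axis(dp, buf["arg"][..., None].astype(np.intp), d[..., None], axis=4)
        dx[:, : oh * 2, : ow * 2, :] = (
            dp.reshape(n, oh, ow, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, oh * 2, ow * 2, c)
        )
        return dx


class _Flatten:
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, d):
        return d.reshape(self._shape)


class _Dense:
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / nin)
        self.W = (rng.standard_normal((nin, nout)) * std).astype(np.float32)
        self.b = np.zeros(nout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        self._x = x if training else None
        return x @ self.W + self.b

    def backward(self, d):
        self.dW = self._x.T @ d
        self.db = d.sum(axis=0)
        self._x = None
        return d @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class _Dropout:
    """Inverted dropout: active only during training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self._rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, d):
        return d if self._mask is None else d * self._mask


# ---------------------------------------------------------------------------
# model


class StressCNN:
    """The fixed conv/pool/dense stack; see module docstring for the inventory."""

    def __init__(self, config: CNNConfig):
        self.config = config
        init_rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0]))
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed & 0x7FFFFFFF, 1])
        )
        layers: list = []
        cin = 1
        size = config.input_size
        for i, cout in enumerate(config.conv_channels):
            layers.append(_Conv3x3(cin, cout, init_rng))
            layers.append(_ReLU())
            cin = cout
            if i % 2 == 1:
                layers.append(_MaxPool2())
                size //= 2
        layers.append(_Flatten())
        nin = cin * size * size
        d1, d2, dout = config.fc_depths
        layers.append(_Dense(nin, d1, init_rng))
        layers.append(_ReLU())
        layers.append(_Dropout(config.dropout_rate, self._dropout_rng))
        layers.append(_Dense(d1, d2, init_rng))
        layers.append(_ReLU())
        layers.append(_Dropout(config.dropout_rate, self._dropout_rng))
        layers.append(_Dense(d2, dout, init_rng))
        self.layers = layers

    # -- introspection used by contract tests and reports
    def layer_inventory(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for layer in self.layers:
            name = type(layer).__name__.lstrip("_")
            counts[name] = counts.get(name, 0) + 1
        return counts

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers if hasattr(layer, "params") for p in layer.params())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x[:, 0]  # logits

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits[:, None].astype(np.float32)
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def trainable(self):
        return [layer for layer in self.layers if hasattr(layer, "params")]


@dataclass
class TrainedModel:
    """A trained network with its config and per-epoch history."""

    model: StressCNN
    config: CNNConfig
    history: dict[str, list[float]]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def _as_batch(images: np.ndarray, input_size: int) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    if x.ndim != 4 or x.shape[1] != input_size or x.shape[2] != input_size or x.shape[3] != 1:
        raise ValueError(
            f"images must be (N, {input_size}, {input_size}[, 1]); got {np.asarray(images).shape}"
        )
    return x


def build_model(config: CNNConfig) -> StressCNN:
    """Construct the untrained network for ``config`` (validates the inventory)."""
    return StressCNN(config)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (_sigmoid(z) - y) / z.size
    return loss, dz.astype(np.float32)


def train(
    model: StressCNN,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray] | None,
    config: CNNConfig | None = None,
) -> TrainedModel:
    """Mini-batch Adam training on binary cross-entropy.

    ``train_data`` / ``val_data`` are ``(images, labels)`` with labels in
    {0, 1} (1 = stressed).  The seed fixes initialisation, shuffling and
    dropout, so identical seeds and data give identical histories.  The
    history records per-epoch mean train loss, train accuracy (over the
    epoch's batches) and validation accuracy.
    """
    config = config or model.config
    x, y = train_data
    x = _as_batch(x, config.input_size)
    y = np.asarray(y, dtype=np.float32).ravel()
    if y.size != x.shape[0]:
        raise ValueError("images and labels disagree in length")
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class; loss is degenerate")
    if val_data is not None and len(val_data[1]):
        xv = _as_batch(val_data[0], config.input_size)
        yv = np.asarray(val_data[1], dtype=np.float32).ravel()
    else:
        if val_data is not None:
            warnings.warn("empty validation set; history will omit val_accuracy values")
        xv = yv = None

    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 2]))
    params = [p for layer in model.trainable() for p in layer.params()]
    opt = _Adam(params, config.learning_rate)
    history: dict[str, list[float]] = {"loss": [], "accuracy": [], "val_accuracy": []}

    n = x.shape[0]
    for _epoch in range(config.epochs):
        perm = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            z = model.forward(xb, training=True)
            loss, dz = _bce_with_logits(z, yb)
            model.backward(dz)
            opt.step([g for layer in model.trainable() for g in layer.grads()])
            epoch_loss += loss * idx.size
            epoch_correct += int(np.sum((z >= 0) == (yb >= 0.5)))
        history["loss"].append(epoch_loss / n)
        history["accuracy"].append(epoch_correct / n)
        if xv is not None:
            probs, _ = predict(model, xv)
            history["val_accuracy"].append(float(np.mean((probs >= 0.5) == (yv >= 0.5))))
    return TrainedModel(model=model, config=config, history=history)


def save_model(trained: TrainedModel, path) -> None:
    """Checkpoint weights (NPZ) plus config and history (JSON sidecar)."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    params = [p for layer in trained.model.trainable() for p in layer.params()]
    np.savez(path, **{f"p{i}": p for i, p in enumerate(params)})
    path.with_suffix(".json").write_text(
        json.dumps({"config": asdict(trained.config), "history": trained.history}, indent=2)
    )


def load_model(path) -> TrainedModel:
    """Rebuild a checkpointed model; predictions match the saved one exactly."""
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = meta["config"]
    for key in ("conv_channels", "fc_depths"):
        cfg[key] = tuple(cfg[key])
    config = CNNConfig(**cfg)
    model = StressCNN(config)
    with np.load(path) as archive:
        params = [p for layer in model.trainable() for p in layer.params()]
        if len(archive.files) != len(params):
            raise ValueError("checkpoint does not match the architecture")
        for i, p in enumerate(params):
            p[...] = archive[f"p{i}"]
    return TrainedModel(model=model, config=config, history=meta["history"])


def predict(
    model: StressCNN | TrainedModel, images: np.ndarray, batch_size: int = 128
) -> tuple[np.ndarray, np.ndarray]:
    """Per-image stressed probability and hard label (p >= 0.5 -> stressed).

    Deterministic (dropout inactive) and invariant to batch ordering.
    """
    net = model.model if isinstance(model, TrainedModel) else model
    x = _as_batch(images, net.config.input_size)
    probs = np.empty(x.shape[0], dtype=np.float64)
    for start in range(0, x.shape[0], batch_size):
        z = net.forward(x[start : start + batch_size], training=False)
        probs[start : start + batch_size] = _sigmoid(z.astype(np.float64))
    return probs, (probs >= 0.5).astype(np.int8)
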