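"""Minimal seeded NumPy neural-network framework.

Supports 1-D convolution, max pooling, dense layers and ReLU, trained with
Adam on a multi-task sigmoid cross-entropy loss. Deliberately small: just
enough to express the convolutional classifiers this package trains, with
deterministic seeding and lossless save/load.

All arrays are float32; given identical seed, data and BLAS, training and
prediction are bit-reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

_DTYPE = np.float32


class Layer:
    """Base layer: forward/backward plus (possibly empty) parameter lists."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def config(self) -> dict:
        return {"type": type(self).__name__}


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(_DTYPE)
        self.b = np.zeros(n_out, dtype=_DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def config(self):
        return {"type": "Dense", "n_in": self.W.shape[0], "n_out": self.W.shape[1]}


class Conv1D(Layer):
    """Valid-mode 1-D convolution over (batch, length, channels) input."""

    def __init__(self, c_in: int, c_out: int, width: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (width * c_in))
        self.W = (rng.standard_normal((width, c_in, c_out)) * scale).astype(_DTYPE)
        self.b = np.zeros(c_out, dtype=_DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        w = self.W.shape[0]
        windows = np.lib.stride_tricks.sliding_window_view(x, w, axis=1)
        # windows: (B, L_out, C_in, w) -> contract over (w, C_in)
        out = np.tensordot(windows, self.W, axes=([3, 2], [0, 1]))
        return (out + self.b).astype(_DTYPE)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        w = self.W.shape[0]
        windows = np.lib.stride_tricks.sliding_window_view(x, w, axis=1)
        # dW[k, ci, co] = sum_{B, L_out} x[b, l+k, ci] * grad[b, l, co]
        self.dW[...] = np.tensordot(windows, grad, axes=([0, 1], [0, 1])).transpose(1, 0, 2)
        self.db[...] = grad.sum(axis=(0, 1))
        dx = np.zeros_like(x)
        l_out = grad.shape[1]
        for k in range(w):
            dx[:, k : k + l_out, :] += grad @ self.W[k].T
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def config(self):
        return {
            "type": "Conv1D",
            "c_in": self.W.shape[1],
            "c_out": self.W.shape[2],
            "width": self.W.shape[0],
        }


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(_DTYPE)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    def config(self):
        return {"type": "ReLU"}


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis (trailing remainder
    positions are dropped)."""

    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, l, c = x.shape
        n = l // self.pool
        self._in_shape = x.shape
        xr = x[:, : n * self.pool, :].reshape(b, n, self.pool, c)
        self._argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, n, c = grad.shape
        dxr = np.zeros((b, n, self.pool, c), dtype=_DTYPE)
        bi, ni, ci = np.ogrid[:b, :n, :c]
        dxr[bi, ni, self._argmax, ci] = grad
        dx = np.zeros(self._in_shape, dtype=_DTYPE)
        dx[:, : n * self.pool, :] = dxr.reshape(b, n * self.pool, c)
        return dx

    def config(self):
        return {"type": "MaxPool1D", "pool": self.pool}


class CenterCrop1D(Layer):
    """Keep the central ``keep`` positions along the length axis."""

    def __init__(self, keep: int):
        self.keep = keep

    def forward(self, x: np.ndarray) -> np.ndarray:
        l = x.shape[1]
        if l < self.keep:
            raise ValueError(f"input length {l} shorter than crop {self.keep}")
        self._in_shape = x.shape
        self._lo = (l - self.keep) // 2
        return x[:, self._lo : self._lo + self.keep, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._in_shape, dtype=_DTYPE)
        dx[:, self._lo : self._lo + self.keep, :] = grad
        return dx

    def config(self):
        return {"type": "CenterCrop1D", "keep": self.keep}


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)

    def config(self):
        return {"type": "Flatten"}


_LAYER_TYPES = {"Dense": Dense, "Conv1D": Conv1D, "ReLU": ReLU,
                "MaxPool1D": MaxPool1D, "Flatten": Flatten,
                "CenterCrop1D": CenterCrop1D}


class Network:
    """Feed-forward stack ending in task logits (sigmoid applied at predict)."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Sigmoid probabilities, computed in batches."""
        outs = []
        for i in range(0, len(x), batch_size):
            z = self.forward(np.asarray(x[i : i + batch_size], dtype=_DTYPE))
            outs.append(_sigmoid(z))
        return np.concatenate(outs, axis=0)

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w

    def config(self) -> list[dict]:
        return [layer.config() for layer in self.layers]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy over all batch x task cells.

    Returns (loss, dloss/dz).
    """
    n = z.size
    # log(1 + exp(z)) computed stably
    softplus = np.where(z > 0, z + np.log1p(np.exp(-np.abs(z))), np.log1p(np.exp(-np.abs(z))))
    loss = float(np.sum(softplus - y * z) / n)
    grad = ((_sigmoid(z) - y) / n).astype(_DTYPE)
    return loss, grad


def build_network(layer_configs: list[dict], seed: int) -> Network:
    """Construct a network from a list of layer config dicts, seeded."""
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    for cfg in layer_configs:
        t = cfg["type"]
        if t == "Dense":
            layers.append(Dense(cfg["n_in"], cfg["n_out"], rng))
        elif t == "Conv1D":
            layers.append(Conv1D(cfg["c_in"], cfg["c_out"], cfg["width"], rng))
        elif t == "ReLU":
            layers.append(ReLU())
        elif t == "MaxPool1D":
            layers.append(MaxPool1D(cfg["pool"]))
        elif t == "Flatten":
            layers.append(Flatten())
        elif t == "CenterCrop1D":
            layers.append(CenterCrop1D(cfg["keep"]))
        else:
            raise ValueError(f"unknown layer type {t!r}")
    return Network(layers)


class Adam:
    """Adam with decoupled (AdamW-style) weight decay."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            if self.weight_decay and p.ndim > 1:   # decay weights, not biases
                p -= (self.lr * self.weight_decay * p).astype(_DTYPE)
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(_DTYPE)


def train_network(
    net: Network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    *,
    epochs: int = 40,
    batch_size: int = 64,
    lr: float = 1e-3,
    patience: int = 5,
    weight_decay: float = 0.0,
    seed: int = 0,
) -> dict:
    """Train with Adam and early stopping on validation loss.

    Restores the best-validation weights before returning. Returns a history
    dict with per-epoch train/validation losses.
    """
    x_train = np.asarray(x_train, dtype=_DTYPE)
    y_train = np.asarray(y_train, dtype=_DTYPE)
    x_val = np.asarray(x_val, dtype=_DTYPE)
    y_val = np.asarray(y_val, dtype=_DTYPE)
    if y_train.ndim == 1:
        y_train = y_train[:, None]
    if y_val.ndim == 1:
        y_val = y_val[:, None]
    rng = np.random.default_rng(seed)
    opt = Adam(net.params(), lr=lr, weight_decay=weight_decay)
    history: dict = {"train_loss": [], "val_loss": []}
    best_loss = np.inf
    best_weights = net.get_weights()
    bad_epochs = 0
    n = len(x_train)
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for i in range(0, n, batch_size):
            take = order[i : i + batch_size]
            z = net.forward(x_train[take])
            loss, dz = bce_with_logits(z, y_train[take])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {n_batches}"
                )
            net.backward(dz)
            opt.step(net.grads())
            epoch_loss += loss
            n_batches += 1
        val_loss = _eval_loss(net, x_val, y_val)
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_weights = net.get_weights()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= patience:
                break
    net.set_weights(best_weights)
    history["best_val_loss"] = best_loss
    return history


def _eval_loss(net: Network, x: np.ndarray, y: np.ndarray, batch_size: int = 512) -> float:
    total = 0.0
    count = 0
    for i in range(0, len(x), batch_size):
        z = net.forward(x[i : i + batch_size])
        loss, _ = bce_with_logits(z, y[i : i + batch_size])
        total += loss * z.size
        count += z.size
    return total / max(count, 1)


class Ensemble:
    """Logit-averaging ensemble of identically shaped networks.

    Exposes the same ``forward``/``predict_proba`` surface as
    :class:`Network`; averaging logits stabilizes small-data training
    against seed-to-seed variation."""

    def __init__(self, networks: list[Network]):
        if not networks:
            raise ValueError("ensemble needs at least one member")
        self.networks = networks

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.networks[0].forward(x).astype(np.float64)
        for net in self.networks[1:]:
            out += net.forward(x)
        return (out / len(self.networks)).astype(_DTYPE)

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            z = self.forward(np.asarray(x[i : i + batch_size], dtype=_DTYPE))
            outs.append(_sigmoid(z))
        return np.concatenate(outs, axis=0)

    def n_params(self) -> int:
        return sum(net.n_params() for net in self.networks)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_network(net: Network | Ensemble, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(net, Ensemble):
        (directory / "ensemble.json").write_text(
            json.dumps({"n_members": len(net.networks)})
        )
        for i, member in enumerate(net.networks):
            save_network(member, directory / f"member{i}")
        return
    (directory / "architecture.json").write_text(json.dumps(net.config(), indent=1))
    np.savez(directory / "weights.npz",
             **{f"p{i}": p for i, p in enumerate(net.params())})


def load_network(directory: str | Path) -> Network | Ensemble:
    directory = Path(directory)
    if (directory / "ensemble.json").exists():
        meta = json.loads((directory / "ensemble.json").read_text())
        return Ensemble(
            [load_network(directory / f"member{i}") for i in range(meta["n_members"])]
        )
    configs = json.loads((directory / "architecture.json").read_text())
    # seed irrelevant: weights are overwritten below
    net = build_network(configs, seed=0)
    with np.load(directory / "weights.npz") as data:
        net.set_weights([data[f"p{i}"] for i in range(len(net.params()))])
    return net
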