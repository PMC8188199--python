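"""Minimal seeded NumPy neural-network engine.

Layers operate on float32 arrays in NCHW layout (images) or (N, D) layout
(dense features).  The engine is deliberately small: stride-1 convolutions
via sliding windows, 2x2 max pooling, ReLU, inverted dropout, dense layers,
identity residual wrappers, softmax cross-entropy with per-class loss
weights, and SGD with momentum.  Every source of randomness (weight
initialization, dropout masks) is drawn from an explicit
``numpy.random.Generator`` so that training runs are bit-reproducible.

Parameterized layers (those carrying weights) expose a ``trainable`` flag;
frozen layers still propagate gradients backwards but receive no updates,
which is what layer freezing for transfer learning requires.
"""

from __future__ import annotations

import json

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "Dense",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dropout",
    "Residual",
    "Network",
    "SGD",
    "softmax",
    "weighted_cross_entropy",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(probs, labels, class_weights):
    """Mean class-weighted cross-entropy and its gradient w.r.t. logits.

    L = sum_i w_{y_i} * (-log p_{i,y_i}) / sum_i w_{y_i}
    """
    n = labels.shape[0]
    w = class_weights[labels].astype(np.float64)
    wsum = w.sum()
    p_true = np.clip(probs[np.arange(n), labels], 1e-12, None)
    loss = float((w * -np.log(p_true)).sum() / wsum)
    grad = probs.astype(np.float64, copy=True)
    grad[np.arange(n), labels] -= 1.0
    grad *= (w / wsum)[:, None]
    return loss, grad.astype(probs.dtype)


class Layer:
    """Base layer: stateless unless it carries parameters."""

    trainable = True

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x, training=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 2-D convolution (cross-correlation), 'same' or 'valid' pad."""

    def __init__(self, in_channels, out_channels, kernel, pad="valid", name=""):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        if pad == "same":
            if kernel % 2 == 0:
                raise ValueError("'same' padding requires an odd kernel")
            self.pad = (kernel - 1) // 2
        elif pad == "valid":
            self.pad = 0
        else:
            self.pad = int(pad)
        self.name = name or f"conv{out_channels}x{kernel}"
        self.W = np.zeros((out_channels, in_channels, kernel, kernel), np.float32)
        self.b = np.zeros(out_channels, np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._win = None

    def init(self, rng: np.random.Generator):
        fan_in = self.in_channels * self.kernel * self.kernel
        sd = np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, sd, self.W.shape).astype(np.float32)
        self.b = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def out_side(self, side):
        return side - self.kernel + 1 + 2 * self.pad

    def n_params(self):
        return self.W.size + self.b.size

    def forward(self, x, training=False):
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        win = sliding_window_view(x, (self.kernel, self.kernel), axis=(2, 3))
        self._win = win if training else None
        out = np.einsum("nchwij,ocij->nohw", win, self.W, optimize=True)
        return out + self.b[None, :, None, None]

    def backward(self, dout):
        win = self._win
        self.dW = np.einsum("nchwij,nohw->ocij", win, dout, optimize=True)
        self.db = dout.sum(axis=(0, 2, 3))
        k, p = self.kernel, self.pad
        full = k - 1 - p
        dp = np.pad(dout, ((0, 0), (0, 0), (full,) * 2, (full,) * 2))
        win2 = sliding_window_view(dp, (k, k), axis=(2, 3))
        Wf = self.W[:, :, ::-1, ::-1]
        dx = np.einsum("nohwij,ocij->nchw", win2, Wf, optimize=True)
        self._win = None
        return dx


class Dense(Layer):
    def __init__(self, in_features, out_features, name=""):
        self.in_features = in_features
        self.out_features = out_features
        self.name = name or f"dense{out_features}"
        self.W = np.zeros((in_features, out_features), np.float32)
        self.b = np.zeros(out_features, np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def init(self, rng: np.random.Generator):
        sd = np.sqrt(2.0 / self.in_features)
        self.W = rng.normal(0.0, sd, self.W.shape).astype(np.float32)
        self.b = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def n_params(self):
        return self.W.size + self.b.size

    def forward(self, x, training=False):
        self._x = x if training else None
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training=False):
        self._mask = x > 0 if training else None
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; spatial dims must be even."""

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._idx, self._shape = idx, (n, c, h, w)
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dout.dtype)
        np.put_along_axis(flat, self._idx[..., None], dout[..., None], axis=-1)
        dx = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(n, c, h, w)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout on dense activations; a no-op when rate is 0."""

    def __init__(self, rate=0.0):
        self.rate = float(rate)
        self.rng = None  # assigned by the trainer
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate <= 0.0:
            return x
        if self.rng is None:
            raise RuntimeError("Dropout used in training without an RNG")
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / x.dtype.type(keep)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        out = dout * self._mask
        self._mask = None
        return out


class Residual(Layer):
    """Identity skip around a sub-stack: y = f(x) + x (shapes must match)."""

    def __init__(self, inner):
        self.inner = list(inner)

    def forward(self, x, training=False):
        y = x
        for layer in self.inner:
            y = layer.forward(y, training=training)
        return y + x

    def backward(self, dout):
        dy = dout
        for layer in reversed(self.inner):
            dy = layer.backward(dy)
        return dy + dout


def _walk(layers):
    for layer in layers:
        if isinstance(layer, Residual):
            yield from _walk(layer.inner)
        else:
            yield layer


class Network:
    """An ordered stack of layers ending in a linear logit layer.

    Images enter as (N, H, W, C) float arrays and are transposed to NCHW
    internally.  ``spec`` (attached by the model zoo) records architecture
    identity and per-layer trainable flags.
    """

    def __init__(self, layers, input_shape, n_classes, spec=None):
        self.layers = list(layers)
        self.input_shape = tuple(input_shape)  # (side, side, channels)
        self.n_classes = int(n_classes)
        self.spec = spec

    # -- layer bookkeeping -------------------------------------------------
    def all_layers(self):
        return list(_walk(self.layers))

    def param_layers(self):
        return [l for l in self.all_layers() if l.params()]

    def layer_names(self):
        return [l.name for l in self.param_layers()]

    def trainable_mask(self):
        return [bool(l.trainable) for l in self.param_layers()]

    def set_trainable_mask(self, mask):
        layers = self.param_layers()
        if len(mask) != len(layers):
            raise ValueError(
                f"mask has {len(mask)} entries, model has {len(layers)} "
                "parameterized layers"
            )
        for layer, flag in zip(layers, mask):
            layer.trainable = bool(flag)
        if self.spec is not None:
            self.spec.trainable = [bool(f) for f in mask]

    def set_dropout_rate(self, rate):
        for layer in self.all_layers():
            if isinstance(layer, Dropout):
                layer.rate = float(rate)

    def set_dropout_rng(self, rng):
        for layer in self.all_layers():
            if isinstance(layer, Dropout):
                layer.rng = rng

    def initialize(self, rng: np.random.Generator):
        for layer in self.all_layers():
            if hasattr(layer, "init"):
                layer.init(rng)

    def n_params(self):
        return sum(l.n_params() for l in self.param_layers())

    # -- running -----------------------------------------------------------
    def _to_internal(self, x):
        x = np.asarray(x)
        if not np.issubdtype(x.dtype, np.floating):
            x = x.astype(np.float32)
        if x.ndim != 4:
            raise ValueError(f"expected (N, H, W, C) input, got shape {x.shape}")
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input geometry {x.shape[1:]} does not match model "
                f"geometry {self.input_shape}"
            )
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def forward(self, x, training=False):
        h = self._to_internal(x)
        for layer in self.layers:
            h = layer.forward(h, training=training)
        return h

    def backward(self, dlogits):
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def predict_proba(self, x, batch_size=256):
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size])))
        return np.concatenate(out, axis=0)

    # -- state -------------------------------------------------------------
    def get_weights(self):
        return [p.copy() for l in self.param_layers() for p in l.params()]

    def set_weights(self, weights):
        flat = [p for l in self.param_layers() for p in l.params()]
        if len(flat) != len(weights):
            raise ValueError("weight list length mismatch")
        for dst, src in zip(flat, weights):
            if dst.shape != src.shape:
                raise ValueError(
                    f"weight shape mismatch: {dst.shape} vs {src.shape}"
                )
            dst[...] = src


class SGD:
    """SGD with classical momentum; honors per-layer trainable flags."""

    def __init__(self, network: Network, learning_rate=0.01, momentum=0.9):
        self.network = network
        self.learning_rate = float(learning_rate)
        self.momentum = float(momentum)
        self.velocity = [
            np.zeros_like(p)
            for l in network.param_layers()
            for p in l.params()
        ]

    def step(self):
        i = 0
        for layer in self.network.param_layers():
            for p, g in zip(layer.params(), layer.grads()):
                if layer.trainable:
                    v = self.velocity[i]
                    v *= self.momentum
                    v -= self.learning_rate * g
                    p += v
                i += 1

    def state(self):
        return {
            "learning_rate": self.learning_rate,
            "momentum": self.momentum,
            "velocity": [v.copy() for v in self.velocity],
        }

    def load_state(self, state):
        self.learning_rate = float(state["learning_rate"])
        self.momentum = float(state["momentum"])
        for dst, src in zip(self.velocity, state["velocity"]):
            dst[...] = src


def rng_state_to_json(rng: np.random.Generator) -> str:
    return json.dumps(rng.bit_generator.state)


def rng_from_json(payload: str) -> np.random.Generator:
    state = json.loads(payload)
    rng = np.random.Generator(np.random.PCG64())
    rng.bit_generator.state = state
    return rng
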