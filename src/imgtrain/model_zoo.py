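"""Registry of network architectures buildable for any input geometry.

Architectures are registered by name and instantiated on demand for the
requested input side, channel count, and number of classes, mirroring the
workflow where the software generates the network to fit the data rather
than the other way round.  The registry is a plain dict behind
:func:`register_architecture`, so user code can add its own builders.

Included architectures:

``lenet5``
    Classic LeNet-5 layout: 2 convolutional (6 and 16 filters, 5x5, valid)
    + 3 dense layers (120, 84, K).
``nitta_6layer``
    4 convolutional (32/32/64/64, 3x3 'same') + 2 dense layers (256, K).
``residual_10layer``
    6 convolutional layers (32->64->128, 3x3 'same') with identity skip
    connections over every second convolution, + 4 dense layers
    (256/128/64, K).
``mlp_64_32`` / ``mlp_256_128``
    Plain multilayer perceptrons on flattened pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import (
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool2,
    Network,
    ReLU,
    Residual,
    SGD,
)

__all__ = [
    "ModelSpec",
    "register_architecture",
    "available_architectures",
    "build_model",
    "set_trainable",
    "plateau_unfreeze",
    "save_checkpoint",
    "load_checkpoint",
]

_REGISTRY: dict = {}


@dataclass
class ModelSpec:
    """Identity card of a built model; pins the architecture for tests."""

    name: str
    input_side: int
    channels: int
    n_classes: int
    layer_names: list = field(default_factory=list)
    trainable: list = field(default_factory=list)
    layer_param_counts: list = field(default_factory=list)

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


def register_architecture(name):
    """Decorator: register ``fn(input_side, channels, n_classes) -> layers``."""

    def deco(fn):
        _REGISTRY[name] = fn
        return fn

    return deco


def available_architectures():
    return sorted(_REGISTRY)


def _check_even_halvings(side, kernel_valid, pools, name):
    """Walk the spatial-size arithmetic; raise naming the minimal side."""

    def final_side(s):
        for k in kernel_valid:
            s = s - k + 1
            if s < 1:
                return 0
            if s % 2:
                return -1  # odd before pooling
            s //= 2
        for _ in range(pools):
            if s % 2:
                return -1
            s //= 2
        return s

    ok = final_side
    # kernel_valid entries each imply conv(valid)+pool; `pools` extra pools.
    result = ok(side)
    if result >= 1:
        return
    minimal = side
    while minimal < 4096 and ok(minimal) < 1:
        minimal += 1
    raise ValueError(
        f"input side {side} is incompatible with architecture '{name}' "
        f"(feature map would vanish); minimal compatible side is {minimal}"
    )


@register_architecture("lenet5")
def _lenet5(side, channels, n_classes):
    _check_even_halvings(side, kernel_valid=[5, 5], pools=0, name="lenet5")
    s = (side - 4) // 2
    s = (s - 4) // 2
    return [
        Conv2D(channels, 6, 5, pad="valid", name="conv1"),
        ReLU(),
        MaxPool2(),
        Conv2D(6, 16, 5, pad="valid", name="conv2"),
        ReLU(),
        MaxPool2(),
        Flatten(),
        Dense(16 * s * s, 120, name="fc1"),
        ReLU(),
        Dropout(),
        Dense(120, 84, name="fc2"),
        ReLU(),
        Dropout(),
        Dense(84, n_classes, name="fc_out"),
    ]


@register_architecture("nitta_6layer")
def _nitta_6layer(side, channels, n_classes):
    if side % 4 or side < 8:
        raise ValueError(
            f"input side {side} is incompatible with architecture "
            "'nitta_6layer' (needs a multiple of 4, minimal compatible side is 8)"
        )
    s = side // 4
    return [
        Conv2D(channels, 32, 3, pad="same", name="conv1"),
        ReLU(),
        Conv2D(32, 32, 3, pad="same", name="conv2"),
        ReLU(),
        MaxPool2(),
        Conv2D(32, 64, 3, pad="same", name="conv3"),
        ReLU(),
        Conv2D(64, 64, 3, pad="same", name="conv4"),
        ReLU(),
        MaxPool2(),
        Flatten(),
        Dense(64 * s * s, 256, name="fc1"),
        ReLU(),
        Dropout(),
        Dense(256, n_classes, name="fc_out"),
    ]


@register_architecture("residual_10layer")
def _residual_10layer(side, channels, n_classes):
    if side % 8 or side < 8:
        raise ValueError(
            f"input side {side} is incompatible with architecture "
            "'residual_10layer' (needs a multiple of 8, minimal compatible "
            "side is 8)"
        )

    def block(cin, cout, i):
        return [
            Conv2D(cin, cout, 3, pad="same", name=f"conv{i}a"),
            ReLU(),
            Residual([Conv2D(cout, cout, 3, pad="same", name=f"conv{i}b"), ReLU()]),
            MaxPool2(),
        ]

    s = side // 8
    layers = block(channels, 32, 1) + block(32, 64, 2) + block(64, 128, 3)
    layers += [
        Flatten(),
        Dense(128 * s * s, 256, name="fc1"),
        ReLU(),
        Dropout(),
        Dense(256, 128, name="fc2"),
        ReLU(),
        Dropout(),
        Dense(128, 64, name="fc3"),
        ReLU(),
        Dense(64, n_classes, name="fc_out"),
    ]
    return layers


def _mlp(widths):
    def builder(side, channels, n_classes):
        layers = [Flatten()]
        d = side * side * channels
        for i, w in enumerate(widths, start=1):
            layers += [Dense(d, w, name=f"fc{i}"), ReLU(), Dropout()]
            d = w
        layers += [Dense(d, n_classes, name="fc_out")]
        return layers

    return builder


register_architecture("mlp_64_32")(_mlp([64, 32]))
register_architecture("mlp_256_128")(_mlp([256, 128]))


def build_model(name, input_side, channels=1, n_classes=2, seed=0,
                dropout_rate=0.0):
    """Build a named architecture for the requested geometry.

    Returns ``(network, spec)``.  All layers start trainable; weights are
    initialized from ``seed`` (He-normal) so that construction is
    reproducible.
    """
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown architecture '{name}'; available: "
            f"{', '.join(available_architectures())}"
        )
    if channels not in (1, 3):
        raise ValueError(f"channels must be 1 or 3, got {channels}")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    layers = _REGISTRY[name](int(input_side), int(channels), int(n_classes))
    net = Network(layers, (input_side, input_side, channels), n_classes)
    net.initialize(np.random.default_rng(seed))
    net.set_dropout_rate(dropout_rate)
    spec = ModelSpec(
        name=name,
        input_side=int(input_side),
        channels=int(channels),
        n_classes=int(n_classes),
        layer_names=net.layer_names(),
        trainable=net.trainable_mask(),
        layer_param_counts=[l.n_params() for l in net.param_layers()],
    )
    net.spec = spec
    return net, spec


def set_trainable(model: Network, mask):
    """Set per-layer trainable flags; frozen layers get no weight updates."""
    model.set_trainable_mask(mask)
    return model


def plateau_unfreeze(val_accuracies, trainable_mask, patience=5, epsilon=0.005):
    """Return the next layer index to unfreeze, or ``None``.

    A plateau is declared when the best validation accuracy over the last
    ``patience`` epochs improves on the best of all earlier epochs by less
    than ``epsilon``.  Unfreezing proceeds from the output toward the
    input, so the deepest (highest-index) still-frozen layer is returned.
    """
    frozen = [i for i, t in enumerate(trainable_mask) if not t]
    if not frozen:
        return None
    val = list(val_accuracies)
    if len(val) < patience + 1:
        return None
    recent = max(val[-patience:])
    before = max(val[:-patience])
    if recent - before < epsilon:
        return frozen[-1]
    return None


# ---------------------------------------------------------------------------
# Checkpoints: a .npz holding every parameter array plus a JSON header with
# the ModelSpec, trainable mask, and (optionally) optimizer state — enough
# to resume training bit-identically.
# ---------------------------------------------------------------------------

def save_checkpoint(model: Network, path, optimizer: SGD | None = None):
    arrays = {}
    weights = model.get_weights()
    for i, w in enumerate(weights):
        arrays[f"p{i}"] = w
    header = {
        "spec": model.spec.to_dict() if model.spec else None,
        "trainable": model.trainable_mask(),
        "n_weights": len(weights),
    }
    if optimizer is not None:
        st = optimizer.state()
        header["optimizer"] = {
            "learning_rate": st["learning_rate"],
            "momentum": st["momentum"],
        }
        for i, v in enumerate(st["velocity"]):
            arrays[f"v{i}"] = v
        header["n_velocity"] = len(st["velocity"])
    arrays["header"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)
    return path


def load_checkpoint(path, with_optimizer=False):
    """Rebuild a model (and optionally its optimizer) from a checkpoint."""
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        if header["spec"] is None:
            raise ValueError(f"checkpoint {path} carries no model spec")
        spec = ModelSpec.from_dict(header["spec"])
        model, _ = build_model(
            spec.name, spec.input_side, spec.channels, spec.n_classes
        )
        model.set_weights([data[f"p{i}"] for i in range(header["n_weights"])])
        model.set_trainable_mask(header["trainable"])
        optimizer = None
        if with_optimizer and "optimizer" in header:
            optimizer = SGD(
                model,
                learning_rate=header["optimizer"]["learning_rate"],
                momentum=header["optimizer"]["momentum"],
            )
            optimizer.load_state(
                {
                    **header["optimizer"],
                    "velocity": [
                        data[f"v{i}"] for i in range(header["n_velocity"])
                    ],
                }
            )
    if with_optimizer:
        return model, optimizer
    return model


def check_geometry(model: Network, images, n_classes=None):
    """Raise if a dataset does not fit the model, naming both shapes."""
    side, side2, channels = model.input_shape
    shape = tuple(images.shape[1:])
    if shape != (side, side2, channels):
        raise ValueError(
            f"model expects images of shape {(side, side2, channels)}, "
            f"dataset has {shape}"
        )
    if n_classes is not None and n_classes != model.n_classes:
        raise ValueError(
            f"model has {model.n_classes} output classes, dataset has "
            f"{n_classes}"
        )
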