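"""Training orchestration.

One *epoch* (training iteration) is: optionally draw a balanced per-class
sample of the training set, run it through the model in augmented
mini-batches under a class-weighted cross-entropy loss, then evaluate
accuracy on the full, un-augmented validation set.  The checkpoint with the
highest validation accuracy seen so far is kept as the "best model".

Hyper-parameters (learning rate, dropout rate, per-class sample size, class
weights, and every augmentation field) can change *during* training: before
each epoch a control source is polled and any changed values take effect
that epoch and are logged.  The control source is either a YAML file (flat
``key: value`` mapping, re-read every epoch, so edits land at the next
epoch boundary) or a scripted schedule (``schedule: {epoch: {key: value}}``,
also accepted as an in-memory dict), which keeps long runs reproducible.

Every run writes a meta-file: dataset content hashes, class names, the full
initial configuration, every per-epoch hyper-parameter snapshot, all change
events, software version and seed — sufficient to re-run identically
(:func:`replay_from_meta`).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .augment import AugmentationConfig, augment_batch
from .imageset import ImageSet, Normalizer
from .model_zoo import build_model, check_geometry, save_checkpoint
from .nn import SGD, softmax, weighted_cross_entropy

__all__ = [
    "TrainingConfig",
    "EpochRecord",
    "TrainingHistory",
    "TrainResult",
    "balanced_epoch_sample",
    "make_class_weights",
    "train",
    "write_meta",
    "read_meta",
    "replay_from_meta",
]

# hyper-parameters adjustable through the control source
_TOP_LEVEL_KEYS = {
    "learning_rate", "n_per_class", "dropout_rate", "class_weights",
    "batch_size",
}
_AUG_KEYS = set(AugmentationConfig().to_dict()) - {"seed"}


@dataclass
class TrainingConfig:
    epochs: int = 10
    batch_size: int = 32
    n_per_class: int | None = None
    class_weights: object = "uniform"  # mode name or explicit vector
    learning_rate: float = 0.01
    momentum: float = 0.9
    dropout_rate: float = 0.0
    seed: int = 0
    augmentation: AugmentationConfig | None = None
    normalization: str = "div255"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if isinstance(self.augmentation, dict):
            self.augmentation = AugmentationConfig.from_dict(self.augmentation)

    def to_dict(self):
        d = asdict(self)
        d["augmentation"] = (
            self.augmentation.to_dict() if self.augmentation else None
        )
        if isinstance(self.class_weights, np.ndarray):
            d["class_weights"] = [float(w) for w in self.class_weights]
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if d.get("augmentation"):
            d["augmentation"] = AugmentationConfig.from_dict(d["augmentation"])
        return cls(**d)


@dataclass
class EpochRecord:
    epoch: int                 # 1-based
    accuracy: float            # training accuracy over the epoch's batches
    val_accuracy: float        # accuracy on the full validation set
    hyperparams: dict          # every hyper-parameter in force this epoch
    changes: dict = field(default_factory=dict)  # control updates this epoch
    timestamp: float = 0.0


class TrainingHistory:
    """Ordered per-epoch records with CSV/DataFrame export."""

    def __init__(self, records=None):
        self.records = list(records or [])

    def append(self, record: EpochRecord):
        self.records.append(record)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def val_accuracies(self):
        return [r.val_accuracy for r in self.records]

    @property
    def accuracies(self):
        return [r.accuracy for r in self.records]

    def best_epoch(self):
        if not self.records:
            raise ValueError("empty history")
        i = int(np.argmax([r.val_accuracy for r in self.records]))
        return self.records[i]

    def change_events(self):
        events = []
        for r in self.records:
            for key, (old, new) in r.changes.items():
                events.append(
                    {"epoch": r.epoch, "key": key, "old": old, "new": new}
                )
        return events

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"epoch": r.epoch, "accuracy": r.accuracy,
                   "val_accuracy": r.val_accuracy}
            row.update(r.hyperparams)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)
        return path


@dataclass
class TrainResult:
    history: TrainingHistory
    best_epoch: int
    best_val_accuracy: float
    checkpoint_path: str | None
    meta_path: str | None
    normalization: object


# ---------------------------------------------------------------------------
# Sampling and loss weights
# ---------------------------------------------------------------------------

def balanced_epoch_sample(labels, n_per_class, rng, n_classes=None):
    """Indices with exactly ``n_per_class`` draws per class, shuffled.

    Classes smaller than ``n_per_class`` are sampled with replacement;
    larger classes without.  A class with zero members is an error.
    """
    labels = np.asarray(labels)
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    k = int(n_classes if n_classes is not None else labels.max() + 1)
    picks = []
    for c in range(k):
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            raise ValueError(f"class {c} has no members to sample from")
        if n_per_class == 0:
            continue
        replace = idx.size < n_per_class
        picks.append(rng.choice(idx, size=n_per_class, replace=replace))
    if not picks:
        return np.array([], dtype=np.int64)
    out = np.concatenate(picks)
    rng.shuffle(out)
    return out


def make_class_weights(labels, mode="uniform", n_classes=None):
    """Per-class loss coefficients.

    ``uniform``: all ones.  ``inverse_frequency``: ``N / (K * N_k)`` so
    rare classes contribute proportionally more loss.  A sequence is
    treated as manual coefficients (must be positive).
    """
    labels = np.asarray(labels)
    k = int(n_classes if n_classes is not None else labels.max() + 1)
    if isinstance(mode, str):
        if mode == "uniform":
            return np.ones(k)
        if mode == "inverse_frequency":
            counts = np.bincount(labels, minlength=k)
            if np.any(counts == 0):
                missing = np.flatnonzero(counts == 0)
                raise ValueError(
                    f"labels do not cover class(es) {missing.tolist()}"
                )
            return len(labels) / (k * counts.astype(np.float64))
        raise ValueError(f"unknown class-weight mode {mode!r}")
    w = np.asarray(mode, dtype=np.float64)
    if w.shape != (k,):
        raise ValueError(f"expected {k} class weights, got shape {w.shape}")
    if np.any(w <= 0):
        raise ValueError("manual class weights must all be > 0")
    return w


# ---------------------------------------------------------------------------
# Control source
# ---------------------------------------------------------------------------

def _parse_control(source):
    """Return (schedule_dict or None, flat_dict or None)."""
    if source is None:
        return None, None
    if isinstance(source, dict):
        if "schedule" in source:
            return {int(k): dict(v) for k, v in source["schedule"].items()}, None
        return None, dict(source)
    path = Path(source)
    if not path.exists():
        return None, None
    try:
        payload = yaml.safe_load(path.read_text()) or {}
        if not isinstance(payload, dict):
            raise ValueError("control file must hold a mapping")
    except (yaml.YAMLError, ValueError, OSError) as exc:
        warnings.warn(
            f"unparseable control file {path}: {exc}; keeping previous "
            "hyper-parameters",
            stacklevel=3,
        )
        return None, None
    if "schedule" in payload:
        return {int(k): dict(v) for k, v in payload["schedule"].items()}, None
    return None, payload


def _poll_control(source, epoch, state, aug):
    """Apply control updates before ``epoch``; return (state, aug, changes)."""
    schedule, flat = _parse_control(source)
    updates = {}
    if schedule is not None:
        updates = schedule.get(epoch, {})
    elif flat is not None:
        updates = flat
    changes = {}
    for key, value in updates.items():
        if key in _TOP_LEVEL_KEYS:
            old = state[key]
            if isinstance(old, np.ndarray):
                same = np.array_equal(old, np.asarray(value))
            else:
                same = old == value
            if not same:
                changes[key] = (_plain(old), _plain(value))
                state[key] = value
        elif key in _AUG_KEYS:
            old = getattr(aug, key)
            new = tuple(value) if key == "brightness_mult_range" else value
            if old != new:
                changes[key] = (_plain(old), _plain(new))
                aug = aug.replace(**{key: new})
        else:
            warnings.warn(
                f"control update for unknown hyper-parameter {key!r} ignored",
                stacklevel=3,
            )
    return state, aug, changes


def _plain(v):
    if isinstance(v, np.ndarray):
        return [float(x) for x in v]
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def _snapshot(state, aug):
    snap = {
        "learning_rate": float(state["learning_rate"]),
        "n_per_class": state["n_per_class"],
        "dropout_rate": float(state["dropout_rate"]),
        "batch_size": int(state["batch_size"]),
        "class_weights": _plain(state["class_weights"]),
    }
    for key, value in aug.to_dict().items():
        if key != "seed":
            snap[f"augmentation.{key}"] = _plain(value)
    return snap


# ---------------------------------------------------------------------------
# The training loop
# ---------------------------------------------------------------------------

def _val_accuracy(model, images, labels, normalizer, batch_size=256):
    correct = 0
    for i in range(0, len(images), batch_size):
        x = normalizer.transform(images[i : i + batch_size])
        probs = softmax(model.forward(x))
        correct += int((probs.argmax(axis=1) == labels[i : i + batch_size]).sum())
    return correct / len(images)


def train(model, train_set: ImageSet, valid_set: ImageSet,
          config: TrainingConfig, control_source=None, out_dir=None,
          run_name="run"):
    """Train ``model`` and return a :class:`TrainResult`.

    Deterministic given ``config.seed`` and a static control source.  When
    ``out_dir`` is given, the best checkpoint, history CSV, and meta-file
    are written there.
    """
    if list(train_set.class_names) != list(valid_set.class_names):
        raise ValueError(
            f"class mismatch between splits: {train_set.class_names} vs "
            f"{valid_set.class_names}"
        )
    check_geometry(model, train_set.images, train_set.n_classes)
    check_geometry(model, valid_set.images, valid_set.n_classes)

    normalizer = Normalizer(method=config.normalization).fit(train_set.images)
    aug = config.augmentation or AugmentationConfig(seed=config.seed)

    sample_rng = np.random.default_rng([int(config.seed), 1])
    dropout_rng = np.random.default_rng([int(config.seed), 2])
    model.set_dropout_rng(dropout_rng)
    model.set_dropout_rate(config.dropout_rate)

    k = train_set.n_classes
    state = {
        "learning_rate": config.learning_rate,
        "n_per_class": config.n_per_class,
        "dropout_rate": config.dropout_rate,
        "batch_size": config.batch_size,
        "class_weights": make_class_weights(
            train_set.labels, config.class_weights, n_classes=k
        ),
    }
    optimizer = SGD(model, learning_rate=state["learning_rate"],
                    momentum=config.momentum)
    target_side = model.input_shape[0]

    history = TrainingHistory()
    best_val, best_epoch = -1.0, -1
    best_weights = None
    global_batch = 0

    for epoch in range(1, config.epochs + 1):
        state, aug, changes = _poll_control(control_source, epoch, state, aug)
        if "class_weights" in changes:
            state["class_weights"] = make_class_weights(
                train_set.labels, state["class_weights"], n_classes=k
            )
        optimizer.learning_rate = float(state["learning_rate"])
        model.set_dropout_rate(float(state["dropout_rate"]))
        weights = np.asarray(state["class_weights"], dtype=np.float64)

        if state["n_per_class"] is not None:
            order = balanced_epoch_sample(
                train_set.labels, int(state["n_per_class"]), sample_rng,
                n_classes=k,
            )
        else:
            order = sample_rng.permutation(len(train_set))

        correct, seen = 0, 0
        bs = int(state["batch_size"])
        for start in range(0, len(order), bs):
            idx = order[start : start + bs]
            raw = augment_batch(
                train_set.images[idx], aug, target_side=target_side,
                batch_index=global_batch,
            )
            global_batch += 1
            x = normalizer.transform(raw)
            y = train_set.labels[idx]
            logits = model.forward(x, training=True)
            probs = softmax(logits)
            correct += int((probs.argmax(axis=1) == y).sum())
            seen += len(y)
            _, dlogits = weighted_cross_entropy(probs, y, weights)
            model.backward(dlogits)
            optimizer.step()

        val_acc = _val_accuracy(
            model, valid_set.images, valid_set.labels, normalizer
        )
        history.append(EpochRecord(
            epoch=epoch,
            accuracy=correct / max(seen, 1),
            val_accuracy=val_acc,
            hyperparams=_snapshot(state, aug),
            changes=changes,
            timestamp=time.time(),
        ))
        if val_acc > best_val:
            best_val, best_epoch = val_acc, epoch
            best_weights = model.get_weights()

    if best_weights is not None:
        model.set_weights(best_weights)

    checkpoint_path = meta_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        checkpoint_path = str(out_dir / f"{run_name}_best.npz")
        save_checkpoint(model, checkpoint_path, optimizer=optimizer)
        history.to_csv(out_dir / f"{run_name}_history.csv")
        meta_path = str(out_dir / f"{run_name}_meta.yaml")
        write_meta(
            history, config, {"train": train_set, "valid": valid_set},
            model.spec, meta_path,
        )

    return TrainResult(
        history=history,
        best_epoch=best_epoch,
        best_val_accuracy=best_val,
        checkpoint_path=checkpoint_path,
        meta_path=meta_path,
        normalization=normalizer.to_spec(),
    )


# ---------------------------------------------------------------------------
# Provenance
# ---------------------------------------------------------------------------

def write_meta(history: TrainingHistory, config: TrainingConfig, datasets,
               model_spec, path):
    """Write the run meta-file (YAML): everything needed to re-run."""
    meta = {
        "software": {"name": "imgtrain", "version": _version},
        "seed": int(config.seed),
        "config": config.to_dict(),
        "model": model_spec.to_dict() if model_spec else None,
        "datasets": {
            name: {
                "fingerprint": ds.fingerprint(),
                "n": len(ds),
                "class_names": list(ds.class_names),
                "split": ds.split,
            }
            for name, ds in datasets.items()
        },
        "epochs": [
            {
                "epoch": r.epoch,
                "accuracy": float(r.accuracy),
                "val_accuracy": float(r.val_accuracy),
                "hyperparams": r.hyperparams,
                "timestamp": float(r.timestamp),
            }
            for r in history
        ],
        "change_events": history.change_events(),
        "best": {
            "epoch": history.best_epoch().epoch,
            "val_accuracy": float(history.best_epoch().val_accuracy),
        },
    }
    Path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_meta(path):
    return yaml.safe_load(Path(path).read_text())


def replay_from_meta(meta_path, train_set: ImageSet, valid_set: ImageSet,
                     out_dir=None):
    """Re-run a training run from its meta-file.

    Dataset fingerprints must match those recorded; the scripted change
    events are replayed at their original epochs, reproducing the original
    history bit-for-bit.
    """
    meta = read_meta(meta_path)
    for name, ds in (("train", train_set), ("valid", valid_set)):
        want = meta["datasets"][name]["fingerprint"]
        got = ds.fingerprint()
        if want != got:
            raise ValueError(
                f"{name} dataset fingerprint mismatch: meta has {want[:12]}…, "
                f"data has {got[:12]}…"
            )
    config = TrainingConfig.from_dict(meta["config"])
    spec = meta["model"]
    model, _ = build_model(
        spec["name"], spec["input_side"], spec["channels"],
        spec["n_classes"], seed=config.seed, dropout_rate=config.dropout_rate,
    )
    model.set_trainable_mask(spec["trainable"])
    schedule: dict = {}
    for ev in meta["change_events"]:
        schedule.setdefault(int(ev["epoch"]), {})[ev["key"]] = ev["new"]
    control = {"schedule": schedule} if schedule else None
    return train(model, train_set, valid_set, config, control_source=control,
                 out_dir=out_dir)
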