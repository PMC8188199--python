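"""Run orchestration: configuration files, run directories, model export.

A :class:`RunConfig` (usually read from a YAML file) names a task and its
inputs; :func:`run` executes it, writing all artifacts — checkpoints,
meta-file, history CSV, evaluation reports, logs — under a timestamped run
directory and returning its path.  :func:`export_model` re-serializes a
checkpoint (the native ``.npz`` format is supported).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .augment import AugmentationConfig
from .estimators import ImageClassifier, TilePipeline
from .evaluate import evaluate, mean_sd
from .imageset import ImageSet, load_folder, load_hdf5, save_hdf5
from .model_zoo import load_checkpoint, save_checkpoint
from .synthdata import make_shapes_dataset, make_stained_culture
from .tilepipe import MaskedImage

__all__ = ["RunConfig", "run", "export_model", "EXPORT_FORMATS"]

EXPORT_FORMATS = ("native",)

log = logging.getLogger("imgtrain")

TASKS = ("train", "evaluate", "tilepipe", "synth", "export")


@dataclass
class RunConfig:
    task: str
    out_dir: str = "runs"
    seed: int = 0
    # dataset paths (HDF5 canonical layout or class folders)
    train_data: str | None = None
    valid_data: str | None = None
    test_data: str | None = None
    model_path: str | None = None
    control_file: str | None = None
    # estimator / training settings
    architecture: str = "lenet5"
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 0.01
    momentum: float = 0.9
    dropout_rate: float = 0.0
    n_per_class: int | None = None
    class_weight: object = "uniform"
    normalization: str = "div255"
    augmentation: dict | None = None
    # synth settings
    synth_kind: str = "shapes"
    n_classes: int = 4
    n_per_class_synth: int = 50
    side: int = 32
    n_images: int = 10
    # tilepipe settings
    tile_side: int = 32
    min_marked: int = 5
    validation_images: int = 2
    # export settings
    export_format: str = "native"

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(
                f"invalid config field 'task': {self.task!r}; choose from "
                f"{', '.join(TASKS)}"
            )

    @classmethod
    def from_yaml(cls, path, **overrides):
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(payload, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValueError(
                f"invalid config field(s): {', '.join(sorted(unknown))}"
            )
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)

    def defaults_yaml(self):
        from dataclasses import asdict

        return yaml.safe_dump(asdict(self), sort_keys=False)


def _load_dataset(path, split) -> ImageSet:
    path = Path(path)
    if path.is_dir():
        return load_folder(path, split=split)
    return load_hdf5(path, split=split)


def _run_dir(config: RunConfig) -> Path:
    stamp = time.strftime("%Y%m%d-%H%M%S")
    out = Path(config.out_dir) / f"{config.task}-{stamp}"
    suffix = 0
    while out.exists():
        suffix += 1
        out = Path(config.out_dir) / f"{config.task}-{stamp}-{suffix}"
    out.mkdir(parents=True)
    return out


def _setup_logging(run_dir: Path):
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def run(config: RunConfig) -> Path:
    """Execute a configured task; returns the run directory.

    Raises on error (the CLI maps exceptions to a nonzero exit status with
    module provenance in the message).
    """
    run_dir = _run_dir(config)
    handler = _setup_logging(run_dir)
    try:
        (run_dir / "config.yaml").write_text(config.defaults_yaml())
        log.info("task %s starting in %s (seed %d)", config.task, run_dir,
                 config.seed)
        if config.task == "synth":
            _task_synth(config, run_dir)
        elif config.task == "train":
            _task_train(config, run_dir)
        elif config.task == "evaluate":
            _task_evaluate(config, run_dir)
        elif config.task == "tilepipe":
            _task_tilepipe(config, run_dir)
        elif config.task == "export":
            export_model(config.model_path, config.export_format,
                         run_dir / "exported.npz")
        log.info("task %s finished", config.task)
        return run_dir
    finally:
        log.removeHandler(handler)
        handler.close()


def _task_synth(config: RunConfig, run_dir: Path):
    if config.synth_kind == "shapes":
        ds = make_shapes_dataset(
            n_classes=config.n_classes, n_per_class=config.n_per_class_synth,
            side=config.side, seed=config.seed,
        )
        save_hdf5(ds, run_dir / "shapes.h5")
        log.info("wrote %d shape images (%d classes)", len(ds), ds.n_classes)
    elif config.synth_kind == "stained":
        import h5py

        masked = make_stained_culture(
            n_images=config.n_images, seed=config.seed
        )
        with h5py.File(run_dir / "stained.h5", "w") as f:
            f.create_dataset(
                "images", data=np.stack([m.image for m in masked]),
                compression="gzip",
            )
            f.create_dataset(
                "masks", data=np.stack([m.mask for m in masked]),
                compression="gzip",
            )
            f.attrs["source_ids"] = [m.source_id for m in masked]
        log.info("wrote %d stained-culture images with masks", len(masked))
    else:
        raise ValueError(
            f"invalid config field 'synth_kind': {config.synth_kind!r}"
        )


def _estimator(config: RunConfig, run_dir: Path | None) -> ImageClassifier:
    aug = (
        AugmentationConfig.from_dict(config.augmentation)
        if config.augmentation else None
    )
    return ImageClassifier(
        architecture=config.architecture,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        momentum=config.momentum,
        dropout_rate=config.dropout_rate,
        n_per_class=config.n_per_class,
        class_weight=config.class_weight,
        augmentation=aug,
        normalization=config.normalization,
        control_source=config.control_file,
        out_dir=str(run_dir) if run_dir else None,
        random_state=config.seed,
    )


def _task_train(config: RunConfig, run_dir: Path):
    if not config.train_data or not config.valid_data:
        raise ValueError("invalid config field 'train_data'/'valid_data': "
                         "both are required for task 'train'")
    train_set = _load_dataset(config.train_data, "train")
    valid_set = _load_dataset(config.valid_data, "valid")
    clf = _estimator(config, run_dir)
    model = None
    if config.model_path:
        model = load_checkpoint(config.model_path)
    clf.fit(train_set, validation_data=valid_set, model=model)
    log.info("best validation accuracy %.4f at epoch %d",
             clf.best_val_accuracy_, clf.best_epoch_)


def _task_evaluate(config: RunConfig, run_dir: Path):
    if not config.model_path or not config.test_data:
        raise ValueError("invalid config field 'model_path'/'test_data': "
                         "both are required for task 'evaluate'")
    model = load_checkpoint(config.model_path)
    data = _load_dataset(config.test_data, "test")

    class _Predictor:
        def __init__(self, model, method):
            from .imageset import Normalizer

            self.model = model
            self.norm = Normalizer(method=method)
            if method == "dataset_standard":
                raise ValueError(
                    "dataset_standard evaluation needs the training set; "
                    "use the library API"
                )

        def predict_proba(self, images):
            return self.model.predict_proba(self.norm.transform(images))

    report = evaluate(_Predictor(model, config.normalization), data)
    report.to_csv(run_dir / "metrics.csv")
    report.to_json(run_dir / "report.json")
    report.confusion_to_csv(run_dir / "confusion.csv")
    log.info("test accuracy %.4f on %d images", report.accuracy, len(data))


def _task_tilepipe(config: RunConfig, run_dir: Path):
    if not config.train_data:
        raise ValueError(
            "invalid config field 'train_data': required for task 'tilepipe'"
        )
    import h5py

    with h5py.File(config.train_data, "r") as f:
        images = f["images"][...]
        masks = f["masks"][...]
        ids = [
            s.decode() if isinstance(s, bytes) else str(s)
            for s in f.attrs.get(
                "source_ids", [f"img-{i}" for i in range(len(images))]
            )
        ]
    masked = [
        MaskedImage(image=images[i], mask=masks[i], source_id=ids[i])
        for i in range(len(images))
    ]
    pipe = TilePipeline(
        tile_side=config.tile_side, min_marked=config.min_marked,
        validation_images=config.validation_images,
        architecture=config.architecture, epochs=config.epochs,
        learning_rate=config.learning_rate, random_state=config.seed,
    )
    pipe.fit(masked)
    held_out = [m for m in masked if m.source_id in pipe.valid_sources_]
    accs = pipe.per_image_accuracies(held_out)
    mean, sd = mean_sd(accs)
    for m, acc in zip(held_out, accs):
        tm, probs = pipe.predict(m.image, source_id=m.source_id)
        tm.to_csv(run_dir / f"{m.source_id}_tilemap.csv")
        tm.to_table(probs[..., 1]).to_csv(
            run_dir / f"{m.source_id}_tiles.csv", index=False
        )
    log.info("held-out per-image accuracy %.4f +- %s over %d images",
             mean, f"{sd:.4f}" if sd is not None else "n/a", len(accs))


def export_model(checkpoint_path, fmt, out_path):
    """Re-serialize a checkpoint; supported formats: native (.npz)."""
    if fmt not in EXPORT_FORMATS:
        raise ValueError(
            f"unsupported export format {fmt!r}; supported formats: "
            f"{', '.join(EXPORT_FORMATS)}"
        )
    model = load_checkpoint(checkpoint_path)  # validates the checkpoint
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "native":
        save_checkpoint(model, out_path)
    return out_path
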