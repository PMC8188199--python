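"""Scikit-learn style estimators wrapping the training workflow.

:class:`ImageClassifier` is the headline API: a classifier over uint8 image
arrays (N, H, W, C) with ``fit`` / ``predict`` / ``predict_proba`` /
``score``, ``get_params`` / ``set_params``, and fitted attributes with a
trailing underscore.  It composes the model zoo, augmentation, balanced
sampling, normalization, and the epoch loop with live hyper-parameter
control and provenance logging.

:class:`TilePipeline` runs segmentation-as-classification end to end: fit
on mask-labeled images, predict per-image tile maps, score by mean
per-image tile accuracy.

Note the feature space is images, not a flat feature matrix, so these
estimators are not ``check_estimator``-conformant; they do follow the
sklearn parameter and fitted-attribute conventions.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from .augment import AugmentationConfig
from .imageset import ImageSet, Normalizer
from .model_zoo import build_model, check_geometry, set_trainable
from .train import TrainingConfig, train
from . import tilepipe as _tp
from .evaluate import mean_sd

__all__ = ["ImageClassifier", "TilePipeline"]


def _as_imageset(X, y, class_names=None, split="train"):
    if isinstance(X, ImageSet):
        return X
    X = np.asarray(X)
    y = np.asarray(y)
    k = int(y.max()) + 1 if class_names is None else len(class_names)
    names = class_names or [str(i) for i in range(k)]
    return ImageSet(
        images=X,
        labels=y,
        class_names=names,
        source_ids=[f"{split}-{i}" for i in range(len(y))],
        split=split,
    )


class ImageClassifier(ClassifierMixin, BaseEstimator):
    """CNN/MLP image classifier with augmentation and balanced sampling.

    Parameters
    ----------
    architecture : str
        Name in the model zoo (``lenet5``, ``nitta_6layer``,
        ``residual_10layer``, ``mlp_64_32``, ``mlp_256_128``).
    epochs, batch_size, learning_rate, momentum, dropout_rate
        Optimization settings (SGD with momentum, class-weighted softmax
        cross-entropy).
    n_per_class : int or None
        Per-epoch balanced sample size per class; ``None`` trains on the
        full shuffled set each epoch.
    class_weight : "uniform" | "inverse_frequency" | sequence
        Loss coefficients per class.
    augmentation : AugmentationConfig or None
        Stochastic batch augmentation; ``None`` disables it.
    normalization : str
        ``div255`` | ``dataset_standard`` | ``per_image_standard``.
    validation_fraction : float
        Stratified share of the training data held out for per-epoch
        validation when no explicit validation set is passed to ``fit``.
    trainable_mask : sequence of bool or None
        Per-layer freeze mask applied after construction (transfer
        learning); ``None`` trains everything.
    control_source : path or dict or None
        Live hyper-parameter control polled between epochs.
    out_dir : path or None
        When set, the best checkpoint, history CSV, and meta-file land
        there.
    random_state : int
        Seeds weight init, sampling, dropout, and augmentation.
    """

    def __init__(self, architecture="lenet5", epochs=10, batch_size=32,
                 learning_rate=0.01, momentum=0.9, dropout_rate=0.0,
                 n_per_class=None, class_weight="uniform", augmentation=None,
                 normalization="div255", validation_fraction=0.2,
                 trainable_mask=None, control_source=None, out_dir=None,
                 random_state=0):
        self.architecture = architecture
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.dropout_rate = dropout_rate
        self.n_per_class = n_per_class
        self.class_weight = class_weight
        self.augmentation = augmentation
        self.normalization = normalization
        self.validation_fraction = validation_fraction
        self.trainable_mask = trainable_mask
        self.control_source = control_source
        self.out_dir = out_dir
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y=None, validation_data=None, model=None):
        """Fit on images ``X`` (N, H, W, C uint8) with labels ``y``.

        ``validation_data`` is ``(X_valid, y_valid)`` or an ``ImageSet``;
        without it a stratified ``validation_fraction`` split is made.
        ``model`` continues training from an existing network (e.g. a
        loaded checkpoint) instead of building a fresh one.
        """
        if isinstance(X, ImageSet):
            train_set, valid_set = X, None
            if validation_data is not None:
                valid_set = (
                    validation_data
                    if isinstance(validation_data, ImageSet)
                    else _as_imageset(*validation_data,
                                      class_names=X.class_names, split="valid")
                )
        else:
            X = np.asarray(X)
            y = np.asarray(y)
            if validation_data is not None:
                train_set = _as_imageset(X, y)
                valid_set = (
                    validation_data
                    if isinstance(validation_data, ImageSet)
                    else _as_imageset(*validation_data,
                                      class_names=train_set.class_names,
                                      split="valid")
                )
            else:
                idx_tr, idx_va = train_test_split(
                    np.arange(len(y)),
                    test_size=self.validation_fraction,
                    random_state=self.random_state,
                    stratify=y,
                )
                train_set = _as_imageset(X[idx_tr], y[idx_tr])
                valid_set = _as_imageset(
                    X[idx_va], y[idx_va],
                    class_names=train_set.class_names, split="valid",
                )
        if valid_set is None:
            raise ValueError(
                "an ImageSet input needs explicit validation_data"
            )

        side, _, channels = train_set.image_shape
        k = train_set.n_classes
        if model is None:
            model, spec = build_model(
                self.architecture, side, channels, k,
                seed=self.random_state, dropout_rate=self.dropout_rate,
            )
        else:
            check_geometry(model, train_set.images, k)
            spec = model.spec
        if self.trainable_mask is not None:
            set_trainable(model, list(self.trainable_mask))

        config = TrainingConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            n_per_class=self.n_per_class,
            class_weights=self.class_weight,
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            dropout_rate=self.dropout_rate,
            seed=self.random_state,
            augmentation=self.augmentation,
            normalization=self.normalization,
        )
        result = train(
            model, train_set, valid_set, config,
            control_source=self.control_source, out_dir=self.out_dir,
        )
        self.model_ = model
        self.spec_ = spec
        self.classes_ = np.arange(k)
        self.class_names_ = list(train_set.class_names)
        self.history_ = result.history
        self.best_epoch_ = result.best_epoch
        self.best_val_accuracy_ = result.best_val_accuracy
        self.checkpoint_path_ = result.checkpoint_path
        self.meta_path_ = result.meta_path
        self.normalizer_ = Normalizer.from_spec(result.normalization)
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this ImageClassifier is not fitted yet")

    def predict_proba(self, X):
        self._check_fitted()
        images = X.images if isinstance(X, ImageSet) else np.asarray(X)
        check_geometry(self.model_, images)
        return self.model_.predict_proba(self.normalizer_.transform(images))

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X, y=None):
        if isinstance(X, ImageSet):
            y = X.labels
        return float((self.predict(X) == np.asarray(y)).mean())


class TilePipeline(BaseEstimator):
    """Train and apply a tile classifier on mask-labeled images.

    ``fit`` takes a list of :class:`~imgtrain.tilepipe.MaskedImage`; tiles
    are cut on the disjoint grid, labeled from the masks (class 1 at
    >= ``min_marked`` marked pixels), the positive class is topped up by
    random-offset oversampling, and ``classifier_params`` configure the
    underlying :class:`ImageClassifier`.
    """

    def __init__(self, tile_side=32, min_marked=5, oversample="balance",
                 validation_images=2, architecture="lenet5", epochs=15,
                 learning_rate=0.01, batch_size=32, n_per_class=None,
                 augmentation=None, random_state=0):
        self.tile_side = tile_side
        self.min_marked = min_marked
        self.oversample = oversample
        self.validation_images = validation_images
        self.architecture = architecture
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_per_class = n_per_class
        self.augmentation = augmentation
        self.random_state = random_state

    def fit(self, masked_images, y=None):
        """Fit the tile classifier; the last ``validation_images`` images
        of the input list are held out as the per-epoch validation set."""
        if len(masked_images) < 2:
            raise ValueError("need at least 2 masked images (train + valid)")
        n_val = min(self.validation_images, len(masked_images) - 1)
        train_imgs = masked_images[:-n_val] if n_val else list(masked_images)
        valid_imgs = masked_images[-n_val:] if n_val else []
        train_tiles = _tp.build_tile_dataset(
            train_imgs, tile_side=self.tile_side, min_marked=self.min_marked,
            oversample=self.oversample, seed=self.random_state, split="train",
        )
        valid_tiles = _tp.build_tile_dataset(
            valid_imgs, tile_side=self.tile_side, min_marked=self.min_marked,
            oversample=0, seed=self.random_state, split="valid",
        )
        clf = ImageClassifier(
            architecture=self.architecture,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            n_per_class=self.n_per_class,
            augmentation=self.augmentation,
            random_state=self.random_state,
        )
        clf.fit(train_tiles, validation_data=valid_tiles)
        self.classifier_ = clf
        self.train_sources_ = [m.source_id for m in train_imgs]
        self.valid_sources_ = [m.source_id for m in valid_imgs]
        return self

    def predict(self, image, source_id="image"):
        """Tile map (and per-tile probabilities) for one image."""
        if not hasattr(self, "classifier_"):
            raise RuntimeError("this TilePipeline is not fitted yet")
        return _tp.predict_tile_map(
            self.classifier_, image, tile_side=self.tile_side,
            source_id=source_id,
        )

    def score(self, masked_images, y=None):
        """Mean per-image tile accuracy against the ground-truth maps."""
        accs = self.per_image_accuracies(masked_images)
        return mean_sd(accs)[0]

    def per_image_accuracies(self, masked_images):
        out = []
        for m in masked_images:
            pred, _ = self.predict(m.image, source_id=m.source_id)
            truth = _tp.truth_tile_map(
                m, tile_side=self.tile_side, min_marked=self.min_marked
            )
            out.append(_tp.per_image_accuracy(pred, truth))
        return out
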