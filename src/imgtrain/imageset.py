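"""Uniform labeled image container and the conversions around it.

All downstream modules consume an :class:`ImageSet`: a rank-4 uint8 array
(N, H, W, C) with integer labels, class names, per-image source ids, and a
split tag.  This module provides folder and HDF5 readers, the HDF5 writer
(the canonical on-disk layout), RGB/grayscale conversion by the luminosity
method, interpolated rescaling, center-crop/pad size equalization, and the
three normalization schemes (divide-by-255, training-set standardization,
per-image standardization).

Conventions (documented, deterministic):

* row-major, origin top-left, 0-based indices, half-open intervals;
* odd crop/pad remainders go to the trailing (bottom/right) side;
* pad fill value is 0;
* luminosity output is rounded half-up and clipped to [0, 255];
* rescaled output side is ``floor(side * factor)``.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as _sk_resize

__all__ = [
    "ImageSet",
    "SizeSpec",
    "NormalizationSpec",
    "Normalizer",
    "load_folder",
    "rgb_to_gray",
    "gray_to_rgb",
    "scale_image",
    "equalize_size",
    "fit_normalizer",
    "apply_normalizer",
    "save_hdf5",
    "load_hdf5",
    "HDF5ImageSet",
]

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}

_INTERP_ORDER = {"nearest": 0, "linear": 1, "quadratic": 2, "cubic": 3}


# ---------------------------------------------------------------------------
# Container
# ---------------------------------------------------------------------------

@dataclass
class ImageSet:
    """N uniform 8-bit images + labels + class names + provenance ids."""

    images: np.ndarray
    labels: np.ndarray
    class_names: list
    source_ids: list
    split: str = "train"

    def __post_init__(self):
        self.images = np.asarray(self.images)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.class_names = [str(c) for c in self.class_names]
        self.source_ids = [str(s) for s in self.source_ids]
        self.validate()

    def validate(self):
        if self.images.ndim == 3:  # (N, H, W) -> single channel
            self.images = self.images[..., None]
        if self.images.ndim != 4:
            raise ValueError(
                f"images must be (N, H, W, C), got shape {self.images.shape}"
            )
        if self.images.dtype != np.uint8:
            raise ValueError(f"images must be uint8, got {self.images.dtype}")
        n, _, _, c = self.images.shape
        if c not in (1, 3):
            raise ValueError(f"channel count must be 1 or 3, got {c}")
        if len(self.labels) != n or len(self.source_ids) != n:
            raise ValueError(
                f"length mismatch: {n} images, {len(self.labels)} labels, "
                f"{len(self.source_ids)} source ids"
            )
        k = len(self.class_names)
        if n and (self.labels.min() < 0 or self.labels.max() >= k):
            raise ValueError(
                f"labels must lie in [0, {k - 1}], got range "
                f"[{self.labels.min()}, {self.labels.max()}]"
            )
        if self.split not in ("train", "valid", "test"):
            raise ValueError(f"split must be train/valid/test, got {self.split!r}")

    # -- basic properties ----------------------------------------------------
    def __len__(self):
        return self.images.shape[0]

    @property
    def n_classes(self):
        return len(self.class_names)

    @property
    def image_shape(self):
        return self.images.shape[1:]

    def class_counts(self):
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, indices, split=None):
        idx = np.asarray(indices)
        return ImageSet(
            images=self.images[idx],
            labels=self.labels[idx],
            class_names=list(self.class_names),
            source_ids=[self.source_ids[i] for i in idx],
            split=split or self.split,
        )

    def iter_batches(self, batch_size):
        for i in range(0, len(self), batch_size):
            yield self.images[i : i + batch_size], self.labels[i : i + batch_size]

    def fingerprint(self):
        """Content hash over pixel data, labels, and class names."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.images).tobytes())
        h.update(np.ascontiguousarray(self.labels).tobytes())
        h.update("|".join(self.class_names).encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class SizeSpec:
    """Target geometry and how to reach it."""

    target_side: int
    mode: str = "center_crop"  # center_crop | pad | scale_then_equalize
    interpolation: str = "nearest"
    scale_factor: float = 1.0

    def __post_init__(self):
        if self.target_side < 1:
            raise ValueError("target_side must be >= 1")
        if self.mode not in ("center_crop", "pad", "scale_then_equalize"):
            raise ValueError(f"unknown size mode {self.mode!r}")
        if self.interpolation not in _INTERP_ORDER:
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")


@dataclass
class NormalizationSpec:
    """Normalization method plus fitted statistics (dataset_standard only)."""

    method: str = "div255"
    fitted_mean: float | None = None
    fitted_sd: float | None = None

    def __post_init__(self):
        if self.method not in ("div255", "dataset_standard", "per_image_standard"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if self.method == "dataset_standard" and self.fitted_sd is not None:
            if self.fitted_sd <= 0:
                raise ValueError("fitted_sd must be > 0")


# ---------------------------------------------------------------------------
# Conversions
# ---------------------------------------------------------------------------

def rgb_to_gray(img):
    """Luminosity conversion: round-half-up(0.21 R + 0.72 G + 0.07 B).

    The weights reflect the human eye's higher sensitivity to green and sum
    to 1, so neutral grays map to themselves.  Accepts (H, W, 3) or
    (N, H, W, 3); returns the same rank with a single trailing channel.
    """
    img = np.asarray(img)
    if img.shape[-1] == 1:
        raise ValueError("input is already grayscale (1 channel)")
    if img.shape[-1] != 3:
        raise ValueError(f"expected 3 channels, got {img.shape[-1]}")
    if np.issubdtype(img.dtype, np.integer):
        # exact decimal arithmetic: round-half-up of (21R + 72G + 7B)/100
        x = img.astype(np.int64)
        gray = (21 * x[..., 0] + 72 * x[..., 1] + 7 * x[..., 2] + 50) // 100
    else:
        w = np.array([0.21, 0.72, 0.07])
        gray = np.floor(img.astype(np.float64) @ w + 0.5)
    gray = np.clip(gray, 0, 255).astype(np.uint8)
    return gray[..., None]


def gray_to_rgb(img):
    """Stack three copies of a grayscale image along the channel axis."""
    img = np.asarray(img)
    if img.shape[-1] == 3:
        raise ValueError("input is already RGB (3 channels)")
    if img.shape[-1] != 1:
        raise ValueError(f"expected 1 channel, got {img.shape[-1]}")
    return np.repeat(img, 3, axis=-1)


def scale_image(img, factor, interpolation="nearest"):
    """Rescale by ``factor``; output sides are ``floor(side * factor)``.

    Interpolation is one of nearest / linear / quadratic / cubic.
    """
    if factor <= 0:
        raise ValueError(f"scale factor must be > 0, got {factor}")
    if interpolation not in _INTERP_ORDER:
        raise ValueError(
            f"unknown interpolation {interpolation!r}; choose from "
            f"{sorted(_INTERP_ORDER)}"
        )
    img = np.asarray(img)
    if factor == 1.0:
        return img.copy()
    h, w = img.shape[:2]
    new_h, new_w = int(h * factor), int(w * factor)
    if new_h < 1 or new_w < 1:
        raise ValueError(f"factor {factor} collapses a {h}x{w} image")
    out = _sk_resize(
        img,
        (new_h, new_w) + img.shape[2:],
        order=_INTERP_ORDER[interpolation],
        preserve_range=True,
        anti_aliasing=False,
        mode="edge",
    )
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(img.dtype)


def _fit_axis(img, axis, target, allow_crop, allow_pad):
    size = img.shape[axis]
    if size == target:
        return img
    if size > target:
        if not allow_crop:
            raise ValueError(
                f"axis {axis} has size {size} > target {target}; use mode "
                "'center_crop' (or 'scale_then_equalize')"
            )
        start = (size - target) // 2  # extra removed pixel on trailing side
        sl = [slice(None)] * img.ndim
        sl[axis] = slice(start, start + target)
        return img[tuple(sl)]
    if not allow_pad:
        raise ValueError(
            f"axis {axis} has size {size} < target {target}; use mode 'pad' "
            "(or 'scale_then_equalize')"
        )
    total = target - size
    before = total // 2  # extra padded pixel on trailing side
    pads = [(0, 0)] * img.ndim
    pads[axis] = (before, total - before)
    return np.pad(img, pads, constant_values=0)


def equalize_size(img, spec: SizeSpec):
    """Bring an image to ``target_side`` x ``target_side``.

    ``center_crop`` removes equal margins (extra pixel trailing when odd),
    ``pad`` adds equal zero margins, ``scale_then_equalize`` first rescales
    by ``scale_factor`` then crops or pads per axis as needed.  Rectangular
    inputs are equalized per axis.
    """
    img = np.asarray(img)
    t = spec.target_side
    if spec.mode == "scale_then_equalize":
        img = scale_image(img, spec.scale_factor, spec.interpolation)
        allow_crop = allow_pad = True
    elif spec.mode == "center_crop":
        allow_crop, allow_pad = True, False
    else:
        allow_crop, allow_pad = False, True
    img = _fit_axis(img, 0, t, allow_crop, allow_pad)
    img = _fit_axis(img, 1, t, allow_crop, allow_pad)
    return img


def center_crop(img, target_side):
    """Square center crop with the trailing-side convention."""
    img = np.asarray(img)
    out = _fit_axis(img, 0, target_side, True, False)
    return _fit_axis(out, 1, target_side, True, False)


# ---------------------------------------------------------------------------
# Normalization (fit on train only, apply anywhere)
# ---------------------------------------------------------------------------

class Normalizer:
    """Scikit-learn style transformer over (N, H, W, C) uint8 image arrays.

    ``div255`` maps intensities to [0, 1]; ``dataset_standard`` standardizes
    with the mean/SD of the whole training set (population moments, fitted
    on training images only); ``per_image_standard`` standardizes each image
    with its own moments, substituting SD=1 for constant images.
    """

    def __init__(self, method="div255"):
        self.method = method

    def fit(self, X, y=None):
        NormalizationSpec(method=self.method)  # validates method name
        if self.method == "dataset_standard":
            X = np.asarray(X, dtype=np.float64)
            self.mean_ = float(X.mean())
            sd = float(X.std())
            if sd <= 0:
                raise ValueError(
                    "training set is constant; dataset_standard undefined"
                )
            self.sd_ = sd
        else:
            self.mean_ = None
            self.sd_ = None
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float32)
        if self.method == "div255":
            return X / np.float32(255.0)
        if self.method == "dataset_standard":
            if getattr(self, "sd_", None) is None:
                raise RuntimeError("dataset_standard Normalizer is not fitted")
            return (X - np.float32(self.mean_)) / np.float32(self.sd_)
        # per_image_standard
        axes = tuple(range(1, X.ndim))
        mean = X.mean(axis=axes, keepdims=True)
        sd = X.std(axis=axes, keepdims=True)
        if np.any(sd == 0):
            warnings.warn(
                "constant image(s) in per_image_standard; substituting SD=1",
                stacklevel=2,
            )
            sd = np.where(sd == 0, 1.0, sd)
        return ((X - mean) / sd).astype(np.float32)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    # sklearn plumbing
    def get_params(self, deep=True):
        return {"method": self.method}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def to_spec(self):
        return NormalizationSpec(
            method=self.method,
            fitted_mean=getattr(self, "mean_", None),
            fitted_sd=getattr(self, "sd_", None),
        )

    @classmethod
    def from_spec(cls, spec: NormalizationSpec):
        norm = cls(method=spec.method)
        norm.mean_ = spec.fitted_mean
        norm.sd_ = spec.fitted_sd
        return norm


def fit_normalizer(train: ImageSet, method="div255") -> NormalizationSpec:
    """Fit a normalization spec on the training split only."""
    return Normalizer(method=method).fit(train.images).to_spec()


def apply_normalizer(x, spec: NormalizationSpec):
    """Apply a fitted normalization spec to an image array."""
    return Normalizer.from_spec(spec).transform(x)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _decode_file(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        if im.mode in ("RGB",):
            arr = np.asarray(im, dtype=np.uint8)
        elif im.mode in ("L",):
            arr = np.asarray(im, dtype=np.uint8)[..., None]
        elif im.mode in ("RGBA", "P", "CMYK", "LA"):
            arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
        elif im.mode in ("I", "I;16", "F"):
            arr = np.asarray(im, dtype=np.float64)
            top = arr.max() or 1.0
            arr = np.clip(np.rint(arr / top * 255), 0, 255).astype(np.uint8)
            arr = arr[..., None]
        else:
            arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    if arr.ndim == 2:
        arr = arr[..., None]
    return arr


def load_folder(root, split="train") -> ImageSet:
    """Load a one-subdirectory-per-class image tree.

    Class names are the sorted subdirectory names; unreadable files are
    skipped with a warning; a folder yielding zero usable images is an
    error, as is a mix of image shapes (equalize sizes first).
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no classes found under {root}")
    images, labels, source_ids = [], [], []
    shapes = set()
    for label, cdir in enumerate(class_dirs):
        files = sorted(
            p for p in cdir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES
        )
        for f in files:
            try:
                arr = _decode_file(f)
            except (OSError, UnidentifiedImageError, ValueError) as exc:
                warnings.warn(f"skipping unreadable image {f}: {exc}", stacklevel=2)
                continue
            shapes.add(arr.shape)
            images.append(arr)
            labels.append(label)
            source_ids.append(str(f))
    if not images:
        raise ValueError(f"no usable images under {root}")
    if len(shapes) > 1:
        raise ValueError(
            f"mixed image shapes {sorted(shapes)}; equalize sizes first "
            "(scale_image / equalize_size), then reload"
        )
    return ImageSet(
        images=np.stack(images),
        labels=np.array(labels),
        class_names=[d.name for d in class_dirs],
        source_ids=source_ids,
        split=split,
    )


def save_hdf5(dataset: ImageSet, path):
    """Write the canonical HDF5 layout: ``images``, ``labels``, attrs."""
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=dataset.images, compression="gzip")
        f.create_dataset("labels", data=dataset.labels)
        str_dt = h5py.string_dtype()
        f.create_dataset(
            "source_ids", data=np.array(dataset.source_ids, dtype=object),
            dtype=str_dt,
        )
        f.attrs["class_names"] = dataset.class_names
        f.attrs["split"] = dataset.split
    return path


def load_hdf5(path, split=None) -> ImageSet:
    with h5py.File(path, "r") as f:
        images = f["images"][...]
        labels = f["labels"][...]
        class_names = [
            c.decode() if isinstance(c, bytes) else str(c)
            for c in f.attrs["class_names"]
        ]
        if "source_ids" in f:
            source_ids = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in f["source_ids"][...]
            ]
        else:
            source_ids = [f"{path}#{i}" for i in range(len(labels))]
        file_split = f.attrs.get("split", "train")
        if isinstance(file_split, bytes):
            file_split = file_split.decode()
    if images.ndim == 3:
        images = images[..., None]
    return ImageSet(
        images=images,
        labels=labels,
        class_names=class_names,
        source_ids=source_ids,
        split=split or str(file_split),
    )


class HDF5ImageSet:
    """Disk-backed view of the canonical HDF5 layout.

    Presents the same contract as :class:`ImageSet` (labels, class names,
    batch iteration) but streams image batches from disk instead of holding
    them in RAM, for datasets larger than memory.  Use as a context manager
    or call :meth:`close`.
    """

    def __init__(self, path, split=None):
        self._file = h5py.File(path, "r")
        self._images = self._file["images"]
        self.labels = self._file["labels"][...].astype(np.int64)
        self.class_names = [
            c.decode() if isinstance(c, bytes) else str(c)
            for c in self._file.attrs["class_names"]
        ]
        if "source_ids" in self._file:
            self.source_ids = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in self._file["source_ids"][...]
            ]
        else:
            self.source_ids = [f"{path}#{i}" for i in range(len(self.labels))]
        file_split = self._file.attrs.get("split", "train")
        if isinstance(file_split, bytes):
            file_split = file_split.decode()
        self.split = split or str(file_split)

    def __len__(self):
        return self._images.shape[0]

    @property
    def n_classes(self):
        return len(self.class_names)

    @property
    def image_shape(self):
        shape = self._images.shape[1:]
        return shape if len(shape) == 3 else shape + (1,)

    def iter_batches(self, batch_size):
        for i in range(0, len(self), batch_size):
            imgs = self._images[i : i + batch_size]
            if imgs.ndim == 3:
                imgs = imgs[..., None]
            yield imgs, self.labels[i : i + batch_size]

    def load(self) -> ImageSet:
        """Materialize the whole container in RAM."""
        imgs = self._images[...]
        if imgs.ndim == 3:
            imgs = imgs[..., None]
        return ImageSet(
            images=imgs,
            labels=self.labels,
            class_names=self.class_names,
            source_ids=self.source_ids,
            split=self.split,
        )

    def close(self):
        self._file.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
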