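"""Stochastic training-batch augmentation.

Operator order is fixed: flips -> rotation -> shift -> zoom -> additive
brightness -> multiplicative brightness -> Gaussian noise -> single clip to
[0, 255] -> final center crop to the target side.  The final crop comes
*after* rotation so that rotation edge artifacts fall into the cropped
margin rather than the training image.  All brightness operations act on
raw 0-255 intensities, i.e. before any normalization.

Randomness: each enabled operator draws from a single per-image stream in
operator order.  The stream is seeded from ``(config.seed, batch_index)``,
so an identical (batch, config, batch index) triple produces bit-identical
output in any process.

Geometric resampling uses nearest neighbor (keeps the 8-bit value set
intact) and fills vacated pixels with 0.  Rotations by exact multiples of
90 degrees on square frames take a lossless grid-rotation path.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy import ndimage

from .imageset import center_crop

__all__ = ["AugmentationConfig", "augment_batch", "preset_config", "PRESETS"]


@dataclass
class AugmentationConfig:
    flip_horizontal: bool = False  # mirror across the central vertical axis
    flip_vertical: bool = False
    rotation_max: float = 0.0      # degrees, uniform in +-rotation_max
    shift_max: int = 0             # pixels per axis, uniform integer
    zoom_delta: float = 0.0        # scale uniform in [1-delta, 1+delta]
    brightness_add_max: float = 0.0    # intensity units, uniform additive
    brightness_mult_range: tuple = (1.0, 1.0)  # uniform multiplier
    noise_scale_max: float = 0.0   # Gaussian sd uniform in [0, max]
    seed: int = 0

    def __post_init__(self):
        self.brightness_mult_range = tuple(self.brightness_mult_range)
        if min(self.rotation_max, self.shift_max, self.zoom_delta,
               self.brightness_add_max, self.noise_scale_max) < 0:
            raise ValueError("augmentation maxima must be >= 0")
        lo, hi = self.brightness_mult_range
        if not (0 < lo <= hi):
            raise ValueError(
                f"brightness_mult_range must satisfy 0 < low <= high, got "
                f"({lo}, {hi})"
            )
        if self.zoom_delta >= 1.0:
            raise ValueError("zoom_delta must be < 1")

    def to_dict(self):
        d = asdict(self)
        d["brightness_mult_range"] = list(self.brightness_mult_range)
        return d

    @classmethod
    def from_dict(cls, d):
        return cls(**d)

    def replace(self, **kwargs):
        return replace(self, **kwargs)

    def is_identity(self):
        return (
            not self.flip_horizontal
            and not self.flip_vertical
            and self.rotation_max == 0
            and self.shift_max == 0
            and self.zoom_delta == 0
            and self.brightness_add_max == 0
            and self.brightness_mult_range == (1.0, 1.0)
            and self.noise_scale_max == 0
        )


# The two parameterizations used for the benchmark training runs.
PRESETS = {
    "cifar_gray": AugmentationConfig(
        flip_horizontal=True,
        rotation_max=5.0,
        shift_max=1,
        zoom_delta=0.35,
        brightness_add_max=15.0,
        brightness_mult_range=(0.6, 1.4),
        noise_scale_max=10.0,
    ),
    "fashion_mnist": AugmentationConfig(
        flip_horizontal=True,
        rotation_max=10.0,
        shift_max=1,
        zoom_delta=0.0,
        brightness_add_max=15.0,
        brightness_mult_range=(0.7, 1.3),
        noise_scale_max=5.0,
    ),
}


def preset_config(name: str) -> AugmentationConfig:
    """Return one of the documented benchmark augmentation presets."""
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available presets: "
            f"{', '.join(sorted(PRESETS))}"
        )
    return replace(PRESETS[name])


def rotate_nearest(img, angle):
    """Rotate about the center, nearest neighbor, zero fill, same canvas."""
    if angle % 90 == 0 and img.shape[0] == img.shape[1]:
        return np.ascontiguousarray(np.rot90(img, k=int(angle // 90) % 4))
    return ndimage.rotate(
        img, angle, axes=(1, 0), reshape=False, order=0, mode="constant",
        cval=0, prefilter=False,
    )


def shift_int(img, dy, dx):
    """Integer-pixel shift with zero fill (dy down, dx right)."""
    out = np.zeros_like(img)
    h, w = img.shape[:2]
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def zoom_nearest(img, factor):
    """Zoom about the center, nearest neighbor, canvas size preserved."""
    h, w = img.shape[:2]
    zoomed = ndimage.zoom(
        img, (factor, factor) + (1,) * (img.ndim - 2), order=0,
        mode="constant", cval=0, prefilter=False,
    )
    # restore the canvas: crop when zoomed in, zero-pad when zoomed out
    from .imageset import _fit_axis

    zoomed = _fit_axis(zoomed, 0, h, True, True)
    zoomed = _fit_axis(zoomed, 1, w, True, True)
    return zoomed


def augment_batch(batch, config: AugmentationConfig, target_side=None,
                  batch_index=0, rng=None):
    """Augment a batch of images and center-crop to ``target_side``.

    ``batch`` is (N, H, W, C) uint8 at working size >= target size; the
    margin absorbs rotation/shift/zoom edge effects.  Output is uint8 in
    [0, 255], deterministic for a given (config.seed, batch_index).
    """
    batch = np.asarray(batch)
    if batch.ndim != 4:
        raise ValueError(f"batch must be (N, H, W, C), got {batch.shape}")
    h, w = batch.shape[1:3]
    if target_side is None:
        target_side = min(h, w)
    if h < target_side or w < target_side:
        raise ValueError(
            f"working size {h}x{w} is smaller than target side {target_side}"
        )
    if rng is None:
        rng = np.random.default_rng([int(config.seed), int(batch_index)])

    lo, hi = config.brightness_mult_range
    out = np.empty(
        (batch.shape[0], target_side, target_side, batch.shape[3]), np.uint8
    )
    for i in range(batch.shape[0]):
        img = batch[i]
        if config.flip_horizontal and rng.random() < 0.5:
            img = img[:, ::-1]
        if config.flip_vertical and rng.random() < 0.5:
            img = img[::-1, :]
        if config.rotation_max > 0:
            angle = rng.uniform(-config.rotation_max, config.rotation_max)
            img = rotate_nearest(img, angle)
        if config.shift_max > 0:
            dy, dx = rng.integers(-config.shift_max, config.shift_max + 1, 2)
            img = shift_int(img, int(dy), int(dx))
        if config.zoom_delta > 0:
            factor = rng.uniform(1 - config.zoom_delta, 1 + config.zoom_delta)
            img = zoom_nearest(img, factor)
        x = img.astype(np.float64)
        if config.brightness_add_max > 0:
            x = x + rng.uniform(-config.brightness_add_max,
                                config.brightness_add_max)
        if (lo, hi) != (1.0, 1.0):
            x = x * rng.uniform(lo, hi)
        if config.noise_scale_max > 0:
            sd = rng.uniform(0.0, config.noise_scale_max)
            if sd > 0:
                x = x + rng.normal(0.0, sd, x.shape)
        x = np.clip(np.rint(x), 0, 255).astype(np.uint8)
        out[i] = center_crop(x, target_side)
    return out
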