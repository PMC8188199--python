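"""Synthetic fixtures for every pipeline in the package.

Three generators, all pure functions of their seed:

* :func:`make_shapes_dataset` — grayscale images of up to six separable
  shape families (disk, square, cross, ring, bar, triangle) with jittered
  position, size, and intensity; a stand-in for natural-image benchmarks
  that a small CNN can learn in seconds.
* :func:`make_stained_culture` — 320x320 RGB cell-culture-like images with
  reddish elliptical stain blobs on a background whose tint varies per
  image, plus the exact ground-truth pixel mask; feeds the tile pipeline.
* :func:`make_cell_events` — single-cell event crops in the style of
  imaging flow cytometry: each event is a disk whose cross-sectional area
  and interior brightness are drawn from per-population Gaussians, so
  populations separate in the classic brightness-vs-area scatter plot.

Plus the event feature extraction (area = pixel count of the cell mask,
brightness = mean grayscale over those pixels) and rectangular gating of
the feature plane used to assemble labeled datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import draw as skdraw

from .imageset import ImageSet

__all__ = [
    "PopulationSpec",
    "Gate",
    "CellEvents",
    "make_shapes_dataset",
    "make_stained_culture",
    "make_cell_events",
    "event_features",
    "apply_gate",
    "SHAPE_FAMILIES",
]

SHAPE_FAMILIES = ("disk", "square", "cross", "ring", "bar", "triangle")


@dataclass
class PopulationSpec:
    """Gaussian population in the (area, brightness) feature plane."""

    name: str
    area_mean: float       # pixels^2
    area_sd: float
    brightness_mean: float  # intensity units
    brightness_sd: float
    abundance: float        # fraction of all events

    def __post_init__(self):
        if self.area_sd <= 0 or self.brightness_sd <= 0:
            raise ValueError("population SDs must be > 0")
        if not (0 < self.abundance <= 1):
            raise ValueError("abundance must be in (0, 1]")


@dataclass
class Gate:
    """Half-open rectangular gate in the (area, brightness) plane."""

    area_range: tuple
    brightness_range: tuple

    def __post_init__(self):
        for lo, hi in (self.area_range, self.brightness_range):
            if not lo < hi:
                raise ValueError(f"gate range ({lo}, {hi}) must have lo < hi")


# ---------------------------------------------------------------------------
# Shapes
# ---------------------------------------------------------------------------

def _draw_shape(canvas, family, cy, cx, radius, intensity):
    side = canvas.shape[0]
    if family == "disk":
        rr, cc = skdraw.disk((cy, cx), radius, shape=canvas.shape)
        canvas[rr, cc] = intensity
    elif family == "square":
        r = int(radius)
        rr, cc = skdraw.rectangle(
            (cy - r, cx - r), extent=(2 * r + 1, 2 * r + 1), shape=canvas.shape
        )
        canvas[rr.astype(int), cc.astype(int)] = intensity
    elif family == "cross":
        r, arm = int(radius), max(int(radius // 3), 1)
        rr, cc = skdraw.rectangle(
            (cy - arm, cx - r), extent=(2 * arm + 1, 2 * r + 1),
            shape=canvas.shape,
        )
        canvas[rr.astype(int), cc.astype(int)] = intensity
        rr, cc = skdraw.rectangle(
            (cy - r, cx - arm), extent=(2 * r + 1, 2 * arm + 1),
            shape=canvas.shape,
        )
        canvas[rr.astype(int), cc.astype(int)] = intensity
    elif family == "ring":
        rr, cc = skdraw.disk((cy, cx), radius, shape=canvas.shape)
        canvas[rr, cc] = intensity
        rr, cc = skdraw.disk(
            (cy, cx), max(radius * 0.55, 1.5), shape=canvas.shape
        )
        canvas[rr, cc] = 0
    elif family == "bar":
        r, half = int(radius), max(int(radius // 4), 1)
        rr, cc = skdraw.rectangle(
            (cy - half, cx - r), extent=(2 * half + 1, 2 * r + 1),
            shape=canvas.shape,
        )
        canvas[rr.astype(int), cc.astype(int)] = intensity
    elif family == "triangle":
        r = radius
        rows = np.array([cy - r, cy + r, cy + r])
        cols = np.array([cx, cx - r, cx + r])
        rr, cc = skdraw.polygon(rows, cols, shape=canvas.shape)
        canvas[rr, cc] = intensity
    else:  # pragma: no cover - guarded by caller
        raise ValueError(f"unknown shape family {family!r}")
    return canvas


def make_shapes_dataset(n_classes=4, n_per_class=50, side=32, seed=0,
                        split="train") -> ImageSet:
    """Grayscale multi-class shape images that a small CNN can separate.

    Each class is one shape family with random center jitter, size jitter,
    foreground intensity in [150, 255] and a dim noisy background.
    """
    if n_classes > len(SHAPE_FAMILIES):
        raise ValueError(
            f"at most {len(SHAPE_FAMILIES)} shape classes available, "
            f"requested {n_classes}"
        )
    if side < 16:
        raise ValueError("side must be >= 16")
    rng = np.random.default_rng(seed)
    families = SHAPE_FAMILIES[:n_classes]
    images, labels, ids = [], [], []
    for label, family in enumerate(families):
        for i in range(n_per_class):
            canvas = rng.normal(30, 8, (side, side))
            jit = max(side // 16, 1)
            cy = side // 2 + rng.integers(-jit, jit + 1)
            cx = side // 2 + rng.integers(-jit, jit + 1)
            radius = rng.uniform(side * 0.28, side * 0.33)
            intensity = rng.uniform(180, 255)
            canvas = _draw_shape(canvas, family, cy, cx, radius, intensity)
            images.append(np.clip(np.rint(canvas), 0, 255).astype(np.uint8))
            labels.append(label)
            ids.append(f"shape-{seed}-{family}-{i}")
    return ImageSet(
        images=np.stack(images)[..., None],
        labels=np.array(labels),
        class_names=list(families),
        source_ids=ids,
        split=split,
    )


# ---------------------------------------------------------------------------
# Stained-culture images with ground-truth masks
# ---------------------------------------------------------------------------

def make_stained_culture(n_images=10, blob_count_range=(4, 12),
                         blob_radius_range=(8, 24),
                         background_tint_range=(0.7, 1.25), side=320,
                         seed=0):
    """RGB culture-well images with reddish stain blobs and exact masks.

    The per-image background tint and brightness vary across the range, the
    blobs are rotated ellipses whose pixels define the ground-truth mask —
    emulating stained-culture photographs that differ in brightness, color,
    and stain distribution.  Returns a list of
    :class:`~imgtrain.tilepipe.MaskedImage`.
    """
    from .tilepipe import MaskedImage  # local import; tilepipe imports us not

    lo_c, hi_c = blob_count_range
    lo_r, hi_r = blob_radius_range
    if lo_c > hi_c or lo_r > hi_r or lo_r <= 0:
        raise ValueError("invalid blob count/radius ranges")
    rng = np.random.default_rng(seed)
    out = []
    base = np.array([212.0, 198.0, 182.0])  # warm brightfield background
    for i in range(n_images):
        tint = rng.uniform(*background_tint_range)
        # mild per-channel cast so images differ in color, not just level
        cast = rng.uniform(0.92, 1.08, 3)
        bg = np.clip(base * tint * cast, 40, 250)
        img = np.ones((side, side, 3)) * bg
        img += rng.normal(0, 6, img.shape)
        mask = np.zeros((side, side), dtype=bool)
        n_blobs = int(rng.integers(lo_c, hi_c + 1))
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0, side, 2)
            r_a = rng.uniform(lo_r, hi_r)
            r_b = rng.uniform(lo_r, hi_r)
            theta = rng.uniform(0, np.pi)
            rr, cc = skdraw.ellipse(
                cy, cx, r_a, r_b, shape=(side, side), rotation=theta
            )
            color = np.array([
                rng.uniform(150, 225),   # strong red (lipid stain)
                rng.uniform(30, 85),
                rng.uniform(35, 90),
            ])
            img[rr, cc] = color + rng.normal(0, 5, (len(rr), 3))
            mask[rr, cc] = True
        out.append(
            MaskedImage(
                image=np.clip(np.rint(img), 0, 255).astype(np.uint8),
                mask=mask,
                source_id=f"culture-{seed}-{i}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cell events
# ---------------------------------------------------------------------------

@dataclass
class CellEvents:
    """Event image crops with ground-truth masks and population labels."""

    images: np.ndarray   # (N, side, side, 1) uint8
    masks: np.ndarray    # (N, side, side) bool
    labels: np.ndarray   # (N,) population index
    class_names: list

    def __len__(self):
        return self.images.shape[0]

    def feature_table(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self)):
            area, brightness = event_features(self.images[i], self.masks[i])
            rows.append(
                {
                    "event_id": i,
                    "area": area,
                    "brightness": brightness,
                    "truth_label": int(self.labels[i]),
                }
            )
        return pd.DataFrame(rows)

    def to_imageset(self, split="train") -> ImageSet:
        return ImageSet(
            images=self.images,
            labels=self.labels,
            class_names=self.class_names,
            source_ids=[f"event-{i}" for i in range(len(self))],
            split=split,
        )


_BACKGROUND = 25.0


def _disk_radius_for_area(target, side):
    """Radius whose rasterized disk pixel count best matches ``target``."""
    best_r, best_err = 1.0, np.inf
    r = max(np.sqrt(target / np.pi) - 1.5, 0.8)
    stop = np.sqrt(target / np.pi) + 2.0
    while r <= stop:
        rr, _ = skdraw.disk((side / 2, side / 2), r, shape=(side, side))
        err = abs(len(rr) - target)
        if err < best_err:
            best_err, best_r = err, r
        r += 0.05
    return best_r


def make_cell_events(populations, n_events=500, image_side=48, seed=0
                     ) -> CellEvents:
    """Draw event crops from Gaussian (area, brightness) populations.

    Each event is one centered disk (a single-cell region of interest) with
    pixel area ~ N(area_mean, area_sd) and interior intensity
    ~ N(brightness_mean, brightness_sd) on a fixed dim background.  A
    warning is emitted when two populations' +-1 SD boxes overlap, since a
    rectangular gate would then mislabel events.
    """
    if not populations:
        raise ValueError("need at least one population")
    abundances = np.array([p.abundance for p in populations])
    if abs(abundances.sum() - 1.0) > 1e-9:
        raise ValueError(
            f"abundances must sum to 1, got {abundances.sum():.6f}"
        )
    for a in range(len(populations)):
        for b in range(a + 1, len(populations)):
            pa, pb = populations[a], populations[b]
            sep_area = abs(pa.area_mean - pb.area_mean) > pa.area_sd + pb.area_sd
            sep_bri = (
                abs(pa.brightness_mean - pb.brightness_mean)
                > pa.brightness_sd + pb.brightness_sd
            )
            if not (sep_area or sep_bri):
                warnings.warn(
                    f"populations {pa.name!r} and {pb.name!r} overlap within "
                    "+-1 SD on both features; gating will mislabel events",
                    stacklevel=2,
                )
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(populations), size=n_events, p=abundances)
    images = np.zeros((n_events, image_side, image_side, 1), np.uint8)
    masks = np.zeros((n_events, image_side, image_side), bool)
    radius_cache: dict = {}
    for i in range(n_events):
        pop = populations[labels[i]]
        area = max(rng.normal(pop.area_mean, pop.area_sd), 4.0)
        brightness = float(
            np.clip(rng.normal(pop.brightness_mean, pop.brightness_sd),
                    _BACKGROUND + 5, 255)
        )
        key = int(round(area))
        if key not in radius_cache:
            radius_cache[key] = _disk_radius_for_area(key, image_side)
        cy = image_side / 2 + rng.uniform(-1.5, 1.5)
        cx = image_side / 2 + rng.uniform(-1.5, 1.5)
        rr, cc = skdraw.disk((cy, cx), radius_cache[key],
                             shape=(image_side, image_side))
        canvas = rng.normal(_BACKGROUND, 3, (image_side, image_side))
        canvas[rr, cc] = brightness + rng.normal(0, 1.5, len(rr))
        images[i, :, :, 0] = np.clip(np.rint(canvas), 0, 255)
        masks[i, rr, cc] = True
    return CellEvents(
        images=images,
        masks=masks,
        labels=labels.astype(np.int64),
        class_names=[p.name for p in populations],
    )


def event_features(image, cell_mask):
    """(area, brightness) of one event.

    Area is the number of mask pixels (cross-sectional area in pixels^2);
    brightness is the mean grayscale value over exactly those pixels.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cell mask: features undefined")
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., 0]
    return int(mask.sum()), float(img[mask].mean())


def apply_gate(features, gate: Gate):
    """Indices of feature pairs inside the half-open rectangular gate."""
    feats = np.asarray(features, dtype=np.float64)
    if feats.ndim != 2 or feats.shape[1] != 2:
        raise ValueError("features must be a list of (area, brightness) pairs")
    (alo, ahi), (blo, bhi) = gate.area_range, gate.brightness_range
    inside = (
        (feats[:, 0] >= alo) & (feats[:, 0] < ahi)
        & (feats[:, 1] >= blo) & (feats[:, 1] < bhi)
    )
    return np.flatnonzero(inside)
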