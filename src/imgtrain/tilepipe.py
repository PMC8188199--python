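"""Tile-based segmentation-as-classification.

Whole-image segmentation is recast as tile classification: each image is
partitioned into a disjoint grid of square tiles, each tile gets a binary
label from the expert pixel mask (class 1 "with differentiation" when it
contains at least ``min_marked`` marked pixels, class 0 otherwise), the
under-represented positive class is topped up with extra tiles drawn at
random positions that satisfy the same criterion, and a small CNN is
trained on the resulting two-class tile set.  Applying the classifier tile
by tile reconstructs a per-image class grid whose agreement with the
ground-truth grid is the per-image accuracy.

Coordinates are row-major, origin top-left, 0-based; tile (r, c) covers
pixel rows [r*s, (r+1)*s) and columns [c*s, (c+1)*s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imageset import ImageSet

__all__ = [
    "MaskedImage",
    "TileMap",
    "decode_mask",
    "partition_tiles",
    "label_tiles",
    "oversample_positive_tiles",
    "build_tile_dataset",
    "predict_tile_map",
    "per_image_accuracy",
]

MASK_COLOR = (0, 255, 0)  # the uniform green used to mark labeled pixels
TILE_CLASS_NAMES = ["without_differentiation", "with_differentiation"]


@dataclass
class MaskedImage:
    """An RGB image paired with its expert pixel mask."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray   # (H, W) bool
    source_id: str = "image"

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(
                f"image must be (H, W, 3), got {self.image.shape}"
            )
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match image "
                f"{self.image.shape[:2]}"
            )


@dataclass
class TileMap:
    """Grid of per-tile classes (labels or predictions) for one image."""

    source_id: str
    tile_side: int
    grid: np.ndarray  # (R, C) int

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")

    @property
    def shape(self):
        return self.grid.shape

    def to_csv(self, path):
        pd.DataFrame(self.grid).to_csv(path, index=False, header=False)
        return path

    def to_table(self, probabilities=None) -> pd.DataFrame:
        """Flat tile table with 0-based half-open pixel coordinates."""
        rows = []
        s = self.tile_side
        nr, nc = self.grid.shape
        for r in range(nr):
            for c in range(nc):
                row = {
                    "source_id": self.source_id,
                    "row0": r * s,
                    "col0": c * s,
                    "row1": (r + 1) * s,
                    "col1": (c + 1) * s,
                    "class": int(self.grid[r, c]),
                }
                if probabilities is not None:
                    row["probability"] = float(probabilities[r, c])
                rows.append(row)
        return pd.DataFrame(rows)


def decode_mask(labeled_image, original=None, source_id="image") -> MaskedImage:
    """Extract the pixel mask from a green-overlay labeled image.

    The mask is true exactly where the pixel equals the pure marker color
    (0, 255, 0); near-misses do not count.  ``original`` supplies the
    unlabeled pixels when available, otherwise the labeled image is kept.
    """
    labeled = np.asarray(labeled_image)
    if labeled.ndim != 3 or labeled.shape[2] != 3:
        raise ValueError(f"labeled image must be (H, W, 3), got {labeled.shape}")
    mask = np.all(labeled == np.array(MASK_COLOR, labeled.dtype), axis=-1)
    image = np.asarray(original) if original is not None else labeled
    return MaskedImage(image=image, mask=mask, source_id=source_id)


def partition_tiles(img, tile_side):
    """Disjoint row-major tile grid; residual borders are discarded.

    Returns ``(tiles, n_rows, n_cols)`` where ``tiles`` has shape
    (R*C, s, s[, channels]).
    """
    img = np.asarray(img)
    s = int(tile_side)
    if s < 1:
        raise ValueError("tile_side must be >= 1")
    h, w = img.shape[:2]
    if s > min(h, w):
        raise ValueError(
            f"tile side {s} exceeds image size {h}x{w}"
        )
    nr, nc = h // s, w // s
    if h % s or w % s:
        warnings.warn(
            f"image {h}x{w} is not divisible by tile side {s}; discarding "
            f"{h - nr * s} residual rows and {w - nc * s} columns",
            stacklevel=2,
        )
    cropped = img[: nr * s, : nc * s]
    new_shape = (nr, s, nc, s) + cropped.shape[2:]
    tiles = cropped.reshape(new_shape).swapaxes(1, 2)
    tiles = tiles.reshape((nr * nc, s, s) + cropped.shape[2:])
    return np.ascontiguousarray(tiles), nr, nc


def label_tiles(mask_tiles, min_marked=5):
    """Class 1 iff a tile contains at least ``min_marked`` marked pixels."""
    mask_tiles = np.asarray(mask_tiles)
    counts = mask_tiles.reshape(mask_tiles.shape[0], -1).sum(axis=1)
    return (counts >= min_marked).astype(np.int64)


def oversample_positive_tiles(masked: MaskedImage, n_extra, tile_side,
                              rng, min_marked=5, max_attempts=1000):
    """Extra class-1 tiles at uniformly random fully-inside offsets.

    Rejection sampling: an offset is accepted when its tile holds more than
    ``min_marked - 1`` marked pixels.  Returns a list of
    ``(tile, (row0, col0))`` pairs; fewer than requested (with a warning)
    when the attempt budget runs out on a sparse mask.
    """
    s = int(tile_side)
    h, w = masked.mask.shape
    if s > min(h, w):
        raise ValueError(f"tile side {s} exceeds image size {h}x{w}")
    if int(masked.mask.sum()) < min_marked:
        raise ValueError(
            f"mask of {masked.source_id} has fewer than {min_marked} marked "
            "pixels; no positive tile exists"
        )
    out = []
    for _ in range(int(n_extra)):
        for _attempt in range(max_attempts):
            r0 = int(rng.integers(0, h - s + 1))
            c0 = int(rng.integers(0, w - s + 1))
            window = masked.mask[r0 : r0 + s, c0 : c0 + s]
            if int(window.sum()) > min_marked - 1:
                out.append((masked.image[r0 : r0 + s, c0 : c0 + s].copy(),
                            (r0, c0)))
                break
        else:
            warnings.warn(
                f"oversampling budget exhausted for {masked.source_id}: "
                f"returning {len(out)} of {n_extra} requested tiles",
                stacklevel=2,
            )
            break
    return out


def build_tile_dataset(masked_images, tile_side=32, min_marked=5,
                       oversample="balance", seed=0, split="train"
                       ) -> ImageSet:
    """Grid tiles + oversampled positives merged into a two-class ImageSet.

    ``oversample`` is ``"balance"`` (add as many positives as the grid's
    class imbalance), an integer count, or 0/None.  Tile provenance is kept
    in ``source_ids`` as ``<source_id>:r<row0>:c<col0>``.
    """
    if not masked_images:
        raise ValueError("need at least one masked image")
    rng = np.random.default_rng(seed)
    images, labels, ids = [], [], []
    for m in masked_images:
        tiles, nr, nc = partition_tiles(m.image, tile_side)
        mask_tiles, _, _ = partition_tiles(m.mask, tile_side)
        classes = label_tiles(mask_tiles, min_marked=min_marked)
        for t in range(len(tiles)):
            r0 = (t // nc) * tile_side
            c0 = (t % nc) * tile_side
            images.append(tiles[t])
            labels.append(int(classes[t]))
            ids.append(f"{m.source_id}:r{r0}:c{c0}")
    labels_arr = np.array(labels)
    n_extra_total = 0
    if oversample == "balance":
        n_extra_total = max(int((labels_arr == 0).sum() - (labels_arr == 1).sum()), 0)
    elif oversample:
        n_extra_total = int(oversample)
    if n_extra_total:
        eligible = [m for m in masked_images if int(m.mask.sum()) >= min_marked]
        if not eligible:
            warnings.warn(
                "no image has enough marked pixels for oversampling",
                stacklevel=2,
            )
        else:
            quota = np.full(len(eligible), n_extra_total // len(eligible))
            quota[: n_extra_total % len(eligible)] += 1
            for m, q in zip(eligible, quota):
                for tile, (r0, c0) in oversample_positive_tiles(
                    m, q, tile_side, rng, min_marked=min_marked
                ):
                    images.append(tile)
                    labels.append(1)
                    ids.append(f"{m.source_id}:r{r0}:c{c0}")
    return ImageSet(
        images=np.stack(images),
        labels=np.array(labels),
        class_names=list(TILE_CLASS_NAMES),
        source_ids=ids,
        split=split,
    )


def truth_tile_map(masked: MaskedImage, tile_side=32, min_marked=5) -> TileMap:
    """Ground-truth tile grid derived from the pixel mask."""
    mask_tiles, nr, nc = partition_tiles(masked.mask, tile_side)
    classes = label_tiles(mask_tiles, min_marked=min_marked)
    return TileMap(
        source_id=masked.source_id,
        tile_side=tile_side,
        grid=classes.reshape(nr, nc),
    )


def predict_tile_map(predictor, image, tile_side=32, source_id="image"):
    """Classify every grid tile of ``image``.

    ``predictor`` must expose ``predict_proba`` over uint8 tile batches.
    Returns ``(TileMap, probabilities)`` where ``probabilities`` has shape
    (R, C, K) in grid order.
    """
    tiles, nr, nc = partition_tiles(np.asarray(image), tile_side)
    probs = predictor.predict_proba(tiles)
    grid = probs.argmax(axis=1).reshape(nr, nc)
    return (
        TileMap(source_id=source_id, tile_side=tile_side, grid=grid),
        probs.reshape(nr, nc, -1),
    )


def per_image_accuracy(pred: TileMap, truth: TileMap) -> float:
    """Fraction of agreeing tiles between a predicted and a true grid."""
    if pred.grid.shape != truth.grid.shape:
        raise ValueError(
            f"grid shape mismatch: {pred.grid.shape} vs {truth.grid.shape}"
        )
    if pred.source_id != truth.source_id:
        raise ValueError(
            f"tile maps describe different images: {pred.source_id!r} vs "
            f"{truth.source_id!r}"
        )
    return float((pred.grid == truth.grid).mean())
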