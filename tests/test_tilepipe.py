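"""Tile partitioning, mask-derived labeling, oversampling, tile maps."""

import numpy as np
import pytest

from imgtrain import (
    MaskedImage,
    TileMap,
    build_tile_dataset,
    decode_mask,
    label_tiles,
    oversample_positive_tiles,
    partition_tiles,
    per_image_accuracy,
    predict_tile_map,
)
from imgtrain.tilepipe import truth_tile_map


def _blob_mask(side=160, center=(40, 40), radius=6):
    yy, xx = np.mgrid[:side, :side]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


class TestDecodeMask:
    def test_counts_pure_green_pixels(self):
        img = np.zeros((10, 10, 3), np.uint8)
        img[2, 3] = (0, 255, 0)
        img[5, 5] = (0, 255, 0)
        img[7, 1] = (0, 254, 0)   # near-green does not count
        masked = decode_mask(img)
        assert masked.mask.sum() == 2
        assert masked.mask[2, 3] and masked.mask[5, 5]
        assert not masked.mask[7, 1]

    def test_all_green(self):
        img = np.zeros((4, 4, 3), np.uint8)
        img[..., 1] = 255
        assert decode_mask(img).mask.all()

    def test_no_green_gives_all_false(self):
        img = np.full((4, 4, 3), 120, np.uint8)
        assert not decode_mask(img).mask.any()

    def test_original_pixels_kept_when_supplied(self):
        labeled = np.zeros((4, 4, 3), np.uint8)
        labeled[0, 0] = (0, 255, 0)
        original = np.full((4, 4, 3), 9, np.uint8)
        masked = decode_mask(labeled, original=original)
        assert (masked.image == 9).all()
        assert masked.mask[0, 0]


class TestPartitionTiles:
    def test_320_into_100_tiles(self):
        img = np.zeros((320, 320, 3), np.uint8)
        tiles, nr, nc = partition_tiles(img, 32)
        assert len(tiles) == 100
        assert (nr, nc) == (10, 10)
        assert tiles.shape == (100, 32, 32, 3)

    def test_single_tile_identity(self, rng):
        img = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        tiles, nr, nc = partition_tiles(img, 32)
        assert (nr, nc) == (1, 1)
        assert np.array_equal(tiles[0], img)

    def test_residual_border_discarded_with_warning(self, rng):
        img = rng.integers(0, 256, (70, 70)).astype(np.uint8)
        with pytest.warns(UserWarning, match="residual"):
            tiles, nr, nc = partition_tiles(img, 32)
        assert len(tiles) == 4 and (nr, nc) == (2, 2)

    def test_tile_side_too_large(self):
        with pytest.raises(ValueError, match="exceeds image size"):
            partition_tiles(np.zeros((20, 20)), 32)

    def test_row_major_reassembly(self, rng):
        img = rng.integers(0, 256, (96, 64, 3)).astype(np.uint8)
        tiles, nr, nc = partition_tiles(img, 32)
        rows = [
            np.concatenate([tiles[r * nc + c] for c in range(nc)], axis=1)
            for r in range(nr)
        ]
        rebuilt = np.concatenate(rows, axis=0)
        assert np.array_equal(rebuilt, img)


class TestLabelTiles:
    @pytest.mark.parametrize("marked,expected", [(0, 0), (4, 0), (5, 1), (9, 1)])
    def test_threshold_rule(self, marked, expected):
        tile = np.zeros((1, 32, 32), bool)
        tile[0].ravel()[:marked] = True
        assert label_tiles(tile, min_marked=5).tolist() == [expected]

    def test_all_false_mask_all_class_zero(self):
        tiles = np.zeros((10, 32, 32), bool)
        assert (label_tiles(tiles) == 0).all()

    def test_monotone_in_marked_pixels(self, rng):
        tile = np.zeros((32, 32), bool)
        order = rng.permutation(32 * 32)
        prev = 0
        for i in range(0, 40):
            tile.ravel()[order[i]] = True
            cls = int(label_tiles(tile[None])[0])
            assert cls >= prev
            prev = cls


class TestOversampling:
    def _masked(self):
        side = 160
        img = np.full((side, side, 3), 120, np.uint8)
        return MaskedImage(image=img, mask=_blob_mask(side), source_id="x")

    def test_tiles_satisfy_criterion(self, rng):
        masked = self._masked()
        out = oversample_positive_tiles(masked, 20, 32, rng)
        assert len(out) == 20
        for tile, (r0, c0) in out:
            window = masked.mask[r0:r0 + 32, c0:c0 + 32]
            assert window.sum() >= 5
            assert tile.shape == (32, 32, 3)

    def test_all_false_mask_rejected(self, rng):
        masked = MaskedImage(image=np.zeros((64, 64, 3), np.uint8),
                             mask=np.zeros((64, 64), bool), source_id="x")
        with pytest.raises(ValueError, match="fewer than 5 marked"):
            oversample_positive_tiles(masked, 5, 32, rng)

    def test_offsets_vary_across_draws(self, rng):
        masked = self._masked()
        offsets = {off for _, off in
                   oversample_positive_tiles(masked, 20, 32, rng)}
        assert len(offsets) >= 2

    def test_budget_exhaustion_warns_and_returns_fewer(self):
        # one tiny blob in a huge image: acceptance probability ~1e-4
        side = 320
        mask = np.zeros((side, side), bool)
        mask[4:7, 4:7] = True  # 9 pixels in one corner
        masked = MaskedImage(image=np.zeros((side, side, 3), np.uint8),
                             mask=mask, source_id="sparse")
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="budget exhausted"):
            out = oversample_positive_tiles(masked, 50, 32, rng,
                                            max_attempts=3)
        assert len(out) < 50


class TestBuildTileDataset:
    def test_unmarked_image_gives_all_class_zero(self):
        img = np.full((320, 320, 3), 150, np.uint8)
        masked = MaskedImage(image=img, mask=np.zeros((320, 320), bool),
                             source_id="blank")
        ds = build_tile_dataset([masked], oversample=0)
        assert len(ds) == 100
        assert (ds.labels == 0).all()

    def test_balance_oversampling_evens_class_counts(self):
        side = 160
        img = np.full((side, side, 3), 150, np.uint8)
        masked = MaskedImage(image=img, mask=_blob_mask(side),
                             source_id="one-blob")
        ds = build_tile_dataset([masked], oversample="balance", seed=0)
        counts = ds.class_counts()
        assert counts[0] == counts[1]

    def test_source_ids_round_trip_to_offsets(self):
        side = 160
        masked = MaskedImage(image=np.zeros((side, side, 3), np.uint8),
                             mask=_blob_mask(side), source_id="img7")
        ds = build_tile_dataset([masked], oversample=3, seed=1)
        for sid, img in zip(ds.source_ids, ds.images):
            src, r, c = sid.rsplit(":", 2)
            r0, c0 = int(r[1:]), int(c[1:])
            assert src == "img7"
            assert np.array_equal(img, masked.image[r0:r0 + 32, c0:c0 + 32])


class TestTileMaps:
    class _ConstantModel:
        def __init__(self, k=2, winner=0):
            self.k, self.winner = k, winner

        def predict_proba(self, images):
            probs = np.full((len(images), self.k), 0.1)
            probs[:, self.winner] = 0.9
            return probs / probs.sum(axis=1, keepdims=True)

    def test_constant_model_all_zero_grid(self):
        img = np.zeros((320, 320, 3), np.uint8)
        tm, probs = predict_tile_map(self._ConstantModel(), img)
        assert tm.grid.shape == (10, 10)
        assert (tm.grid == 0).all()
        assert probs.shape == (10, 10, 2)

    def test_per_image_accuracy_counts_agreement(self):
        truth = TileMap(source_id="a", tile_side=32,
                        grid=np.zeros((10, 10), int))
        pred = TileMap(source_id="a", tile_side=32,
                       grid=np.zeros((10, 10), int))
        assert per_image_accuracy(pred, truth) == 1.0
        pred.grid[0, 0] = 1
        assert per_image_accuracy(pred, truth) == pytest.approx(0.99)
        assert per_image_accuracy(
            TileMap("a", 32, 1 - truth.grid), truth) == 0.0

    def test_shape_mismatch(self):
        a = TileMap("a", 32, np.zeros((10, 10), int))
        b = TileMap("a", 32, np.zeros((5, 5), int))
        with pytest.raises(ValueError, match="shape mismatch"):
            per_image_accuracy(a, b)

    def test_truth_map_matches_label_rule(self, stained_small):
        m = stained_small[0]
        tm = truth_tile_map(m, tile_side=32)
        tiles, nr, nc = partition_tiles(m.mask, 32)
        assert np.array_equal(
            tm.grid.ravel(), label_tiles(tiles, min_marked=5))

    def test_tile_table_has_half_open_coordinates(self):
        tm = TileMap("img", 32, np.arange(4).reshape(2, 2) % 2)
        table = tm.to_table()
        first = table.iloc[0]
        assert (first.row0, first.col0, first.row1, first.col1) == (0, 0, 32, 32)
        last = table.iloc[-1]
        assert (last.row0, last.col0, last.row1, last.col1) == (32, 32, 64, 64)
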