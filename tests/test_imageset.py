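"""Container, conversion, resizing, and normalization behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from imgtrain import (
    HDF5ImageSet,
    ImageSet,
    Normalizer,
    SizeSpec,
    apply_normalizer,
    equalize_size,
    fit_normalizer,
    gray_to_rgb,
    load_folder,
    load_hdf5,
    rgb_to_gray,
    save_hdf5,
    scale_image,
)


def _write_folder(root, class_sizes, shape=(28, 28)):
    for cname, n in class_sizes.items():
        d = root / cname
        d.mkdir(parents=True)
        for i in range(n):
            arr = np.full(shape + (3,), 10 * i, dtype=np.uint8)
            Image.fromarray(arr).save(d / f"img{i}.png")


class TestLoadFolder:
    def test_counts_and_sorted_class_names(self, tmp_path):
        _write_folder(tmp_path, {"b_class": 3, "a_class": 3})
        ds = load_folder(tmp_path)
        assert len(ds) == 6
        assert ds.class_names == ["a_class", "b_class"]
        assert ds.class_counts().tolist() == [3, 3]
        assert ds.images.shape == (6, 28, 28, 3)

    def test_empty_root_errors(self, tmp_path):
        with pytest.raises(ValueError, match="no classes found"):
            load_folder(tmp_path)

    def test_mixed_sizes_instruct_equalization(self, tmp_path):
        _write_folder(tmp_path, {"a": 2})
        Image.fromarray(np.zeros((32, 32, 3), np.uint8)).save(
            tmp_path / "a" / "big.png"
        )
        with pytest.raises(ValueError, match="equalize sizes first"):
            load_folder(tmp_path)

    def test_unreadable_file_skipped_with_warning(self, tmp_path):
        _write_folder(tmp_path, {"a": 2})
        (tmp_path / "a" / "broken.png").write_bytes(b"not a png at all")
        with pytest.warns(UserWarning, match="skipping unreadable"):
            ds = load_folder(tmp_path)
        assert len(ds) == 2

    def test_container_invariants(self, tmp_path):
        _write_folder(tmp_path, {"a": 2, "b": 1, "c": 4})
        ds = load_folder(tmp_path)
        assert ds.images.dtype == np.uint8
        assert len(ds.labels) == len(ds.source_ids) == len(ds)
        assert ds.labels.min() >= 0 and ds.labels.max() < ds.n_classes


class TestColorConversion:
    @pytest.mark.parametrize(
        "pixel,expected",
        [((100, 100, 100), 100), ((0, 0, 0), 0), ((0, 255, 0), 184),
         ((255, 255, 255), 255)],
    )
    def test_luminosity_values(self, pixel, expected):
        img = np.array([[pixel]], dtype=np.uint8)
        assert rgb_to_gray(img)[0, 0, 0] == expected

    def test_luminosity_matches_per_pixel_loop(self, rng):
        img = rng.integers(0, 256, (9, 7, 3)).astype(np.uint8)
        got = rgb_to_gray(img)
        for r in range(9):
            for c in range(7):
                R, G, B = (int(v) for v in img[r, c])
                # scalar round-half-up of the exact decimal weighted sum
                want = min(max((21 * R + 72 * G + 7 * B + 50) // 100, 0), 255)
                assert got[r, c, 0] == want

    def test_gray_input_rejected(self):
        with pytest.raises(ValueError, match="already grayscale"):
            rgb_to_gray(np.zeros((4, 4, 1), np.uint8))

    def test_gray_to_rgb_stacks_three_copies(self):
        img = np.array([[[42]]], dtype=np.uint8)
        out = gray_to_rgb(img)
        assert out.shape == (1, 1, 3)
        assert (out == 42).all()
        with pytest.raises(ValueError, match="already RGB"):
            gray_to_rgb(out)

    @given(st.integers(0, 255))
    @settings(deadline=None)
    def test_round_trip_identity(self, value):
        img = np.full((3, 3, 1), value, np.uint8)
        assert np.array_equal(rgb_to_gray(gray_to_rgb(img)), img)


class TestScaleImage:
    def test_printed_upscale_28_to_32(self, rng):
        img = rng.integers(0, 256, (28, 28, 1)).astype(np.uint8)
        out = scale_image(img, 1.15, "nearest")
        assert out.shape == (32, 32, 1)
        # nearest neighbor introduces no new intensity values
        assert set(np.unique(out)) <= set(np.unique(img))

    def test_identity_factor(self, rng):
        img = rng.integers(0, 256, (10, 10, 3)).astype(np.uint8)
        assert np.array_equal(scale_image(img, 1.0), img)

    @pytest.mark.parametrize("interp", ["nearest", "linear", "quadratic", "cubic"])
    def test_constant_field_stays_constant(self, interp):
        img = np.full((10, 10, 1), 77, np.uint8)
        out = scale_image(img, 2.0, interp)
        assert out.shape == (20, 20, 1)
        assert (out == 77).all()

    def test_invalid_factor(self):
        with pytest.raises(ValueError, match="> 0"):
            scale_image(np.zeros((4, 4, 1), np.uint8), 0)


class TestEqualizeSize:
    def test_crop_margins(self, rng):
        img = rng.integers(0, 256, (36, 36, 1)).astype(np.uint8)
        out = equalize_size(img, SizeSpec(32, mode="center_crop"))
        assert np.array_equal(out, img[2:34, 2:34])

    def test_pad_zero_borders(self, rng):
        img = rng.integers(1, 256, (28, 28, 1)).astype(np.uint8)
        out = equalize_size(img, SizeSpec(32, mode="pad"))
        assert out.shape == (32, 32, 1)
        assert np.array_equal(out[2:30, 2:30], img)
        assert out[:2].sum() == 0 and out[:, :2].sum() == 0

    def test_odd_remainder_trails(self):
        img = np.arange(33, dtype=np.uint8).reshape(33, 1, 1) * np.ones(
            (1, 33, 1), np.uint8
        )
        out = equalize_size(img, SizeSpec(32, mode="center_crop"))
        assert out[0, 0, 0] == 0  # row 0 kept, last row dropped

    def test_identity_when_already_target(self, rng):
        img = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        for mode in ("center_crop", "pad"):
            assert np.array_equal(equalize_size(img, SizeSpec(32, mode=mode)), img)

    def test_crop_smaller_than_target_directs_to_pad(self):
        with pytest.raises(ValueError, match="pad"):
            equalize_size(np.zeros((28, 28, 1), np.uint8),
                          SizeSpec(32, mode="center_crop"))

    def test_scale_then_equalize_reproduces_printed_protocol(self, rng):
        img = rng.integers(0, 256, (28, 28, 1)).astype(np.uint8)
        spec = SizeSpec(32, mode="scale_then_equalize", interpolation="nearest",
                        scale_factor=1.15)
        assert equalize_size(img, spec).shape == (32, 32, 1)

    def test_rectangular_input_equalized_per_axis(self, rng):
        img = rng.integers(0, 256, (40, 20, 1)).astype(np.uint8)
        spec = SizeSpec(32, mode="scale_then_equalize", scale_factor=1.0)
        out = equalize_size(img, spec)
        assert out.shape == (32, 32, 1)

    @given(st.integers(32, 48), st.integers(32, 48))
    @settings(deadline=None, max_examples=20)
    def test_idempotent(self, h, w):
        rng = np.random.default_rng(h * 100 + w)
        img = rng.integers(0, 256, (h, w, 1)).astype(np.uint8)
        spec = SizeSpec(32, mode="center_crop")
        once = equalize_size(img, spec)
        assert np.array_equal(equalize_size(once, spec), once)


class TestNormalization:
    def test_div255(self):
        x = np.array([[[[255]]]], dtype=np.uint8)
        spec = fit_normalizer(_tiny_set(x), "div255")
        assert apply_normalizer(x, spec)[0, 0, 0, 0] == pytest.approx(1.0)

    def test_dataset_standard_moments_by_hand(self):
        imgs = np.stack([
            np.zeros((4, 4, 1), np.uint8),
            np.full((4, 4, 1), 200, np.uint8),
        ])
        spec = fit_normalizer(_tiny_set(imgs), "dataset_standard")
        assert spec.fitted_mean == pytest.approx(100.0)
        assert spec.fitted_sd == pytest.approx(100.0)
        out = apply_normalizer(imgs, spec)
        assert out.mean() == pytest.approx(0.0, abs=1e-6)
        assert out.std() == pytest.approx(1.0, abs=1e-6)

    def test_per_image_standard_and_constant_image(self, rng):
        imgs = rng.integers(0, 256, (3, 8, 8, 1)).astype(np.uint8)
        out = Normalizer("per_image_standard").fit(imgs).transform(imgs)
        for i in range(3):
            assert out[i].mean() == pytest.approx(0.0, abs=1e-5)
            assert out[i].std() == pytest.approx(1.0, abs=1e-5)
        const = np.full((1, 8, 8, 1), 9, np.uint8)
        with pytest.warns(UserWarning, match="constant image"):
            zeros = Normalizer("per_image_standard").fit(const).transform(const)
        assert (zeros == 0).all()

    def test_fit_reads_train_statistics_only(self, rng):
        train = rng.integers(0, 256, (5, 6, 6, 1)).astype(np.uint8)
        valid = rng.integers(0, 256, (5, 6, 6, 1)).astype(np.uint8)
        norm = Normalizer("dataset_standard").fit(train)
        mean_before, sd_before = norm.mean_, norm.sd_
        valid[...] = 255  # mutate the other split
        norm.transform(valid)
        assert (norm.mean_, norm.sd_) == (mean_before, sd_before)


def _tiny_set(images):
    if images.ndim == 3:
        images = images[None]
    n = len(images)
    return ImageSet(images=images, labels=np.zeros(n, int), class_names=["x"],
                    source_ids=[str(i) for i in range(n)])


class TestHDF5:
    def test_round_trip(self, tmp_path, shapes_train):
        path = tmp_path / "ds.h5"
        save_hdf5(shapes_train, path)
        back = load_hdf5(path)
        assert np.array_equal(back.images, shapes_train.images)
        assert np.array_equal(back.labels, shapes_train.labels)
        assert back.class_names == shapes_train.class_names
        assert back.source_ids == shapes_train.source_ids
        assert back.fingerprint() == shapes_train.fingerprint()

    def test_disk_backed_stream_matches_ram_contract(self, tmp_path, shapes_train):
        path = tmp_path / "ds.h5"
        save_hdf5(shapes_train, path)
        with HDF5ImageSet(path) as streamed:
            assert len(streamed) == len(shapes_train)
            assert streamed.class_names == shapes_train.class_names
            chunks = [imgs for imgs, _ in streamed.iter_batches(7)]
            assert np.array_equal(np.concatenate(chunks), shapes_train.images)
            labels = np.concatenate(
                [lab for _, lab in streamed.iter_batches(7)]
            )
            assert np.array_equal(labels, shapes_train.labels)

    def test_fingerprint_detects_modification(self, shapes_train):
        fp = shapes_train.fingerprint()
        mutated = shapes_train.subset(np.arange(len(shapes_train)))
        mutated.images = mutated.images.copy()
        mutated.images[0, 0, 0, 0] ^= 1
        assert mutated.fingerprint() != fp


class TestContainerValidation:
    def test_label_range_enforced(self):
        with pytest.raises(ValueError, match="labels must lie"):
            ImageSet(images=np.zeros((2, 4, 4, 1), np.uint8),
                     labels=[0, 5], class_names=["a", "b"],
                     source_ids=["x", "y"])

    def test_channel_count_enforced(self):
        with pytest.raises(ValueError, match="channel count"):
            ImageSet(images=np.zeros((1, 4, 4, 2), np.uint8), labels=[0],
                     class_names=["a"], source_ids=["x"])
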