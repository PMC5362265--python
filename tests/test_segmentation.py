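"""Segmentation workflow: preprocessing, local threshold, cleanup, invariants."""

import numpy as np
import pytest
from skimage import filters, morphology

import pictquant as pq
from pictquant.segmentation import (ANCHOR_DEFAULTS, PREY_DEFAULTS,
                                    clean_mask, local_mean_threshold,
                                    preprocess_channel, segment_spots)


def brute_force_disk_mean(image, radius):
    """Independent per-pixel disk mean with reflected boundaries."""
    pad = np.pad(image, radius, mode="symmetric")
    disk = morphology.disk(radius).astype(bool)
    out = np.empty(image.shape, dtype=float)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            out[i, j] = pad[i:i + 2 * radius + 1, j:j + 2 * radius + 1][disk].mean()
    return out


def brute_force_opening(image, radius):
    """Grey erosion then dilation with a disk, explicit loops, reflect pad."""
    disk = morphology.disk(radius).astype(bool)
    pad = np.pad(image, radius, mode="symmetric")
    eroded = np.empty(image.shape)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            eroded[i, j] = pad[i:i + 2 * radius + 1, j:j + 2 * radius + 1][disk].min()
    pad_e = np.pad(eroded, radius, mode="symmetric")
    opened = np.empty(image.shape)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            opened[i, j] = pad_e[i:i + 2 * radius + 1, j:j + 2 * radius + 1][disk].max()
    return opened


class TestPreprocess:
    def test_constant_image_maps_to_zero(self):
        p = pq.SegmentationParams(tophat_radius=4)
        out = preprocess_channel(np.full((32, 32), 7.5), p)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_isolated_peak_survives_background_removal(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1000.0
        p = pq.SegmentationParams(gauss_sigma=1.0, tophat_radius=6)
        out = preprocess_channel(img, p)
        blurred = filters.gaussian(img, 1.0, mode="reflect", preserve_range=True)
        assert out.max() == pytest.approx(blurred.max(), rel=0.01)
        assert np.all(out <= blurred + 1e-9)
        assert np.all(out >= -1e-9)

    def test_ramp_residual_bounded_and_matches_bruteforce(self):
        slope = 2.0
        img = slope * np.arange(32, dtype=float)[None, :].repeat(32, axis=0)
        p = pq.SegmentationParams(gauss_sigma=0.5, tophat_radius=5)
        out = preprocess_channel(img, p)
        blurred = filters.gaussian(img, 0.5, mode="reflect", preserve_range=True)
        oracle = blurred - brute_force_opening(blurred, 5)
        assert np.allclose(out, oracle)
        assert out.max() < slope * p.tophat_radius * 2

    def test_oversized_structuring_element_rejected(self):
        p = pq.SegmentationParams(tophat_radius=20)
        with pytest.raises(ValueError):
            preprocess_channel(np.zeros((32, 32)), p)


class TestLocalMeanThreshold:
    def test_constant_image_gives_empty_mask(self):
        img = np.full((20, 20), 3.0)
        assert not local_mean_threshold(img, 4, 0.5).any()
        # strict inequality: offset 0 on a constant image is still empty
        assert not local_mean_threshold(img, 4, 0.0).any()

    def test_plateau_detected_background_not(self):
        img = np.zeros((15, 15))
        img[6:9, 6:9] = 10.0
        mask = local_mean_threshold(img, 5, 1.0)
        oracle = img > brute_force_disk_mean(img, 5) + 1.0
        assert np.array_equal(mask, oracle)
        assert mask[6:9, 6:9].all()
        assert not mask[img == 0].any()

    def test_matches_bruteforce_on_random_images(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            img = rng.uniform(0, 100, (32, 32))
            radius = int(rng.integers(2, 7))
            offset = float(rng.uniform(0, 5))
            mask = local_mean_threshold(img, radius, offset)
            oracle = img > brute_force_disk_mean(img, radius) + offset
            assert np.array_equal(mask, oracle)


class TestCleanMask:
    def test_lone_pixel_removed_by_median(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[8, 8] = True
        spots = clean_mask(mask, pq.SegmentationParams(median_radius=1))
        assert spots.n_spots == 0

    def test_solid_disk_survives_with_area_preserved(self):
        mask = np.zeros((64, 64), dtype=bool)
        yy, xx = np.mgrid[:64, :64]
        disk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 7**2
        mask[disk] = True
        spots = clean_mask(mask, pq.SegmentationParams(min_area=10, max_area=500))
        assert spots.n_spots == 1
        perimeter = np.count_nonzero(disk) - np.count_nonzero(
            morphology.erosion(disk, morphology.disk(1)))
        assert abs(spots.table["area_px2"].iloc[0] - disk.sum()) <= perimeter

    def test_area_opening_drops_small_component(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:20, 10:20] = True  # area 100
        mask[40:42, 40:43] = True  # area 6 < min_area 10
        spots = clean_mask(mask, pq.SegmentationParams(min_area=10, max_area=500))
        assert spots.n_spots == 1

    def test_relabeling_is_idempotent(self):
        from skimage import measure
        rng = np.random.default_rng(0)
        mask = rng.random((48, 48)) > 0.7
        p = pq.SegmentationParams(min_area=2, max_area=100)
        spots = clean_mask(mask, p)
        relabeled = measure.label(spots.labels > 0, connectivity=2)
        areas = sorted(r.area for r in measure.regionprops(relabeled))
        assert areas == sorted(spots.table["area_px2"])


class TestSegmentSpots:
    def test_blank_image_yields_no_spots(self):
        img = np.zeros((64, 64))
        spots = segment_spots(img, img, pq.SegmentationParams())
        assert spots.n_spots == 0

    def test_intensity_shift_leaves_mask_unchanged(self):
        rng = np.random.default_rng(3)
        img = rng.poisson(100, (96, 96)).astype(float)
        img[40:43, 40:43] += 300
        p = pq.SegmentationParams(local_mean_offset=10.0)
        a = segment_spots(img, img, p)
        b = segment_spots(img + 57.0, img + 57.0, p)
        assert np.array_equal(a.labels, b.labels)

    def test_scale_equivariance_with_scaled_offset(self):
        rng = np.random.default_rng(4)
        img = rng.poisson(100, (96, 96)).astype(float)
        img[30:33, 60:63] += 400
        k = 3.7
        a = segment_spots(img, img, pq.SegmentationParams(local_mean_offset=10.0))
        b = segment_spots(k * img, k * img,
                          pq.SegmentationParams(local_mean_offset=k * 10.0))
        assert np.array_equal(a.labels, b.labels)

    def test_intensity_statistics_measured_on_raw_channel(self):
        rng = np.random.default_rng(5)
        img = np.full((64, 64), 100.0)
        img[30:34, 30:34] += 500
        noisy = img + rng.normal(0, 2, img.shape)
        spots = segment_spots(noisy, noisy, pq.SegmentationParams())
        assert spots.n_spots == 1
        row = spots.table.iloc[0]
        region = spots.labels == row["label"]
        assert row["integrated_raw"] == pytest.approx(noisy[region].sum())
        assert row["mean_raw"] == pytest.approx(noisy[region].mean())
        mr, mc = int(row["max_row"]), int(row["max_col"])
        assert noisy[mr, mc] == noisy[region].max()

    def test_anchor_channel_of_synthetic_field_recovers_all_anchors(self):
        p = pq.SceneParams(image_shape=(128, 128), n_cells=4,
                           cell_radius_range=(10.0, 14.0), seed=3)
        fld, truth = pq.simulate_field(p, seed=7)
        anchors, _ = pq.segment_field(fld)
        assert anchors.n_spots == len(truth.anchor_centers)
        det = anchors.table[["centroid_row", "centroid_col"]].to_numpy()
        for c in truth.anchor_centers:
            assert np.min(np.linalg.norm(det - c, axis=1)) <= 2.0
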