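import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage import draw, filters, morphology

import oracles
from focidens import SegmentationParams, otsu_threshold, segment_nuclei
from focidens.errors import DegenerateImageError
from focidens.filters import adaptive_median
from focidens.segmentation import export_labels


def disk_image(radii_centers, shape=(256, 256), value=200, background=10):
    img = np.full(shape, background, dtype=np.uint8)
    for (cy, cx), r in radii_centers:
        rr, cc = draw.disk((cy, cx), r, shape=shape)
        img[rr, cc] = value
    return img


class TestOtsu:
    def test_bimodal_matches_exhaustive_scan(self):
        values = np.array([0] * 50 + [255] * 50, dtype=np.float64).reshape(10, 10)
        t = otsu_threshold(values)
        assert 0 < t <= 255
        assert t == oracles.otsu_scan_from_data(values)
        # any threshold in (0, 255] separates perfectly
        assert ((values >= t) == (values == 255)).all()

    def test_constant_raster_is_degenerate(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.full((5, 5), 17))

    def test_skewed_bimodal_threshold_between_modes(self):
        values = np.array([10] * 90 + [200] * 10, dtype=np.float64)
        t = otsu_threshold(values)
        assert 10 < t <= 200
        assert t == oracles.otsu_scan_from_data(values)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_8bit_matches_histogram_scan(self, seed):
        rng = np.random.default_rng(seed)
        values = np.concatenate(
            [rng.normal(60, 20, 300), rng.normal(180, 25, 200)]
        ).clip(0, 255).round()
        assert otsu_threshold(values) == oracles.otsu_scan_from_histogram(values)

    @pytest.mark.parametrize("seed", range(3))
    def test_partition_agrees_with_skimage_within_one_bin(self, seed):
        rng = np.random.default_rng(seed)
        values = np.concatenate(
            [rng.normal(60, 20, 500), rng.normal(180, 25, 300)]
        ).clip(0, 255).round()
        t = otsu_threshold(values)
        t_sk = filters.threshold_otsu(values, nbins=256)
        bin_width = (values.max() - values.min()) / 256
        assert abs(t - t_sk) <= bin_width * 1.5


class TestAdaptiveMedian:
    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_on_grayscale(self, seed):
        rng = np.random.default_rng(seed)
        img = np.round(rng.random((24, 24)) * 255) / 255
        np.testing.assert_array_equal(adaptive_median(img), oracles.adaptive_median(img))

    def test_matches_bruteforce_on_binary(self):
        rng = np.random.default_rng(7)
        mask = rng.random((24, 24)) > 0.5
        got = adaptive_median(mask)
        want = oracles.adaptive_median(mask.astype(np.float64)) > 0.5
        np.testing.assert_array_equal(got, want)

    def test_removes_isolated_impulses_keeps_block(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[8:24, 8:24] = True
        noisy = mask.copy()
        noisy[2, 2] = True  # salt
        noisy[15, 15] = False  # pepper inside the block
        cleaned = adaptive_median(noisy)
        assert not cleaned[2, 2]
        assert cleaned[15, 15]


class TestErosionEquivalence:
    @pytest.mark.parametrize("radius", [3, 7, 25])
    @pytest.mark.parametrize("seed", range(3))
    def test_edt_erosion_equals_disk_erosion(self, radius, seed):
        rng = np.random.default_rng(seed)
        mask = ndi.binary_dilation(rng.random((90, 90)) > 0.985, iterations=6)
        assert mask.any() and (~mask).any()
        via_edt = ndi.distance_transform_edt(mask) > radius
        via_disk = morphology.erosion(mask, morphology.disk(radius))
        np.testing.assert_array_equal(via_edt, via_disk)


class TestSegmentNuclei:
    def test_single_disk_area_recovered(self):
        img = disk_image([((128, 128), 40)])
        labeled = segment_nuclei(img)
        assert labeled.n_objects == 1
        area = labeled.object_areas[1]
        assert abs(area - np.pi * 40**2) <= 0.03 * np.pi * 40**2

    def test_disk_below_min_radius_removed(self):
        img = disk_image([((64, 64), 10)], shape=(128, 128))
        assert segment_nuclei(img).n_objects == 0

    def test_disk_at_custom_min_radius(self):
        img = disk_image([((64, 64), 10)], shape=(128, 128))
        labeled = segment_nuclei(img, SegmentationParams(min_nucleus_radius_px=5))
        assert labeled.n_objects == 1

    def test_hole_is_filled(self):
        img = disk_image([((128, 128), 40)])
        img[126:131, 126:131] = 10  # 5-px hole
        labeled = segment_nuclei(img)
        assert labeled.n_objects == 1
        assert labeled.labels[128, 128] == 1

    def test_overlapping_disks_stay_merged(self):
        # centers 70 px apart with radius 40: overlap ~10 px, no watershed split
        img = disk_image([((128, 90), 40), ((128, 160), 40)])
        assert segment_nuclei(img).n_objects == 1

    def test_separate_disks_stay_separate(self):
        img = disk_image([((64, 64), 40), ((192, 192), 40)])
        labeled = segment_nuclei(img)
        assert labeled.n_objects == 2
        assert sum(labeled.object_areas.values()) == (labeled.labels > 0).sum()

    def test_deterministic(self):
        img = disk_image([((100, 100), 35), ((190, 170), 45)])
        a = segment_nuclei(img)
        b = segment_nuclei(img)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_degenerate_raster_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="degenerate"):
            labeled = segment_nuclei(np.zeros((32, 32), dtype=np.uint8))
        assert labeled.n_objects == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_robust_to_one_percent_impulse_noise(self, seed):
        img = disk_image([((100, 100), 40), ((190, 180), 35)])
        clean = segment_nuclei(img)
        rng = np.random.default_rng(seed)
        noisy = img.copy()
        idx = rng.random(img.shape) < 0.01
        noisy[idx] = np.where(rng.random(idx.sum()) < 0.5, 0, 255)
        noisy_labeled = segment_nuclei(noisy)
        assert noisy_labeled.n_objects == clean.n_objects
        a, b = clean.labels > 0, noisy_labeled.labels > 0
        iou = (a & b).sum() / (a | b).sum()
        assert iou > 0.99

    def test_export_labels_tiff_and_centroid_csv(self, tmp_path):
        import pandas as pd
        import tifffile

        img = disk_image([((64, 64), 40), ((192, 192), 35)])
        labeled = segment_nuclei(img)
        export_labels(labeled, tmp_path / "labels.tif", tmp_path / "objects.csv")
        back = tifffile.imread(tmp_path / "labels.tif")
        assert back.dtype == np.uint16
        np.testing.assert_array_equal(back, labeled.labels)
        table = pd.read_csv(tmp_path / "objects.csv")
        assert len(table) == 2
        # centroids land near the drawn disk centers
        assert abs(table.centroid_row.iloc[0] - 64) < 2
        assert abs(table.centroid_col.iloc[1] - 192) < 2

    def test_every_object_contains_the_minimum_disk_before_closing(self):
        img = disk_image([((100, 100), 40), ((190, 180), 30)])
        params = SegmentationParams(closing_iterations=0)
        labeled = segment_nuclei(img, params)
        for lab in labeled.object_areas:
            obj = labeled.labels == lab
            assert (ndi.distance_transform_edt(obj) > params.min_nucleus_radius_px).any()
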