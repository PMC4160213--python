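"""Normalisation, thresholding, contour spectrum, component cleanup."""

import numpy as np
import pytest

from wallfibril3d.segmentation import (clean_components, contour_spectrum,
                                       normalize_density, select_isovalue,
                                       threshold_segment)
from wallfibril3d.volume import DensityVolume

VS = 0.87


@pytest.fixture
def two_level_volume():
    rng = np.random.default_rng(5)
    data = np.zeros((20, 20, 20), np.float32)
    idx = rng.choice(20 ** 3, size=800, replace=False)  # 10% high voxels
    data.ravel()[idx] = 5.0
    return DensityVolume(data, VS)


class TestNormalize:
    def test_zero_mean_unit_sd(self, two_level_volume):
        out = normalize_density(two_level_volume)
        assert abs(float(out.data.mean())) < 1e-6
        assert float(out.data.std()) == pytest.approx(1.0, abs=1e-6)

    def test_high_level_voxels_positive(self, two_level_volume):
        out = normalize_density(two_level_volume)
        high = two_level_volume.data > 2.5
        assert (out.data[high] > 0).all()

    def test_dense_dark_negates(self, two_level_volume):
        bright = normalize_density(two_level_volume, "dense_bright")
        dark_in = two_level_volume.with_data(-two_level_volume.data)
        dark = normalize_density(dark_in, "dense_dark")
        assert np.allclose(bright.data, dark.data, atol=1e-6)

    def test_idempotent(self, two_level_volume):
        once = normalize_density(two_level_volume)
        twice = normalize_density(once)
        assert np.abs(twice.data - once.data).max() < 1e-6

    def test_constant_volume_error(self):
        with pytest.raises(ValueError, match="no contrast"):
            normalize_density(DensityVolume(np.ones((8, 8, 8), np.float32), VS))


class TestThresholdSegment:
    def test_below_minimum_all_foreground(self, two_level_volume):
        vol = normalize_density(two_level_volume)
        labels = threshold_segment(vol, float(vol.data.min()) - 1)
        assert labels.mask.all()
        assert labels.n_components == 1

    def test_above_maximum_empty(self, two_level_volume):
        vol = normalize_density(two_level_volume)
        labels = threshold_segment(vol, float(vol.data.max()) + 1)
        assert not labels.mask.any()
        assert labels.n_components == 0

    def test_foreground_monotone_in_threshold(self, two_level_volume):
        vol = normalize_density(two_level_volume)
        counts = [int(threshold_segment(vol, t).mask.sum())
                  for t in np.linspace(-2, 3, 11)]
        assert all(a >= b for a, b in zip(counts[:-1], counts[1:]))

    def test_noiseless_cylinders_exact_mask(self, two_cylinder_bridge):
        vol, truth, spec = two_cylinder_bridge
        # midway threshold on raw soft rasterisation reproduces dist<=r
        labels = threshold_segment(vol, 0.5)
        from wallfibril3d.phantom import rasterize_truth_mask
        expected = rasterize_truth_mask(spec, truth)
        jac = (labels.mask & expected).sum() / (labels.mask | expected).sum()
        assert jac > 0.95

    def test_component_ids_contiguous(self, two_level_volume):
        vol = normalize_density(two_level_volume)
        labels = threshold_segment(vol, 1.0)
        ids = np.unique(labels.data)
        assert ids[0] == 0
        assert np.array_equal(ids[1:], np.arange(1, labels.n_components + 1))


class TestContourSpectrum:
    def test_volume_fraction_non_increasing(self, two_level_volume):
        cs = contour_spectrum(normalize_density(two_level_volume), 16)
        assert (np.diff(cs.volume_fraction) <= 1e-12).all()

    def test_two_level_step_fractions(self, two_level_volume):
        cs = contour_spectrum(two_level_volume, 16)
        # below the 5.0 level every sampled superlevel set is the 10% set
        inner = (cs.isovalues > 0.1) & (cs.isovalues < 4.9)
        assert np.allclose(cs.volume_fraction[inner], 0.10, atol=0.001)

    def test_sphere_area_peaks_between_levels(self):
        z, y, x = np.mgrid[0:32, 0:32, 0:32].astype(float)
        r = np.sqrt((z - 16) ** 2 + (y - 16) ** 2 + (x - 16) ** 2)
        data = np.clip((10.0 - r) / 4.0, 0, 1).astype(np.float32)  # soft sphere
        rng = np.random.default_rng(8)
        data = data + rng.normal(0, 0.05, data.shape).astype(np.float32)
        cs = contour_spectrum(DensityVolume(data, VS), 24)
        peak = cs.isovalues[np.argmax(cs.surface_area)]
        assert cs.isovalues[0] < peak < cs.isovalues[-1]

    def test_requires_enough_samples(self, two_level_volume):
        with pytest.raises(ValueError):
            contour_spectrum(two_level_volume, 4)

    def test_degenerate_range(self):
        with pytest.raises(ValueError):
            contour_spectrum(DensityVolume(np.ones((10, 10, 10), np.float32), VS))


class TestSelectIsovalue:
    def test_two_level_selected_between_levels(self, two_level_volume):
        # soft interface: gradient is maximal between the two plateaus
        import scipy.ndimage as ndi
        smooth = two_level_volume.with_data(
            ndi.gaussian_filter(two_level_volume.data, 1.0))
        vol = normalize_density(smooth)
        iso = select_isovalue(contour_spectrum(vol, 32))
        assert float(vol.data.min()) < iso < float(vol.data.max())

    def test_flat_criterion_warns_and_returns_median(self):
        # a pure 1D ramp has constant gradient magnitude everywhere
        data = np.broadcast_to(np.linspace(0, 1, 32, dtype=np.float32),
                               (16, 16, 32)).copy()
        cs = contour_spectrum(DensityVolume(data, VS), 16)
        with pytest.warns(UserWarning, match="flat"):
            iso = select_isovalue(cs)
        assert iso == pytest.approx(float(np.median(cs.isovalues)))

    def test_affine_rescale_invariance(self, two_level_volume):
        # select after normalisation is unchanged by an affine rescale before it
        v1 = normalize_density(two_level_volume)
        scaled = two_level_volume.with_data(two_level_volume.data * 7.0 + 3.0)
        v2 = normalize_density(scaled)
        iso1 = select_isovalue(contour_spectrum(v1, 32))
        iso2 = select_isovalue(contour_spectrum(v2, 32))
        assert iso1 == pytest.approx(iso2, abs=1e-5)


class TestCleanComponents:
    def test_min_one_is_identity(self, two_level_volume):
        labels = threshold_segment(normalize_density(two_level_volume), 1.0)
        out = clean_components(labels, 1)
        assert np.array_equal(out.data > 0, labels.data > 0)

    def test_specks_removed_rod_kept(self):
        data = np.zeros((20, 30, 20), np.float32)
        data[9:11, 5:25, 9:12] = 1.0  # ~120-voxel rod
        rng = np.random.default_rng(2)
        for _ in range(5):  # five 2-voxel specks
            z, y, x = rng.integers(2, 17, 3)
            if data[z, y, x] == 0:
                data[z, y, x] = 1.0
                data[z, y, x + 1] = 1.0
        labels = threshold_segment(DensityVolume(data, VS), 0.5)
        out = clean_components(labels, 8)
        assert out.n_components == 1

    def test_empty_mask_passthrough(self):
        labels = threshold_segment(DensityVolume(np.zeros((10, 10, 10), np.float32), VS), 1.0)
        out = clean_components(labels, 27)
        assert out.n_components == 0
        assert not out.mask.any()
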