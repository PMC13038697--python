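"""Mask/statistics primitives: exact volume accounting and ROI geometry."""

import numpy as np
import pytest

from ctlt.volume_model import (
    CTVolume,
    EmptyRegionError,
    LungMeasurement,
    MaskAlignmentError,
    RoiSpec,
    VoxelMask,
    combine_statistics,
    hu_window_mask,
    mask_statistics,
    roi_mean_hu,
)


def _uniform(value, shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0)):
    return CTVolume(np.full(shape, float(value)), spacing)


class TestMaskStatistics:
    def test_uniform_cube(self):
        vol = _uniform(-800.0)
        m = mask_statistics(vol, VoxelMask.full(vol.shape))
        assert m.volume_ml == pytest.approx(1.0)
        assert m.mean_hu == pytest.approx(-800.0)

    def test_half_and_half_mean(self):
        values = np.zeros((10, 10, 10))
        values[:5] = -1000.0
        vol = CTVolume(values, (1, 1, 1))
        m = mask_statistics(vol, VoxelMask.full(vol.shape))
        assert m.mean_hu == pytest.approx(-500.0)

    def test_fraction_field_matches_per_voxel_loop(self, rng):
        # HU assigned from a known fraction field; the mean must equal the
        # brute-force volume-weighted mixture voxel by voxel
        frac = rng.uniform(0, 1, size=(6, 7, 8))
        air, tissue = -980.0, 39.5
        hu = frac * tissue + (1 - frac) * air
        vol = CTVolume(hu, (2.0, 1.5, 1.0))
        sel = rng.random((6, 7, 8)) > 0.4
        m = mask_statistics(vol, VoxelMask(sel))
        acc = n = 0
        for idx in np.ndindex(*sel.shape):
            if sel[idx]:
                acc += hu[idx]
                n += 1
        assert m.mean_hu == pytest.approx(acc / n, rel=1e-12)
        assert m.volume_ml == pytest.approx(n * 3.0 / 1000.0, rel=1e-12)

    def test_volume_depends_only_on_count_and_spacing(self, rng):
        vol = _uniform(-700.0, spacing=(2.0, 2.0, 2.0))
        scattered = rng.random(vol.shape) < 0.3
        blocky = np.zeros(vol.shape, dtype=bool)
        blocky.ravel()[: scattered.sum()] = True
        a = mask_statistics(vol, VoxelMask(scattered))
        b = mask_statistics(vol, VoxelMask(blocky))
        assert a.volume_ml == pytest.approx(b.volume_ml)

    def test_empty_mask_raises(self):
        vol = _uniform(0.0)
        with pytest.raises(EmptyRegionError):
            mask_statistics(vol, VoxelMask.empty(vol.shape))

    def test_misaligned_mask_raises(self):
        vol = _uniform(0.0)
        with pytest.raises(MaskAlignmentError):
            mask_statistics(vol, VoxelMask.empty((5, 5, 5)))


class TestCombineStatistics:
    def test_identity(self):
        m = LungMeasurement(2312.0, -754.7)
        out = combine_statistics([m])
        assert (out.volume_ml, out.mean_hu) == (2312.0, -754.7)

    def test_equal_volume_symmetry(self):
        out = combine_statistics([LungMeasurement(5, -900), LungMeasurement(5, -700)])
        assert out.mean_hu == pytest.approx(-800.0)

    def test_weighted_pooling(self):
        out = combine_statistics([LungMeasurement(3, -600), LungMeasurement(1, -1000)])
        assert out.volume_ml == pytest.approx(4.0)
        assert out.mean_hu == pytest.approx(-700.0)

    def test_zero_total_volume_raises(self):
        with pytest.raises(EmptyRegionError):
            combine_statistics([LungMeasurement(0.0, -800.0)])

    def test_partition_recombines_exactly(self, rng):
        vol = CTVolume(rng.uniform(-1000, 100, (8, 8, 8)), (1.1, 0.9, 1.3))
        full = VoxelMask.full(vol.shape)
        labels = rng.integers(0, 4, vol.shape)
        parts = [
            mask_statistics(vol, VoxelMask(labels == k))
            for k in range(4)
            if (labels == k).any()
        ]
        pooled = combine_statistics(parts)
        whole = mask_statistics(vol, full)
        assert pooled.volume_ml == pytest.approx(whole.volume_ml, rel=1e-9)
        assert pooled.mean_hu == pytest.approx(whole.mean_hu, rel=1e-9)


class TestRoiMeanHu:
    def test_uniform_region(self):
        vol = _uniform(-980.0, shape=(3, 30, 30))
        roi = RoiSpec(slice_index=1, center_mm=(15.0, 15.0), diameter_mm=12.0)
        assert roi_mean_hu(vol, roi) == pytest.approx(-980.0)

    def test_symmetric_half_disc(self):
        values = np.full((3, 21, 21), -960.0)
        values[:, :, :10] = -1000.0  # columns 0..9 on the left of the disc centre
        vol = CTVolume(values, (1, 1, 1))
        roi = RoiSpec(slice_index=1, center_mm=(10.0, 9.5), diameter_mm=11.0)
        assert roi_mean_hu(vol, roi) == pytest.approx(-980.0)

    def test_scatter_offset_trachea(self, default_phantom):
        spec, vol, _ = default_phantom
        assert roi_mean_hu(vol, spec.trachea_roi()) == pytest.approx(spec.true_air_hu)

    def test_disc_outside_slice_raises(self):
        vol = _uniform(0.0, shape=(3, 20, 20))
        with pytest.raises(ValueError):
            roi_mean_hu(vol, RoiSpec(1, (2.0, 10.0), 12.0))

    def test_diameter_band_enforced(self):
        with pytest.raises(ValueError):
            RoiSpec(0, (10.0, 10.0), 5.0)
        RoiSpec(0, (10.0, 10.0), 5.0, diameter_band=(2.0, 30.0))  # configurable


class TestHuWindowMask:
    def test_window_containing_all_values_is_identity(self):
        vol = _uniform(-800.0)
        base = VoxelMask.full(vol.shape)
        out = hu_window_mask(vol, base, -1000.0, 100.0)
        assert np.array_equal(out.selected, base.selected)

    def test_degenerate_window_selects_exact_value(self, rng):
        values = rng.integers(-1000, 0, (6, 6, 6)).astype(float)
        vol = CTVolume(values, (1, 1, 1))
        out = hu_window_mask(vol, VoxelMask.full(vol.shape), -500.0, -500.0)
        assert np.array_equal(out.selected, values == -500.0)

    def test_matches_brute_force_filter(self, rng):
        values = rng.uniform(-1100, 200, (5, 6, 7))
        vol = CTVolume(values, (1, 1, 1))
        base = VoxelMask(rng.random((5, 6, 7)) > 0.5)
        out = hu_window_mask(vol, base, -1000.0, -500.0)
        for idx in np.ndindex(*values.shape):
            expected = base.selected[idx] and -1000.0 <= values[idx] <= -500.0
            assert out.selected[idx] == expected

    def test_bounds_out_of_order_raise(self):
        vol = _uniform(0.0)
        with pytest.raises(ValueError):
            hu_window_mask(vol, VoxelMask.full(vol.shape), -500.0, -1000.0)


class TestMaskAlgebra:
    def test_closure_and_alignment(self):
        a = VoxelMask(np.eye(4, dtype=bool)[None].repeat(4, axis=0))
        b = VoxelMask.full((4, 4, 4))
        assert (a | b).count == 64
        assert (a & b).count == a.count
        assert (b - a).count == 64 - a.count
        with pytest.raises(MaskAlignmentError):
            a.union(VoxelMask.full((3, 3, 3)))

    def test_invalid_volume_inputs(self):
        with pytest.raises(ValueError):
            CTVolume(np.zeros((4, 4)), (1, 1, 1))
        with pytest.raises(ValueError):
            CTVolume(np.zeros((4, 4, 4)), (1, 0, 1))
        with pytest.raises(ValueError):
            LungMeasurement(-1.0, -800.0)
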