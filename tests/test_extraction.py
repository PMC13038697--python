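"""Staged lung-field extraction: segmentation, airway/vessel removal,
surface shell, and the full protocol on phantoms with known truth."""

import numpy as np
import pytest

from ctlt.lung_extraction import (
    EmptyInteriorError,
    ExtractionConfig,
    SegmentationError,
    extract_whole_lung,
    remove_airways_vessels,
    run_extraction,
    surface_shell,
)
from ctlt.phantom import PhantomSpec, generate
from ctlt.tissue_model import CalibrationConstants, tissue_volume
from ctlt.volume_model import CTVolume, VoxelMask, mask_statistics


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2 * (a & b).sum() / (a.sum() + b.sum())


class TestExtractWholeLung:
    def test_phantom_lungs_recovered(self, default_phantom):
        _spec, vol, truth = default_phantom
        mask = extract_whole_lung(vol, ExtractionConfig())
        assert _dice(mask.selected, truth.lung_mask.selected) >= 0.99

    def test_all_soft_tissue_raises(self):
        vol = CTVolume(np.full((12, 12, 12), 40.0), (1, 1, 1))
        with pytest.raises(SegmentationError):
            extract_whole_lung(vol, ExtractionConfig())

    def test_border_connected_background_excluded(self, default_phantom):
        _spec, vol, truth = default_phantom
        mask = extract_whole_lung(vol, ExtractionConfig())
        # exterior air is low-HU but touches the volume border: none of it
        # may leak into the lung mask
        outside_body = ~truth.wall_mask.selected & ~truth.lung_mask.selected \
            & ~truth.airway_mask.selected
        border_air = np.zeros_like(outside_body)
        border_air[[0, -1]] = True
        border_air[:, [0, -1]] = True
        border_air[:, :, [0, -1]] = True
        assert not (mask.selected & border_air).any()

    def test_vessels_inside_after_hole_fill(self, default_phantom):
        _spec, vol, truth = default_phantom
        mask = extract_whole_lung(vol, ExtractionConfig())
        covered = (mask.selected & truth.vessel_mask.selected).sum()
        assert covered == truth.vessel_mask.count


class TestRemoveAirwaysVessels:
    def test_phantom_vessels_removed(self, default_phantom):
        _spec, vol, truth = default_phantom
        cfg = ExtractionConfig()
        lung = extract_whole_lung(vol, cfg)
        cleaned = remove_airways_vessels(vol, lung, cfg)
        removed = lung.selected & ~cleaned.selected
        recall = (removed & truth.vessel_mask.selected).sum() / truth.vessel_mask.count
        assert recall >= 0.95

    def test_clean_lung_unchanged(self):
        # uniform -800 HU lung with nothing above the vessel threshold and
        # no near-air seed anywhere: the mask passes through untouched
        vol = CTVolume(np.full((16, 16, 16), -800.0), (1, 1, 1))
        lung = VoxelMask(np.zeros((16, 16, 16), dtype=bool))
        lung.selected[4:12, 4:12, 4:12] = True
        out = remove_airways_vessels(vol, lung, ExtractionConfig())
        assert np.array_equal(out.selected, lung.selected)

    def test_contiguous_trachea_removed_by_region_growing(self):
        # a near-air tracheal cylinder contiguous with the lung region is
        # grown from the seed and excised even though thresholding alone
        # would keep it
        values = np.full((30, 21, 21), 40.0)
        values[2:16, 4:17, 4:17] = -800.0  # lung block
        values[10:28, 9:12, 9:12] = -980.0  # trachea, touching the lung top
        vol = CTVolume(values, (1, 1, 1))
        lung = VoxelMask(values <= -320.0)
        out = remove_airways_vessels(vol, lung, ExtractionConfig())
        assert not (out.selected & (values == -980.0)).any()
        assert out.selected[5, 5, 5]


class TestSurfaceShell:
    def test_cube_interior_band_matches_brute_force(self):
        mask = np.zeros((26, 26, 26), dtype=bool)
        mask[3:23, 3:23, 3:23] = True  # 20-voxel cube
        cfg = ExtractionConfig(shell_thickness_mm=1.0)
        shell = surface_shell(VoxelMask(mask), cfg, (1.0, 1.0, 1.0))
        inner_band = shell.selected & mask
        # brute force: cube voxels with a face neighbour outside the cube
        expected = 20**3 - 18**3
        assert inner_band.sum() == expected

    def test_empty_mask_gives_empty_shell(self):
        cfg = ExtractionConfig(shell_thickness_mm=2.0)
        shell = surface_shell(VoxelMask.empty((8, 8, 8)), cfg, (1, 1, 1))
        assert shell.count == 0

    def test_sphere_shell_scales_with_surface_area(self):
        r, t = 20, 3.0
        n = 2 * r + 12
        zz, yy, xx = np.ogrid[0:n, 0:n, 0:n]
        c = n / 2
        mask = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r**2
        cfg = ExtractionConfig(shell_thickness_mm=t)
        shell = surface_shell(VoxelMask(mask), cfg, (1, 1, 1))
        # continuous band of half-width t around the sphere surface,
        # approximately surface area x 2t
        analytic = 4.0 / 3.0 * np.pi * ((r + t) ** 3 - (r - t) ** 3)
        assert shell.count == pytest.approx(analytic, rel=0.10)

    def test_shell_thicker_than_mask_raises(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[4:6, 4:6, 4:6] = True
        cfg = ExtractionConfig(shell_thickness_mm=3.0)
        with pytest.raises(EmptyInteriorError):
            surface_shell(VoxelMask(mask), cfg, (1, 1, 1))


class TestRunExtraction:
    def test_final_region_excludes_boundary_soft_tissue(self, default_phantom):
        spec, vol, truth = default_phantom
        res = run_extraction(vol)
        final = res.masks["final"].selected
        assert not (final & truth.wall_mask.selected).any()
        interior_mean = spec.tissue_fraction * spec.true_tissue_hu + \
            (1 - spec.tissue_fraction) * spec.true_air_hu
        assert abs(res.measurement.mean_hu - interior_mean) <= 5.0
        assert vol.values[final].max() <= 100.0  # soft-tissue guard

    def test_stage_nesting_and_pooling(self, default_phantom, default_extraction):
        _spec, vol, _truth = default_phantom
        res = default_extraction
        a, b, c, d, e = (res.masks[k].selected for k in "abcde")
        assert not (d & e).any()
        assert (d & ~b).sum() == 0 and (b & ~a).sum() == 0
        assert (e & ~c).sum() == 0
        final = res.masks["final"].selected
        assert (final & ~(d | e)).sum() == 0
        # clipping never increases volume
        assert final.sum() <= (d | e).sum()
        assert res.measurement.volume_ml <= (d.sum() + e.sum()) * vol.voxel_volume_ml + 1e-9

    def test_addback_restores_surface_parenchyma(self):
        # thicker shell + high vessel threshold: the inner shell margin is
        # true parenchyma and must come back through the add-back window
        spec = PhantomSpec(seed=4)
        vol, truth = generate(spec)
        cfg = ExtractionConfig(shell_thickness_mm=6.0, vessel_threshold_hu=-300.0)
        res = run_extraction(vol, cfg)
        assert res.masks["e"].count > 0
        cal = CalibrationConstants(spec.true_air_hu, spec.true_tissue_hu)
        got = tissue_volume(res.measurement, cal).tissue_ml
        assert got == pytest.approx(truth.tissue_volume_ml, rel=0.02)

    def test_uniform_lung_measured_exactly(self):
        # fraction 0.2 with classical endpoints: parenchyma sits at -800 HU
        spec = PhantomSpec(tissue_fraction=0.2, true_air_hu=-1000.0, true_tissue_hu=0.0,
                           vessel_count=0, seed=6)
        vol, truth = generate(spec)
        res = run_extraction(vol)
        assert res.measurement.mean_hu == pytest.approx(-800.0, abs=0.5)
        assert res.measurement.volume_ml == pytest.approx(truth.interior_volume_ml, rel=0.02)

    def test_determinism(self, default_phantom):
        _spec, vol, _truth = default_phantom
        r1 = run_extraction(vol)
        r2 = run_extraction(vol)
        for k in r1.masks:
            assert np.array_equal(r1.masks[k].selected, r2.masks[k].selected)
        assert r1.measurement == r2.measurement
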