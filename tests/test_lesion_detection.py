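import numpy as np
import pytest
from scipy import ndimage

from octa_lesion.config import DetectionConfig
from octa_lesion.heatmap_mapping import HeatMap2D, HeatVolume, RoiGrid, make_roi_grid
from octa_lesion.lesion_detection import (
    classify_subtype,
    detect_nbcc_area,
    detect_sbcc_area,
    lesion_present,
    place_healthy_roi,
    place_lesion_roi,
    refine_mask,
)
from octa_lesion.volume_io import VoxelGrid


def heat_volume_from_values(values):
    vol = np.asarray(values, dtype=float)[None, :, :]
    return HeatVolume(values=vol, support=(vol != 0).astype(np.uint8), parameter="VD")


def heat_map(values):
    v = np.asarray(values, dtype=float)
    return HeatMap2D(values=v, coverage=np.ones_like(v, dtype=int), parameter="VD")


def gaussian_bump(n=128, center=(64, 64), amp=0.003, base=0.001, sigma=12):
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return base + amp * np.exp(-((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * sigma**2))


CFG = DetectionConfig()
SMALL_CFG = DetectionConfig(disk_radius_px=5)


class TestLesionPresent:
    def test_uniform_not_present(self):
        hv = heat_volume_from_values(np.full((8, 8), 0.002))
        present, sd = lesion_present(hv, CFG)
        assert sd == 0.0 and not present

    def test_two_value_sd(self):
        vals = np.full((4, 4), 0.001)
        vals[2:] = 0.003
        hv = heat_volume_from_values(vals)
        present, sd = lesion_present(hv, CFG)
        assert sd == pytest.approx(0.001, rel=1e-12)
        assert present  # 0.001 >= 4e-5

    def test_threshold_boundary(self):
        vals = np.full((100, 100), 0.002)
        vals[:50] += 7.9e-5  # sd just below 4e-5
        hv = heat_volume_from_values(vals)
        present, sd = lesion_present(hv, CFG)
        assert sd < 4e-5 and not present

    def test_empty_skeleton_rejected(self):
        hv = HeatVolume(values=np.zeros((1, 4, 4)), support=np.zeros((1, 4, 4), np.uint8),
                        parameter="VD")
        with pytest.raises(ValueError):
            lesion_present(hv, CFG)


class TestClassifySubtype:
    def test_single_bump_is_sbcc(self):
        assert classify_subtype(heat_map(gaussian_bump()), CFG) == "sBCC"

    def test_multiple_patches_is_nbcc(self):
        vals = np.full((128, 128), 0.001)
        for c in ((20, 20), (100, 100), (20, 100)):
            vals += gaussian_bump(center=c, amp=0.003, base=0.0, sigma=6)
        assert classify_subtype(heat_map(vals), CFG) == "nBCC"

    def test_small_specks_ignored(self):
        vals = np.full((128, 128), 0.001)
        vals += gaussian_bump(center=(64, 64), amp=0.003, base=0.0, sigma=10)
        vals[5, 5] = 0.0038  # above threshold but a single-pixel speck
        assert classify_subtype(heat_map(vals), CFG) == "sBCC"


class TestDetectSbccArea:
    def test_threshold_oracle(self):
        vals = gaussian_bump(amp=0.003, base=0.001)  # peak 0.004
        mask = detect_sbcc_area(heat_map(vals), SMALL_CFG)
        core = vals >= 0.75 * vals.max()
        assert np.all(mask[core])  # refined mask contains the raw threshold region

    def test_constant_map_selects_everything(self):
        vals = np.full((64, 64), 0.002)
        mask = detect_sbcc_area(heat_map(vals), SMALL_CFG)
        assert mask.all()

    def test_tie_broken_by_area_then_centroid(self):
        vals = np.full((64, 64), 0.0)
        vals[10:14, 10:14] = 1.0  # 16 px
        vals[40:46, 40:46] = 1.0  # 36 px: larger wins
        mask = detect_sbcc_area(heat_map(vals), SMALL_CFG)
        assert mask[43, 43] and not mask[12, 12]


class TestDetectNbccArea:
    def test_single_basin_first_iteration(self):
        vals = np.full((128, 128), 0.003)
        yy, xx = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
        basin = (yy - 64) ** 2 + (xx - 64) ** 2 <= 15**2
        vals[basin] = 0.001
        mask, trace = detect_nbcc_area(heat_map(vals), SMALL_CFG)
        assert len(trace) == 1
        assert trace[0] == pytest.approx(1.2 * 0.001)
        assert mask[64, 64]

    def test_sweep_oracle_equivalence(self):
        rng = np.random.default_rng(71)
        vals = 0.003 + 0.001 * rng.random((96, 96))
        yy, xx = np.meshgrid(np.arange(96), np.arange(96), indexing="ij")
        vals[(yy - 30) ** 2 + (xx - 30) ** 2 <= 10**2] = 0.0012
        vals[(yy - 70) ** 2 + (xx - 70) ** 2 <= 6**2] = 0.0014
        hm = heat_map(vals)
        mask, trace = detect_nbcc_area(hm, SMALL_CFG)
        # independent exhaustive sweep over the threshold sequence
        m0 = vals[vals > 0].min()
        thr = 1.2 * m0
        expected_thr = None
        while thr <= vals.max() * 1.3 + 1e-12:
            sel = (vals > 0) & (vals <= thr)
            lab, n = ndimage.label(sel, structure=np.ones((3, 3)))
            counts = np.bincount(lab.ravel())[1:]
            if (counts >= 10).sum() == 1:
                expected_thr = thr
                break
            thr *= 1.3
        assert expected_thr is not None
        assert trace[-1] == pytest.approx(expected_thr, rel=1e-12)

    def test_non_convergence_error(self):
        # two equal, far-apart basins that merge with the background at
        # every threshold: no single-component threshold exists
        vals = np.zeros((64, 64))
        vals[10:20, 10:20] = 0.001
        vals[44:54, 44:54] = 0.001
        with pytest.raises(ValueError, match="trace"):
            detect_nbcc_area(heat_map(vals), SMALL_CFG)


class TestRefineMask:
    def test_single_pixel_becomes_disk(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[32, 32] = True
        out = refine_mask(mask, CFG)
        area = out.sum()
        assert abs(area - np.pi * 20**2) / (np.pi * 20**2) < 0.05

    def test_two_close_blobs_merge(self):
        from scipy import ndimage

        mask = np.zeros((128, 128), dtype=bool)
        mask[60:64, 30:34] = True
        mask[60:64, 60:64] = True  # ~30 px apart, closing disk radius 20
        out = refine_mask(mask, CFG)
        _, n = ndimage.label(out, structure=np.ones((3, 3)))
        assert n == 1

    def test_border_clipped(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[0, 0] = True
        out = refine_mask(mask, CFG)
        assert out.shape == (40, 40)
        assert out[0, 0]

    def test_extensive(self):
        rng = np.random.default_rng(73)
        mask = rng.random((64, 64)) > 0.9
        out = refine_mask(mask, SMALL_CFG)
        assert np.all(out[mask])

    def test_monotone_in_radius(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[30:34, 30:34] = True
        small = refine_mask(mask, DetectionConfig(disk_radius_px=5))
        big = refine_mask(mask, DetectionConfig(disk_radius_px=10))
        assert np.all(big[small])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            refine_mask(np.zeros((8, 8), dtype=bool), CFG)


class TestPlaceLesionRoi:
    GRID = VoxelGrid((10, 256, 256), (0.03, 0.03125, 0.03125))

    def test_centered_on_peak(self):
        vals = gaussian_bump(n=256, center=(128, 128), amp=0.003, base=0.001, sigma=20)
        mask = vals >= 0.75 * vals.max()
        roi = place_lesion_roi(heat_map(vals), mask, CFG, self.GRID, "sBCC")
        cy, cx = roi.center_mm[1], roi.center_mm[2]
        assert abs(cy - 128.5 * 0.03125) < 0.05
        assert abs(cx - 128.5 * 0.03125) < 0.05

    def test_clamped_inside(self):
        vals = gaussian_bump(n=256, center=(5, 5), amp=0.003, base=0.001, sigma=4)
        mask = vals >= 0.75 * vals.max()
        roi = place_lesion_roi(heat_map(vals), mask, CFG, self.GRID, "sBCC")
        assert roi.origin_mm[1] == 0.0 and roi.origin_mm[2] == 0.0

    def test_nbcc_centres_on_minimum(self):
        vals = np.full((256, 256), 0.003)
        yy, xx = np.meshgrid(np.arange(256), np.arange(256), indexing="ij")
        d2 = (yy - 90) ** 2 + (xx - 160) ** 2
        vals = vals - 0.002 * np.exp(-d2 / (2 * 20**2))
        mask = d2 <= 40**2
        roi = place_lesion_roi(heat_map(vals), mask, CFG, self.GRID, "nBCC")
        assert abs(roi.center_mm[1] - 90.5 * 0.03125) < 0.05
        assert abs(roi.center_mm[2] - 160.5 * 0.03125) < 0.05

    def test_empty_mask_rejected(self):
        vals = np.full((256, 256), 0.002)
        with pytest.raises(ValueError):
            place_lesion_roi(heat_map(vals), np.zeros((256, 256), bool), CFG, self.GRID)


class TestPlaceHealthyRoi:
    GRID = VoxelGrid((10, 256, 256), (0.03, 0.03125, 0.03125))

    def _grid(self):
        return make_roi_grid(self.GRID, roi_size_mm=(2.5, 2.5), overlap_frac=0.3)

    def test_corner_lesion_far_corner_healthy(self):
        rg = self._grid()
        mask = np.zeros((256, 256), dtype=bool)
        mask[:60, :60] = True
        roi = place_healthy_roi(rg, mask)
        ext = self.GRID.extent_mm
        assert roi.origin_mm[1] + roi.size_mm[1] == pytest.approx(ext[1], abs=0.05)
        assert roi.origin_mm[2] + roi.size_mm[2] == pytest.approx(ext[2], abs=0.05)

    def test_central_lesion_corner_tiebreak(self):
        rg = self._grid()
        mask = np.zeros((256, 256), dtype=bool)
        mask[119:138, 119:138] = True  # symmetric about the grid centre
        roi = place_healthy_roi(rg, mask)
        # all four corners are equidistant; the smallest ROI index (0) wins
        assert roi is rg.rois[0]

    def test_brute_force_distance_oracle(self):
        rng = np.random.default_rng(79)
        rg = self._grid()
        mask = np.zeros((256, 256), dtype=bool)
        mask[30:80, 140:210] = True
        roi = place_healthy_roi(rg, mask)
        # exhaustive: for each candidate compute min distance centre->mask
        les = np.argwhere(mask)
        sp = (0.03125, 0.03125)
        best = None
        best_key = None
        for i, cand in enumerate(rg.rois):
            _, _, y0, y1, x0, x1 = cand.voxel_bounds(self.GRID)
            if mask[y0:y1, x0:x1].any():
                continue
            cy, cx = (y0 + y1) // 2, (x0 + x1) // 2
            d = np.sqrt(((les[:, 0] - cy) * sp[0]) ** 2 + ((les[:, 1] - cx) * sp[1]) ** 2).min()
            key = (-d, i)
            if best_key is None or key < best_key:
                best, best_key = cand, key
        assert roi is best

    def test_all_rois_intersect_rejected(self):
        rg = self._grid()
        mask = np.ones((256, 256), dtype=bool)
        with pytest.raises(ValueError):
            place_healthy_roi(rg, mask)
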