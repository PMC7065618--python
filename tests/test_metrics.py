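import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from octa_lesion.skeletonization import RadiusMap, SkeletonMask, build_graph, estimate_radii, skeletonize
from octa_lesion.vascular_metrics import (
    RoiBox,
    count_inflections,
    distance_metric,
    inflection_count_metric,
    roi_params,
    sum_of_angles_metric,
    vascular_density,
)
from octa_lesion.vessel_segmentation import VesselMask
from octa_lesion.volume_io import VoxelGrid

from conftest import tube_mask


def path3(xy):
    """Embed a 2D (y, x) path into (z, y, x) at z = 0."""
    xy = np.asarray(xy, dtype=float)
    return np.column_stack([np.zeros(len(xy)), xy])


class TestDistanceMetric:
    def test_straight_line_is_one(self):
        pts = path3([(0, 0), (0, 1), (0, 2)])
        assert distance_metric(pts) == 1.0

    def test_right_angle(self):
        pts = path3([(0, 0), (0, 1), (1, 1)])
        assert distance_metric(pts) == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_semicircle_analytic_limit(self):
        t = np.linspace(0, np.pi, 360)
        pts = path3(np.column_stack([np.sin(t), np.cos(t)]))
        assert distance_metric(pts) == pytest.approx(np.pi / 2, rel=0.005)

    def test_closed_path_missing(self):
        pts = path3([(0, 0), (0, 1), (1, 1), (0, 0)])
        assert distance_metric(pts) is None

    def test_projection_ignores_depth(self):
        # the metric is two-dimensional: depth excursions do not count
        pts = np.array([[0.0, 0, 0], [5.0, 0, 1], [0.0, 0, 2]])
        assert distance_metric(pts) == 1.0

    def test_rigid_motion_and_scale_invariance(self):
        rng = np.random.default_rng(43)
        for _ in range(10):
            xy = np.cumsum(rng.normal(size=(20, 2)), axis=0)
            pts = path3(xy)
            dm = distance_metric(pts)
            theta = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
            moved = path3(xy @ R.T + rng.normal(size=2))
            assert distance_metric(moved) == pytest.approx(dm, rel=1e-9)
            assert distance_metric(path3(3.7 * xy)) == pytest.approx(dm, rel=1e-9)


class TestInflectionCount:
    def test_straight_path_zero(self):
        pts = path3([(0, i) for i in range(10)])
        assert inflection_count_metric(pts) == 0.0

    def test_single_arc_zero(self):
        t = np.linspace(0, np.pi / 2, 50)
        pts = path3(np.column_stack([np.sin(t), 1 - np.cos(t)]))
        assert inflection_count_metric(pts) == 0.0

    def test_sine_period_two_inflections(self):
        # one full period sampled from a crest: curvature flips sign twice
        x = np.linspace(0, 2 * np.pi, 100)
        pts = path3(np.column_stack([np.cos(x), x]))
        assert count_inflections(np.column_stack([np.cos(x), x])) == 2
        dm = distance_metric(pts)
        assert inflection_count_metric(pts) == pytest.approx(2 * dm, rel=1e-9)

    def test_brute_force_sign_flips(self):
        rng = np.random.default_rng(47)
        xy = np.cumsum(rng.normal(size=(60, 2)), axis=0)
        tang = np.diff(xy, axis=0)
        cross = tang[:-1, 0] * tang[1:, 1] - tang[:-1, 1] * tang[1:, 0]
        signs = np.sign(cross[np.abs(np.arctan2(np.abs(cross), (tang[:-1] * tang[1:]).sum(1))) >= 1e-6])
        signs = signs[signs != 0]
        expected = int(np.sum(signs[:-1] * signs[1:] < 0))
        assert count_inflections(xy) == expected

    def test_too_short_missing(self):
        assert inflection_count_metric(path3([(0, 0), (0, 1), (1, 1)])) is None


class TestSumOfAngles:
    def test_straight_zero(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]], dtype=float)
        assert sum_of_angles_metric(pts) == 0.0

    def test_planar_right_angle(self):
        pts = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 1]], dtype=float)  # two 1 mm legs
        assert sum_of_angles_metric(pts) == pytest.approx((np.pi / 2) / 2, rel=1e-12)

    def test_helix_turning_rate(self):
        from octa_lesion.synthetic_phantom import helix_turning_rate, make_path

        r, pitch = 0.5, 1.0
        pts = make_path("helix", {"center": (0, 1, 1), "radius": r, "pitch": pitch, "turns": 2, "n": 500})
        soam = sum_of_angles_metric(pts)
        assert soam == pytest.approx(helix_turning_rate(r, pitch), rel=0.02)

    def test_coincident_path_missing(self):
        pts = np.zeros((5, 3))
        assert sum_of_angles_metric(pts) is None

    def test_rigid_invariance_and_length_scaling(self):
        rng = np.random.default_rng(53)
        for seed in range(20):
            r = np.random.default_rng(seed)
            pts = np.cumsum(r.normal(size=(25, 3)), axis=0)
            soam = sum_of_angles_metric(pts)
            R = Rotation.random(random_state=seed).as_matrix()
            moved = pts @ R.T + r.normal(size=3)
            assert sum_of_angles_metric(moved) == pytest.approx(soam, rel=1e-9)
            assert sum_of_angles_metric(2.0 * pts) == pytest.approx(soam / 2, rel=1e-12)


class TestVascularDensity:
    def _skel(self, shape, voxels, spacing=(1, 1, 1)):
        data = np.zeros(shape, dtype=np.uint8)
        for v in voxels:
            data[v] = 1
        return SkeletonMask(data, VoxelGrid(shape, spacing))

    def test_full_roi(self):
        shape = (4, 4, 4)
        skel = self._skel(shape, [(z, y, x) for z in range(4) for y in range(4) for x in range(4)])
        roi = RoiBox((0, 0, 0), (4, 4, 4))
        assert vascular_density(skel, roi) == 1.0

    def test_empty_roi(self):
        skel = self._skel((4, 4, 4), [])
        assert vascular_density(skel, RoiBox((0, 0, 0), (4, 4, 4))) == 0.0

    def test_counting_oracle_tube(self):
        shape = (50, 50, 50)
        skel = self._skel(shape, [(25, 25, x) for x in range(50)])
        vd = vascular_density(skel, RoiBox((0, 0, 0), (50, 50, 50)))
        assert vd == pytest.approx(50 / 50**3, abs=0)

    def test_roi_outside_volume(self):
        skel = self._skel((4, 4, 4), [])
        with pytest.raises(ValueError):
            vascular_density(skel, RoiBox((10, 10, 10), (2, 2, 2)))

    def test_additivity_of_disjoint_rois(self):
        rng = np.random.default_rng(59)
        shape = (10, 20, 20)
        vox = [tuple(v) for v in rng.integers(0, [10, 20, 20], size=(60, 3))]
        skel = self._skel(shape, vox)
        left = RoiBox((0, 0, 0), (10, 20, 10))
        right = RoiBox((0, 0, 10), (10, 20, 10))
        whole = RoiBox((0, 0, 0), (10, 20, 20))
        nl = vascular_density(skel, left) * 10 * 20 * 10
        nr = vascular_density(skel, right) * 10 * 20 * 10
        nw = vascular_density(skel, whole) * 10 * 20 * 20
        assert nl + nr == pytest.approx(nw, abs=1e-9)


class TestRoiParams:
    def _build(self, mask_data, spacing=(1, 1, 1)):
        grid = VoxelGrid(mask_data.shape, spacing)
        mask = VesselMask(mask_data.astype(np.uint8), grid)
        skel = skeletonize(mask)
        radii = estimate_radii(mask, skel)
        graph = build_graph(skel, radii, prune_spur_vox=0)
        return graph, skel, radii

    def test_single_tube_composite(self):
        shape = (16, 16, 40)
        graph, skel, radii = self._build(tube_mask(shape, (8, 8), 3))
        roi = RoiBox((0, 0, 0), shape)
        p = roi_params(graph, skel, radii, roi)
        assert p.NT == 1
        assert p.NB == 1
        assert p.DM == pytest.approx(1.0, abs=1e-6)
        assert p.ICM == 0.0
        assert p.SOAM == pytest.approx(0.0, abs=1e-9)

    def test_two_tubes_additive(self):
        shape = (16, 32, 40)
        data = tube_mask(shape, (8, 8), 3) | tube_mask(shape, (8, 24), 3)
        graph, skel, radii = self._build(data)
        p = roi_params(graph, skel, radii, RoiBox((0, 0, 0), shape))
        assert p.NT == 2
        assert p.NB == 2

    def test_undefined_metrics_reported_missing(self):
        shape = (8, 8, 8)
        data = np.zeros(shape)
        graph, skel, radii = self._build(data)
        p = roi_params(graph, skel, radii, RoiBox((0, 0, 0), shape))
        assert p.NT == 0 and p.NB == 0 and p.VD == 0.0
        assert p.MR is None and p.DM is None and p.ICM is None and p.SOAM is None

    @pytest.mark.parametrize("seed", range(5))
    def test_full_brute_force_oracle(self, seed):
        from scipy import ndimage

        rng = np.random.default_rng(100 + seed)
        shape = (20, 40, 40)
        data = np.zeros(shape, dtype=np.uint8)
        for _ in range(3):
            cz = int(rng.integers(4, 16))
            cy = int(rng.integers(4, 36))
            data |= tube_mask(shape, (cz, cy), 2)
        graph, skel, radii = self._build(data)
        roi = RoiBox((2.0, 5.0, 5.0), (12.0, 22.0, 28.0))
        p = roi_params(graph, skel, radii, roi)

        z0, z1, y0, y1, x0, x1 = roi.voxel_bounds(skel.grid)
        sub = skel.data[z0:z1, y0:y1, x0:x1]
        # NT: independent flood fill
        assert p.NT == ndimage.label(sub, structure=np.ones((3, 3, 3)))[1]
        # VD: exhaustive count
        count = sum(
            1
            for z in range(z0, z1)
            for y in range(y0, y1)
            for x in range(x0, x1)
            if skel.data[z, y, x]
        )
        assert p.VD == pytest.approx(count / ((z1 - z0) * (y1 - y0) * (x1 - x0)), abs=0)
        # NB: branch membership by voxel scan
        nb = sum(
            1
            for b in graph.branches
            if any(
                z0 <= v[0] < z1 and y0 <= v[1] < y1 and x0 <= v[2] < x1 for v in b.voxels
            )
        )
        assert p.NB == nb
        # MR: mean of EDT radii over in-ROI skeleton voxels
        sel = [
            radii.get(tuple(v))
            for v in np.argwhere(skel.data)
            if z0 <= v[0] < z1 and y0 <= v[1] < y1 and x0 <= v[2] < x1
        ]
        if sel:
            assert p.MR == pytest.approx(float(np.mean(sel)), rel=1e-12)
        else:
            assert p.MR is None


class TestRoiBox:
    def test_half_open_bounds(self):
        grid = VoxelGrid((10, 10, 10), (0.5, 0.5, 0.5))
        roi = RoiBox((0.0, 1.0, 1.0), (1.0, 2.0, 2.0))
        assert roi.voxel_bounds(grid) == (0, 2, 2, 6, 2, 6)

    def test_clipping(self):
        grid = VoxelGrid((10, 10, 10), (1, 1, 1))
        roi = RoiBox((8.0, 8.0, 8.0), (5.0, 5.0, 5.0))
        assert roi.voxel_bounds(grid) == (8, 10, 8, 10, 8, 10)

    def test_rejects_nonpositive_size(self):
        with pytest.raises(ValueError):
            RoiBox((0, 0, 0), (1.0, 0.0, 1.0))
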