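"""The seven quantitative vascular parameters evaluated inside an ROI.

* NT — number of trees: 26-connected components of the skeleton
  restricted to the ROI.
* NB — number of branches with at least one voxel inside the ROI.
* VD — vascular density: skeleton voxels / all voxels inside the ROI.
* MR — mean radius (mm) over skeleton voxels inside the ROI.
* DM — distance metric: en-face path length over endpoint chord length
  (1 for a straight vessel, growing with curvature).
* ICM — inflection count metric: DM times the number of
  curvature-sign inflections along the en-face path.
* SOAM — sum of angles metric: total 3D turning angle per unit path
  length (rad/mm), sensitive to tight coiling.

DM and ICM are two-dimensional: paths are projected to the en-face
(y, x) plane first.  SOAM uses the full 3D path.  Metrics that are
undefined for a given ROI (no qualifying branch) are reported as
``None``, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .skeletonization import RadiusMap, SkeletonGraph, SkeletonMask
from .volume_io import VoxelGrid, mm_to_vox

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned box, origin and size in mm (z, y, x order)."""

    origin_mm: Tuple[float, float, float]
    size_mm: Tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size_mm):
            raise ValueError(f"ROI size must be positive, got {self.size_mm}")

    def voxel_bounds(self, grid: VoxelGrid) -> Tuple[int, int, int, int, int, int]:
        """Half-open voxel bounds (z0, z1, y0, y1, x0, x1), clipped to the grid."""
        lo = [mm_to_vox(o, s) for o, s in zip(self.origin_mm, grid.spacing)]
        n = [mm_to_vox(sz, s) for sz, s in zip(self.size_mm, grid.spacing)]
        b = []
        for axis in range(3):
            i0 = max(0, min(lo[axis], grid.shape[axis]))
            i1 = max(0, min(lo[axis] + max(1, n[axis]), grid.shape[axis]))
            b.extend([i0, i1])
        if b[0] >= b[1] or b[2] >= b[3] or b[4] >= b[5]:
            raise ValueError(f"ROI {self} lies fully outside the volume")
        return tuple(b)

    @property
    def center_mm(self) -> Tuple[float, float, float]:
        return tuple(o + s / 2 for o, s in zip(self.origin_mm, self.size_mm))


@dataclass
class VascularParams:
    NT: int
    NB: int
    VD: float
    MR: Optional[float]
    DM: Optional[float]
    ICM: Optional[float]
    SOAM: Optional[float]
    n_branches_evaluated: int

    def as_dict(self) -> dict:
        return {
            "NT": self.NT,
            "NB": self.NB,
            "VD": self.VD,
            "MR_mm": self.MR,
            "DM": self.DM,
            "ICM": self.ICM,
            "SOAM": self.SOAM,
            "n_branches_evaluated": self.n_branches_evaluated,
        }


def _dedupe(points: np.ndarray) -> np.ndarray:
    """Collapse consecutive coincident points."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.shape[0] < 2:
        return pts
    keep = np.ones(pts.shape[0], dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0
    return pts[keep]


def _smooth(points: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average along the path; endpoints kept fixed."""
    if window <= 1 or points.shape[0] < 3:
        return points
    half = (window - 1) // 2
    out = points.copy()
    for i in range(1, points.shape[0] - 1):
        lo = max(0, i - half)
        hi = min(points.shape[0], i + half + 1)
        out[i] = points[lo:hi].mean(axis=0)
    return out


def distance_metric(points: np.ndarray) -> Optional[float]:
    """En-face tortuosity: projected path length over endpoint chord length.

    ``points`` are (n, 3) (z, y, x) mm coordinates; the path is projected
    to the en-face (y, x) plane first.  Returns ``None`` for degenerate
    paths (fewer than 2 distinct projected points, or coincident
    endpoints).
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2:
        raise ValueError("points must be a 2D array of coordinates")
    proj = _dedupe(pts[:, 1:] if pts.shape[1] == 3 else pts)
    if proj.shape[0] < 2:
        return None
    chord = float(np.linalg.norm(proj[-1] - proj[0]))
    if chord == 0:
        return None
    length = float(np.linalg.norm(np.diff(proj, axis=0), axis=1).sum())
    return length / chord


def count_inflections(
    points2d: np.ndarray, angle_floor: float = 1e-6, smooth_window: int = 1
) -> int:
    """Curvature-sign flips along a 2D path.

    The sign of the z-component of the cross product of consecutive
    tangent vectors gives the local turning direction; a sign change is
    an inflection.  Turns with angle below ``angle_floor`` rad are
    treated as noise and ignored.
    """
    pts = _dedupe(np.asarray(points2d, dtype=np.float64))
    pts = _smooth(pts, smooth_window)
    pts = _dedupe(pts)
    if pts.shape[0] < 4:
        return 0
    tang = np.diff(pts, axis=0)
    cross = tang[:-1, 0] * tang[1:, 1] - tang[:-1, 1] * tang[1:, 0]
    dot = (tang[:-1] * tang[1:]).sum(axis=1)
    ang = np.arctan2(np.abs(cross), dot)
    signs = np.sign(cross)[(ang >= angle_floor) & (np.sign(cross) != 0)]
    if signs.size < 2:
        return 0
    return int(np.sum(signs[:-1] * signs[1:] < 0))


def inflection_count_metric(
    points: np.ndarray, angle_floor: float = 1e-6, smooth_window: int = 1
) -> Optional[float]:
    """ICM = DM x (number of en-face curvature-sign inflections)."""
    pts = np.asarray(points, dtype=np.float64)
    proj = _dedupe(pts[:, 1:] if pts.shape[1] == 3 else pts)
    if proj.shape[0] < 4:
        return None
    dm = distance_metric(points)
    if dm is None:
        return None
    return dm * count_inflections(proj, angle_floor=angle_floor, smooth_window=smooth_window)


def sum_of_angles_metric(points: np.ndarray, smooth_window: int = 1) -> Optional[float]:
    """Total 3D turning angle divided by total 3D path length (rad/mm)."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim == 2 and pts.shape[1] == 2:  # planar path: embed in 3D
        pts = np.column_stack([np.zeros(len(pts)), pts])
    pts = _dedupe(pts)
    pts = _smooth(pts, smooth_window)
    pts = _dedupe(pts)
    if pts.shape[0] < 3:
        return None
    tang = np.diff(pts, axis=0)
    length = float(np.linalg.norm(tang, axis=1).sum())
    if length == 0:
        return None
    cross = np.cross(tang[:-1], tang[1:])
    dot = (tang[:-1] * tang[1:]).sum(axis=1)
    angles = np.arctan2(np.linalg.norm(np.atleast_2d(cross), axis=1), dot)
    return float(angles.sum() / length)


def vascular_density(skel: SkeletonMask, roi: RoiBox) -> float:
    """Skeleton voxels inside the ROI divided by all voxels inside the ROI."""
    z0, z1, y0, y1, x0, x1 = roi.voxel_bounds(skel.grid)
    sub = skel.data[z0:z1, y0:y1, x0:x1]
    return float(sub.sum()) / float(sub.size)


def _roi_runs(voxels: np.ndarray, bounds) -> List[np.ndarray]:
    """Maximal contiguous runs of branch voxel indices inside the ROI."""
    z0, z1, y0, y1, x0, x1 = bounds
    inside = (
        (voxels[:, 0] >= z0)
        & (voxels[:, 0] < z1)
        & (voxels[:, 1] >= y0)
        & (voxels[:, 1] < y1)
        & (voxels[:, 2] >= x0)
        & (voxels[:, 2] < x1)
    )
    if not inside.any():
        return []
    d = np.diff(inside.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if inside[0]:
        starts = np.concatenate(([0], starts))
    if inside[-1]:
        ends = np.concatenate((ends, [inside.size]))
    return [np.arange(s, e) for s, e in zip(starts, ends)]


def roi_params(
    graph: SkeletonGraph,
    skel: SkeletonMask,
    radii: RadiusMap,
    roi: RoiBox,
    min_branch_points: int = 4,
    smooth_window: int = 3,
    angle_floor: float = 1e-6,
) -> VascularParams:
    """Evaluate all seven vascular parameters inside one ROI.

    DM/ICM/SOAM are unweighted means over branches clipped to the ROI:
    for each branch, every maximal contiguous in-ROI run with at least
    ``min_branch_points`` points is evaluated and the run values
    averaged; branches with no qualifying run are skipped.
    """
    bounds = roi.voxel_bounds(skel.grid)
    z0, z1, y0, y1, x0, x1 = bounds
    sub = skel.data[z0:z1, y0:y1, x0:x1]
    nt = int(ndimage.label(sub, structure=_STRUCT26)[1])
    vd = float(sub.sum()) / float(sub.size)

    in_roi = np.zeros(len(radii), dtype=bool)
    if len(radii):
        c = radii.coords
        in_roi = (
            (c[:, 0] >= z0)
            & (c[:, 0] < z1)
            & (c[:, 1] >= y0)
            & (c[:, 1] < y1)
            & (c[:, 2] >= x0)
            & (c[:, 2] < x1)
        )
    mr = float(radii.radii_mm[in_roi].mean()) if in_roi.any() else None

    nb = 0
    dms: List[float] = []
    icms: List[float] = []
    soams: List[float] = []
    n_eval = 0
    for b in graph.branches:
        runs = _roi_runs(b.voxels, bounds)
        if not runs:
            continue
        nb += 1
        b_dm: List[float] = []
        b_icm: List[float] = []
        b_soam: List[float] = []
        for run in runs:
            if run.size < min_branch_points:
                continue
            pts = b.points_mm[run]
            dm = distance_metric(pts)
            icm = inflection_count_metric(
                pts, angle_floor=angle_floor, smooth_window=smooth_window
            )
            soam = sum_of_angles_metric(pts, smooth_window=smooth_window)
            if dm is not None:
                b_dm.append(dm)
            if icm is not None:
                b_icm.append(icm)
            if soam is not None:
                b_soam.append(soam)
        if b_dm or b_icm or b_soam:
            n_eval += 1
        if b_dm:
            dms.append(float(np.mean(b_dm)))
        if b_icm:
            icms.append(float(np.mean(b_icm)))
        if b_soam:
            soams.append(float(np.mean(b_soam)))

    return VascularParams(
        NT=nt,
        NB=nb,
        VD=vd,
        MR=mr,
        DM=float(np.mean(dms)) if dms else None,
        ICM=float(np.mean(icms)) if icms else None,
        SOAM=float(np.mean(soams)) if soams else None,
        n_branches_evaluated=n_eval,
    )
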