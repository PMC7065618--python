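"""Overlapping ROI grids and en-face parameter heat maps.

The volume is tiled with ROIs of fixed en-face size laid out row-major
with a configurable fractional overlap between juxtaposed ROIs (default
30%).  The final row/column is shifted inward so the last ROI ends flush
with the volume boundary, keeping every ROI the same size.  Each ROI's
scalar parameter value is spread over its en-face footprint; where
footprints overlap, the arithmetic mean over contributing ROIs is
reported.  The same averaged value can be painted back onto skeleton or
vessel voxels to produce non-binary "heat volumes" for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .skeletonization import RadiusMap, SkeletonGraph, SkeletonMask
from .vascular_metrics import RoiBox, VascularParams, roi_params
from .vessel_segmentation import VesselMask
from .volume_io import VoxelGrid

PARAMETER_NAMES = ("NT", "NB", "VD", "MR", "DM", "ICM", "SOAM")


@dataclass
class RoiGrid:
    """Ordered (row-major in y, then x) list of identically sized ROIs."""

    rois: List[RoiBox]
    roi_size_mm: Tuple[float, float, float]
    overlap_frac: float
    grid: VoxelGrid

    def __len__(self) -> int:
        return len(self.rois)


@dataclass
class HeatMap2D:
    """En-face parameter map with per-pixel contributing-ROI counts.

    ``values`` is NaN where no contributing ROI had a defined value.
    """

    values: np.ndarray
    coverage: np.ndarray
    parameter: str


@dataclass
class HeatVolume:
    """Parameter values painted onto skeleton (or vessel) voxels, 0 elsewhere."""

    values: np.ndarray
    support: np.ndarray  # binary mask of painted voxels
    parameter: str

    def support_values(self) -> np.ndarray:
        return self.values[self.support.astype(bool)]


def _axis_starts(extent: float, size: float, stride: float) -> List[float]:
    eps = 1e-9
    starts = [0.0]
    while starts[-1] + stride + size <= extent + eps:
        starts.append(starts[-1] + stride)
    last = extent - size
    if last > starts[-1] + eps:
        starts.append(last)
    return starts


def make_roi_grid(
    grid: VoxelGrid,
    roi_size_mm: Tuple[float, float] = (2.5, 2.5),
    overlap_frac: float = 0.3,
) -> RoiGrid:
    """Lay out overlapping ROIs covering the full en-face extent.

    ``roi_size_mm`` is the en-face (y, x) ROI size; the depth span of
    every ROI is the full depth of ``grid`` (the pipeline applies this to
    the already-isolated 0.3 mm depth window).  Stride between ROI
    origins is ``size * (1 - overlap_frac)``.
    """
    if not (0 <= overlap_frac < 1):
        raise ValueError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    ext = grid.extent_mm
    sy, sx = float(roi_size_mm[0]), float(roi_size_mm[1])
    if sy > ext[1] + 1e-9 or sx > ext[2] + 1e-9:
        raise ValueError(
            f"ROI size {roi_size_mm} mm exceeds en-face extent {(ext[1], ext[2])} mm"
        )
    sy, sx = min(sy, ext[1]), min(sx, ext[2])
    ys = _axis_starts(ext[1], sy, sy * (1 - overlap_frac))
    xs = _axis_starts(ext[2], sx, sx * (1 - overlap_frac))
    dz = ext[0]
    rois = [
        RoiBox(origin_mm=(0.0, y, x), size_mm=(dz, sy, sx)) for y in ys for x in xs
    ]
    return RoiGrid(rois=rois, roi_size_mm=(dz, sy, sx), overlap_frac=overlap_frac, grid=grid)


def compute_roi_table(
    graph: SkeletonGraph,
    skel: SkeletonMask,
    radii: RadiusMap,
    roigrid: RoiGrid,
    smooth_window: int = 3,
    angle_floor: float = 1e-6,
) -> List[VascularParams]:
    """All seven parameters for every ROI of the grid, in grid order."""
    return [
        roi_params(
            graph, skel, radii, roi, smooth_window=smooth_window, angle_floor=angle_floor
        )
        for roi in roigrid.rois
    ]


def compute_heatmap(
    graph: SkeletonGraph,
    skel: SkeletonMask,
    radii: RadiusMap,
    roigrid: RoiGrid,
    parameter: str,
    vessel: Optional[VesselMask] = None,
    roi_table: Optional[List[VascularParams]] = None,
) -> Tuple[HeatMap2D, HeatVolume, Optional[HeatVolume]]:
    """En-face heat map of one parameter, plus painted heat volumes.

    Returns the 2D map (overlap-averaged), the value painted onto
    skeleton voxels, and — when a vessel mask is supplied — onto vessel
    voxels.  ROIs whose parameter is undefined contribute nothing to the
    average.
    """
    if parameter not in PARAMETER_NAMES:
        raise ValueError(f"unknown parameter {parameter!r}; expected one of {PARAMETER_NAMES}")
    if roi_table is None:
        roi_table = compute_roi_table(graph, skel, radii, roigrid)
    ny, nx = skel.grid.shape[1], skel.grid.shape[2]
    acc = np.zeros((ny, nx), dtype=np.float64)
    cnt = np.zeros((ny, nx), dtype=np.int64)
    attr = "MR" if parameter == "MR" else parameter
    for roi, params in zip(roigrid.rois, roi_table):
        value = getattr(params, attr)
        if value is None:
            continue
        _, _, y0, y1, x0, x1 = roi.voxel_bounds(skel.grid)
        acc[y0:y1, x0:x1] += float(value)
        cnt[y0:y1, x0:x1] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    hm = HeatMap2D(values=values, coverage=cnt, parameter=parameter)

    skel_vol = np.zeros(skel.grid.shape, dtype=np.float64)
    sk = skel.data.astype(bool)
    painted = np.where(np.isnan(values), 0.0, values)
    skel_vol[sk] = np.broadcast_to(painted, skel.grid.shape)[sk]
    hv_skel = HeatVolume(values=skel_vol, support=sk.astype(np.uint8), parameter=parameter)

    hv_vessel = None
    if vessel is not None:
        ves_vol = np.zeros(vessel.grid.shape, dtype=np.float64)
        vm = vessel.data.astype(bool)
        ves_vol[vm] = np.broadcast_to(painted, vessel.grid.shape)[vm]
        hv_vessel = HeatVolume(values=ves_vol, support=vm.astype(np.uint8), parameter=parameter)
    return hm, hv_skel, hv_vessel


def normalize_for_display(hm: HeatMap2D) -> HeatMap2D:
    """Divide by the map maximum (display only; detection thresholds are
    relative, so masks are identical before and after normalization)."""
    finite = np.isfinite(hm.values)
    if not finite.any():
        raise ValueError("heat map has no defined values")
    vmax = np.nanmax(hm.values)
    values = hm.values / vmax if vmax != 0 else np.where(finite, 1.0, np.nan)
    return HeatMap2D(values=values, coverage=hm.coverage.copy(), parameter=hm.parameter)


def roi_table_to_csv(roigrid: RoiGrid, roi_table: List[VascularParams], path) -> None:
    import pandas as pd

    rows = []
    for i, (roi, p) in enumerate(zip(roigrid.rois, roi_table)):
        row = {"roi": i, "origin_z_mm": roi.origin_mm[0], "origin_y_mm": roi.origin_mm[1],
               "origin_x_mm": roi.origin_mm[2]}
        row.update(p.as_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
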