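"""Rule-based lesion presence check, subtype discrimination, and area extraction.

The vascular-density (VD) heat map drives everything:

1. *Presence*: the standard deviation of VD values over the painted
   skeleton voxels is compared against a minimum limit (no lesion means
   an even density distribution, hence a small SD).
2. *Subtype*: threshold the map at 75% of its maximum.  A superficial
   lesion is vessel-rich, so a single high-density component survives;
   a nodular lesion is vessel-poor, so the high-density threshold yields
   several scattered components instead.
3. *Area*: superficial — keep the largest component above the 75%
   threshold; nodular — iteratively select the low-density pixels below
   a threshold starting 20% above the nonzero minimum, raising it by 30%
   per step until exactly one component remains.  Either mask is then
   enlarged and smoothed by morphological closing + dilation with a disk
   structuring element.
4. *Reporting ROIs*: the lesion ROI is centred on the VD extremum inside
   the lesion mask (maximum for superficial, minimum for nodular); the
   healthy ROI is the grid ROI disjoint from the lesion mask whose
   centre is furthest from any lesion pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .config import DetectionConfig, PipelineConfig
from .heatmap_mapping import (
    HeatMap2D,
    HeatVolume,
    RoiGrid,
    compute_heatmap,
    compute_roi_table,
    make_roi_grid,
)
from .preprocess import frangi_vesselness, median3d, select_depth_window
from .skeletonization import RadiusMap, SkeletonGraph, build_graph, estimate_radii, skeletonize
from .vascular_metrics import RoiBox, VascularParams, roi_params
from .vessel_segmentation import VesselMask, segment_vessels
from .volume_io import OctaVolume

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity for en-face masks


@dataclass
class LesionResult:
    present: bool
    subtype: str  # "sBCC" | "nBCC" | "none"
    vd_std: float
    lesion_mask: Optional[np.ndarray] = None
    lesion_roi: Optional[RoiBox] = None
    healthy_roi: Optional[RoiBox] = None
    lesion_params: Optional[VascularParams] = None
    healthy_params: Optional[VascularParams] = None
    centroid_mm: Optional[Tuple[float, float]] = None
    thresholds: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        out = {
            "present": bool(self.present),
            "subtype": self.subtype,
            "vd_std": float(self.vd_std),
            "thresholds": self.thresholds,
        }
        if self.centroid_mm is not None:
            out["lesion_centroid_mm"] = [float(v) for v in self.centroid_mm]
        if self.lesion_roi is not None:
            out["lesion_roi_mm"] = {
                "origin": list(self.lesion_roi.origin_mm),
                "size": list(self.lesion_roi.size_mm),
            }
        if self.healthy_roi is not None:
            out["healthy_roi_mm"] = {
                "origin": list(self.healthy_roi.origin_mm),
                "size": list(self.healthy_roi.size_mm),
            }
        if self.lesion_params is not None:
            out["lesion_params"] = self.lesion_params.as_dict()
        if self.healthy_params is not None:
            out["healthy_params"] = self.healthy_params.as_dict()
        if self.lesion_mask is not None:
            out["lesion_area_px"] = int(self.lesion_mask.sum())
        return out


def lesion_present(
    vd_heat_skel: HeatVolume, cfg: DetectionConfig
) -> Tuple[bool, float]:
    """SD of VD values over skeleton voxels vs. the minimum-SD limit."""
    vals = vd_heat_skel.support_values()
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("heat volume needs at least 2 skeleton voxels")
    vd_std = float(np.std(vals))
    return vd_std >= cfg.vd_std_lim, vd_std


def _significant_components(sel: np.ndarray, min_px: int):
    """Label 8-connected components, dropping those below ``min_px``."""
    labels, n = ndimage.label(sel, structure=_STRUCT8)
    if n == 0:
        return labels, 0, np.array([], dtype=np.int64)
    counts = np.bincount(labels.ravel())[1:]
    keep = np.nonzero(counts >= min_px)[0] + 1
    return labels, len(keep), keep


def classify_subtype(vd_map: HeatMap2D, cfg: DetectionConfig) -> str:
    """One significant component above 75% of the maximum -> sBCC; more -> nBCC."""
    vmax = np.nanmax(vd_map.values)
    sel = np.nan_to_num(vd_map.values, nan=-np.inf) >= cfg.sbcc_thr_frac * vmax
    _, n, _ = _significant_components(sel, cfg.min_component_px)
    if n == 0:
        raise ValueError("no significant component above the subtype threshold")
    return "sBCC" if n == 1 else "nBCC"


def detect_sbcc_area(vd_map: HeatMap2D, cfg: DetectionConfig) -> np.ndarray:
    """Threshold at 75% of max, keep the largest component, refine."""
    vmax = np.nanmax(vd_map.values)
    sel = np.nan_to_num(vd_map.values, nan=-np.inf) >= cfg.sbcc_thr_frac * vmax
    if not sel.any():
        raise ValueError("empty mask at the superficial-lesion threshold")
    labels, _, keep = _significant_components(sel, 1)
    counts = np.bincount(labels.ravel())
    # largest component; ties broken by smallest centroid in lexicographic order
    best, best_key = None, None
    for lab in keep:
        area = counts[lab]
        cy, cx = np.argwhere(labels == lab).mean(axis=0)
        key = (-area, cy, cx)
        if best_key is None or key < best_key:
            best, best_key = lab, key
    mask = labels == best
    if mask.all():
        logger.warning("constant heat map: whole footprint selected as lesion")
    return refine_mask(mask, cfg)


def detect_nbcc_area(
    vd_map: HeatMap2D, cfg: DetectionConfig
) -> Tuple[np.ndarray, List[float]]:
    """Iterative low-density thresholding for nodular lesions.

    Selects pixels with ``0 < value <= thr``; ``thr`` starts 20% above
    the nonzero map minimum and is raised by 30% per iteration while two
    or more significant components remain.  Returns the refined mask and
    the threshold trace; raises if no single-component threshold exists
    before ``thr`` exceeds the map maximum.
    """
    vals = np.nan_to_num(vd_map.values, nan=0.0)
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("heat map has no positive values")
    vmax = float(pos.max())
    thr = (1.0 + cfg.nbcc_init_frac) * float(pos.min())
    trace: List[float] = []
    while True:
        trace.append(thr)
        sel = (vals > 0) & (vals <= thr)
        labels, n, keep = _significant_components(sel, cfg.min_component_px)
        if n == 1:
            mask = np.isin(labels, keep)
            return refine_mask(mask, cfg), trace
        if thr > vmax:
            raise ValueError(
                f"nodular-lesion threshold never converged to one component; trace={trace}"
            )
        thr *= 1.0 + cfg.nbcc_step_frac


def refine_mask(mask: np.ndarray, cfg: DetectionConfig) -> np.ndarray:
    """Enlarge and smooth: morphological closing then dilation with a disk."""
    from skimage.morphology import closing, dilation, disk

    if not mask.any():
        raise ValueError("cannot refine an empty mask")
    se = disk(cfg.disk_radius_px)
    out = closing(mask.astype(bool), se)
    out = dilation(out, se)
    return out


def mask_centroid_mm(
    mask: np.ndarray, grid, weights: Optional[np.ndarray] = None
) -> Tuple[float, float]:
    """Centroid of an en-face mask in mm; optionally weighted.

    With weights (e.g. the VD excess over the detection threshold) the
    centroid tracks the density anomaly itself instead of the blocky
    ROI-averaged plateau around it.
    """
    idx = np.argwhere(mask)
    if weights is not None:
        w = weights[mask.astype(bool)]
        w = np.clip(w, 0.0, None)
        if w.sum() > 0:
            cy, cx = (idx * w[:, None]).sum(axis=0) / w.sum()
        else:
            cy, cx = idx.mean(axis=0)
    else:
        cy, cx = idx.mean(axis=0)
    return ((cy + 0.5) * grid.spacing[1], (cx + 0.5) * grid.spacing[2])


def place_lesion_roi(
    vd_map: HeatMap2D,
    lesion_mask: np.ndarray,
    cfg: DetectionConfig,
    grid,
    subtype: str = "sBCC",
    depth_span_mm: Optional[float] = None,
) -> RoiBox:
    """ROI centred on the VD extremum inside the lesion mask, clamped inside.

    The extremum is the map maximum for superficial lesions and the
    nonzero minimum for nodular ones (with ``cfg.literal_global_max`` the
    global maximum is used regardless).
    """
    if not lesion_mask.any():
        raise ValueError("lesion mask is empty")
    vals = np.nan_to_num(vd_map.values, nan=0.0)
    if cfg.literal_global_max:
        iy, ix = np.unravel_index(np.argmax(vals), vals.shape)
    elif subtype == "nBCC":
        inside = np.where(lesion_mask & (vals > 0), vals, np.inf)
        if not np.isfinite(inside).any():
            inside = np.where(lesion_mask, vals, np.inf)
        iy, ix = np.unravel_index(np.argmin(inside), vals.shape)
    else:
        inside = np.where(lesion_mask, vals, -np.inf)
        iy, ix = np.unravel_index(np.argmax(inside), vals.shape)
    cy = (iy + 0.5) * grid.spacing[1]
    cx = (ix + 0.5) * grid.spacing[2]
    dz_mm, dy_mm, dx_mm = cfg.roi_size_mm
    if depth_span_mm is None:
        depth_span_mm = grid.extent_mm[0]
    dz_mm = min(dz_mm, depth_span_mm)
    ext = grid.extent_mm
    oy = min(max(cy - dy_mm / 2, 0.0), max(ext[1] - dy_mm, 0.0))
    ox = min(max(cx - dx_mm / 2, 0.0), max(ext[2] - dx_mm, 0.0))
    return RoiBox(origin_mm=(0.0, oy, ox), size_mm=(dz_mm, min(dy_mm, ext[1]), min(dx_mm, ext[2])))


def place_healthy_roi(roigrid: RoiGrid, lesion_mask: np.ndarray) -> RoiBox:
    """Grid ROI disjoint from the lesion whose centre is furthest from it."""
    grid = roigrid.grid
    # distance (mm) from every pixel to the nearest lesion pixel
    dist = ndimage.distance_transform_edt(
        ~lesion_mask.astype(bool), sampling=(grid.spacing[1], grid.spacing[2])
    )
    best, best_key = None, None
    for i, roi in enumerate(roigrid.rois):
        _, _, y0, y1, x0, x1 = roi.voxel_bounds(grid)
        if lesion_mask[y0:y1, x0:x1].any():
            continue
        cy = min(max(int((y0 + y1) // 2), 0), grid.shape[1] - 1)
        cx = min(max(int((x0 + x1) // 2), 0), grid.shape[2] - 1)
        key = (-dist[cy, cx], i)
        if best_key is None or key < best_key:
            best, best_key = roi, key
    if best is None:
        raise ValueError("every grid ROI intersects the lesion mask")
    return best


def run_pipeline(
    vol: OctaVolume, config: Optional[PipelineConfig] = None, artifacts: Optional[dict] = None
) -> LesionResult:
    """Execute the full chain from raw OCTA volume to lesion report.

    ``artifacts``, when given a dict, receives the intermediate products
    (cropped volume, vessel mask, skeleton, graph, ROI grid, VD heat
    map/volumes, ROI table) keyed by stage name.
    """
    cfg = config or PipelineConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # annotate failures with the stage name
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        logger.info("stage %s done", name)
        if artifacts is not None:
            artifacts[name] = out
        return out

    window = stage("depth_window", select_depth_window, vol, cfg.preprocess.window_mm)
    den = stage("median", median3d, window, cfg.preprocess.median_kernel)
    ves = stage("frangi", frangi_vesselness, den, cfg.preprocess.frangi())
    mask = stage(
        "segmentation",
        segment_vessels,
        ves,
        cfg.segmentation.window_frac,
        cfg.segmentation.sensitivity,
        cfg.segmentation.min_object_vox,
        cfg.segmentation.slice_axis,
        cfg.segmentation.min_intensity_frac,
    )
    skel = stage("skeleton", skeletonize, mask)
    radii = stage("radii", estimate_radii, mask, skel)
    graph = stage("graph", build_graph, skel, radii, cfg.skeleton.prune_spur_vox)
    roigrid = stage(
        "roi_grid", make_roi_grid, skel.grid, cfg.heatmap.roi_size_mm, cfg.heatmap.overlap_frac
    )
    roi_table = stage(
        "roi_table",
        compute_roi_table,
        graph,
        skel,
        radii,
        roigrid,
        cfg.metrics.smooth_window,
        cfg.metrics.angle_floor,
    )
    vd_map, vd_skel, vd_vessel = stage(
        "vd_heatmap",
        compute_heatmap,
        graph,
        skel,
        radii,
        roigrid,
        "VD",
        mask,
        roi_table,
    )

    present, vd_std = stage("presence", lesion_present, vd_skel, cfg.detection)
    logger.info("vd_std=%.3g (limit %.3g) -> present=%s", vd_std, cfg.detection.vd_std_lim, present)
    if not present:
        return LesionResult(present=False, subtype="none", vd_std=vd_std)

    subtype = stage("subtype", classify_subtype, vd_map, cfg.detection)
    thresholds = {"vd_std": vd_std, "vd_std_lim": cfg.detection.vd_std_lim}
    vals = np.nan_to_num(vd_map.values, nan=0.0)
    if subtype == "sBCC":
        lesion_mask = stage("sbcc_area", detect_sbcc_area, vd_map, cfg.detection)
        thr = float(cfg.detection.sbcc_thr_frac * np.nanmax(vd_map.values))
        thresholds["sbcc_thr"] = thr
        centroid_w = vals - thr
    else:
        lesion_mask, trace = stage("nbcc_area", detect_nbcc_area, vd_map, cfg.detection)
        thresholds["nbcc_trace"] = [float(t) for t in trace]
        centroid_w = trace[-1] - vals

    lesion_roi = stage(
        "lesion_roi",
        place_lesion_roi,
        vd_map,
        lesion_mask,
        cfg.detection,
        skel.grid,
        subtype,
        skel.grid.extent_mm[0],
    )
    healthy_roi = stage("healthy_roi", place_healthy_roi, roigrid, lesion_mask)
    kw = dict(
        min_branch_points=cfg.metrics.min_branch_points,
        smooth_window=cfg.metrics.smooth_window,
        angle_floor=cfg.metrics.angle_floor,
    )
    lesion_params = stage("lesion_params", roi_params, graph, skel, radii, lesion_roi, **kw)
    healthy_params = stage("healthy_params", roi_params, graph, skel, radii, healthy_roi, **kw)

    return LesionResult(
        present=True,
        subtype=subtype,
        vd_std=vd_std,
        lesion_mask=lesion_mask,
        lesion_roi=lesion_roi,
        healthy_roi=healthy_roi,
        lesion_params=lesion_params,
        healthy_params=healthy_params,
        centroid_mm=mask_centroid_mm(lesion_mask, skel.grid, weights=centroid_w),
        thresholds=thresholds,
    )
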