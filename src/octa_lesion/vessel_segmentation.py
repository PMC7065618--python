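"""Binary vessel segmentation by fast adaptive (local-mean) thresholding.

A pixel is vessel iff its value exceeds ``(1 - sensitivity)`` times the
mean over a square window centred on it, with border windows clipped to
the slice.  The local mean is computed with an integral image, so the
cost is O(1) per pixel regardless of window size.  Thresholding runs
slice by slice (en-face slices by default) and the binary slices are
stacked back into a 3D mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .volume_io import OctaVolume, VoxelGrid, mm_to_vox


@dataclass
class VesselMask:
    """Binary vessel volume (values in {0, 1}) with voxel geometry."""

    data: np.ndarray
    grid: VoxelGrid
    depth_offset_mm: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if tuple(self.data.shape) != self.grid.shape:
            raise ValueError(
                f"mask shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.data = self.data.astype(np.uint8)


def _clipped_window_mean(slice2d: np.ndarray, side: int) -> np.ndarray:
    """Mean over a side x side window centred per pixel, clipped at borders."""
    a = np.asarray(slice2d, dtype=np.float64)
    if side <= 1:
        return a.copy()  # 1x1 window: the mean is the pixel itself, exactly
    h, w = a.shape
    # integral image with a leading zero row/column
    ii = np.zeros((h + 1, w + 1), dtype=np.float64)
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=ii[1:, 1:])
    lo = (side - 1) // 2
    hi = side // 2
    rows = np.arange(h)
    cols = np.arange(w)
    r0 = np.clip(rows - lo, 0, h)
    r1 = np.clip(rows + hi + 1, 0, h)
    c0 = np.clip(cols - lo, 0, w)
    c1 = np.clip(cols + hi + 1, 0, w)
    sums = ii[np.ix_(r1, c1)] - ii[np.ix_(r0, c1)] - ii[np.ix_(r1, c0)] + ii[np.ix_(r0, c0)]
    counts = (r1 - r0)[:, None] * (c1 - c0)[None, :]
    return sums / counts


def adaptive_threshold_slice(
    slice2d: np.ndarray,
    window_frac: float = 1.0 / 8.0,
    sensitivity: float = 0.15,
    floor: float = 0.0,
) -> np.ndarray:
    """Local-mean threshold of one 2D slice.

    The window side is ``round(window_frac * slice width)`` pixels
    (width = number of columns).  A pixel is vessel iff its value
    exceeds both ``(1 - sensitivity)`` times the local mean and the
    absolute ``floor`` (0 disables the floor; a relative local-mean
    test alone marks arbitrary noise in windows containing no signal).
    Returns a uint8 map in {0, 1}.
    """
    a = np.asarray(slice2d)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError(f"slice must be 2D with >= 2 pixels per axis, got {a.shape}")
    if not (0 < window_frac <= 1):
        raise ValueError(f"window_frac must be in (0, 1], got {window_frac}")
    if not (0 <= sensitivity < 1):
        raise ValueError(f"sensitivity must be in [0, 1), got {sensitivity}")
    side = max(1, mm_to_vox(window_frac * a.shape[1], 1.0))
    mean = _clipped_window_mean(a, side)
    return ((a > (1.0 - sensitivity) * mean) & (a > floor)).astype(np.uint8)


def remove_small_objects_3d(mask: np.ndarray, min_vox: int) -> np.ndarray:
    """Drop 26-connected components with fewer than ``min_vox`` voxels."""
    from scipy import ndimage

    if min_vox <= 1:
        return mask.astype(np.uint8)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return mask.astype(np.uint8)
    counts = np.bincount(labels.ravel())
    keep = counts >= min_vox
    keep[0] = False
    return keep[labels].astype(np.uint8)


def segment_vessels(
    vol: OctaVolume,
    window_frac: float = 1.0 / 8.0,
    sensitivity: float = 0.15,
    min_object_vox: int = 27,
    slice_axis: int = 0,
    min_intensity_frac: float = 0.05,
) -> VesselMask:
    """Segment vessels slice by slice and stack into a 3D binary mask.

    ``slice_axis`` selects the slicing orientation: 0 thresholds en-face
    (constant-depth) slices, 1 thresholds B-scan slices.  Components
    smaller than ``min_object_vox`` voxels (26-connectivity) are removed;
    pass 0 to disable.  ``min_intensity_frac`` sets an absolute floor of
    that fraction of the volume maximum under the local-mean test, so
    that signal-free windows do not binarize their noise; 0 disables.
    """
    if slice_axis not in (0, 1, 2):
        raise ValueError(f"slice_axis must be 0, 1 or 2, got {slice_axis}")
    floor = float(min_intensity_frac) * float(vol.data.max()) if vol.data.size else 0.0
    data = np.moveaxis(vol.data, slice_axis, 0)
    out = np.empty(data.shape, dtype=np.uint8)
    for i in range(data.shape[0]):
        out[i] = adaptive_threshold_slice(data[i], window_frac, sensitivity, floor=floor)
    out = np.moveaxis(out, 0, slice_axis)
    out = remove_small_objects_3d(out, int(min_object_vox))
    return VesselMask(data=out, grid=vol.grid, depth_offset_mm=vol.depth_offset_mm)
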