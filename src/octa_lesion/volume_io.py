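"""Volume input/output, voxel-grid geometry, and en-face renderings.

All volumes are indexed ``(z, y, x)`` with ``z`` the depth axis
(increasing downward into the skin), ``y`` the slow scan direction and
``x`` the fast scan direction.  Physical sizes are millimetres
throughout; conversion from millimetres to voxel indices uses
round-half-up (see :func:`mm_to_vox`).

Supported on-disk formats:

* multi-page TIFF stacks (one page per z-slice) with an optional JSON
  sidecar ``<file>.json`` holding ``spacing_mm``;
* NIfTI-1 volumes (spacing read from the header zooms);
* raw little-endian binary with a mandatory JSON sidecar
  ``{"shape": [nz, ny, nx], "spacing_mm": [dz, dy, dx], "dtype": ...}``.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

logger = logging.getLogger(__name__)

#: Voxel spacing (dz, dy, dx) in mm of the native acquisition geometry:
#: 410 px over 1.35 mm depth, 512 B-scans over 9.57 mm, 490 A-lines over 10 mm.
DEFAULT_SPACING_MM: Tuple[float, float, float] = (1.35 / 410, 9.57 / 512, 10.0 / 490)


def mm_to_vox(mm: float, spacing: float) -> int:
    """Convert a physical length/coordinate to a voxel count/index, round-half-up."""
    return int(math.floor(mm / spacing + 0.5))


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a voxel lattice: counts per axis and mm spacing per axis."""

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ValueError("shape and spacing must have 3 components")
        if any(int(n) < 1 for n in self.shape):
            raise ValueError(f"all shape components must be >= 1, got {self.shape}")
        if any(not (s > 0) for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def extent_mm(self) -> Tuple[float, float, float]:
        """Physical extent (shape * spacing) per axis in mm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def to_index(self, mm: float, axis: int) -> int:
        return mm_to_vox(mm, self.spacing[axis])

    def n_voxels(self, mm: float, axis: int) -> int:
        return mm_to_vox(mm, self.spacing[axis])


@dataclass
class OctaVolume:
    """A 3D non-negative OCTA scalar field with attached voxel geometry.

    ``depth_offset_mm`` records how deep slice ``z = 0`` of this volume
    sits below the top of the originally acquired volume, so that depth
    windows cropped out of a parent volume keep absolute depth
    coordinates.
    """

    data: np.ndarray
    grid: VoxelGrid
    depth_offset_mm: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if tuple(self.data.shape) != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.data.size and self.data.min() < 0:
            raise ValueError("volume contains negative values")

    def slice_depth_mm(self, z: int) -> float:
        """Absolute depth (mm) of slice ``z`` below the original volume top."""
        return self.depth_offset_mm + z * self.grid.spacing[0]


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def _read_sidecar(path: Path) -> Optional[dict]:
    sc = _sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            return json.load(fh)
    return None


def read_volume(
    path: os.PathLike | str,
    format: Optional[str] = None,
    metadata: Optional[VoxelGrid] = None,
    as_mask: bool = False,
) -> OctaVolume:
    """Read a volume from disk and normalize it to ``(z, y, x)`` order.

    Parameters
    ----------
    path:
        File to read.
    format:
        One of ``{"tiff", "nifti", "raw"}``; inferred from the file
        suffix when omitted.
    metadata:
        Explicit geometry.  Mandatory for ``raw`` files without a JSON
        sidecar; overrides sidecar/header spacing when given.
    as_mask:
        Interpret on-disk values as a binary mask (nonzero -> 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    if format is None:
        suffix = path.suffix.lower()
        if suffix in (".tif", ".tiff"):
            format = "tiff"
        elif suffix in (".nii",) or str(path).lower().endswith(".nii.gz"):
            format = "nifti"
        else:
            format = "raw"

    depth_offset = 0.0
    if format == "tiff":
        import tifffile

        data = np.asarray(tifffile.imread(path))
        if data.ndim == 2:
            data = data[None]
        sidecar = _read_sidecar(path)
        if metadata is not None:
            spacing = metadata.spacing
        elif sidecar is not None and "spacing_mm" in sidecar:
            spacing = tuple(sidecar["spacing_mm"])
        else:
            logger.warning(
                "no spacing metadata for %s; assuming native acquisition spacing %s mm",
                path,
                DEFAULT_SPACING_MM,
            )
            spacing = DEFAULT_SPACING_MM
        if sidecar is not None:
            depth_offset = float(sidecar.get("depth_offset_mm", 0.0))
    elif format == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        # NIfTI stores (x, y, z); transpose to (z, y, x).
        data = np.asarray(img.dataobj).transpose(2, 1, 0)
        zooms = img.header.get_zooms()[:3]
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        if metadata is not None:
            spacing = metadata.spacing
    elif format == "raw":
        sidecar = _read_sidecar(path)
        if metadata is None and sidecar is None:
            raise ValueError("raw volumes require a JSON sidecar or explicit metadata")
        if sidecar is not None:
            shape = tuple(sidecar["shape"])
            spacing = tuple(sidecar["spacing_mm"])
            dtype = np.dtype(sidecar.get("dtype", "float32"))
            depth_offset = float(sidecar.get("depth_offset_mm", 0.0))
        else:
            shape, spacing, dtype = metadata.shape, metadata.spacing, np.dtype("float32")
        if metadata is not None:
            shape, spacing = metadata.shape, metadata.spacing
        raw = np.fromfile(path, dtype=dtype.newbyteorder("<"))
        expected = int(np.prod(shape))
        if raw.size != expected:
            raise ValueError(
                f"raw file holds {raw.size} elements but shape {shape} needs {expected}"
            )
        data = raw.reshape(shape)
    else:
        raise ValueError(f"unknown volume format: {format!r}")

    grid = VoxelGrid(tuple(data.shape), tuple(spacing))
    if metadata is not None and tuple(metadata.shape) != tuple(data.shape):
        raise ValueError(
            f"metadata shape {metadata.shape} does not match file shape {data.shape}"
        )
    if as_mask:
        data = (data != 0).astype(np.uint8)
    return OctaVolume(data=data, grid=grid, depth_offset_mm=depth_offset)


def write_volume(vol, path: os.PathLike | str, format: Optional[str] = None) -> None:
    """Write a volume or binary mask to disk, re-readable by :func:`read_volume`.

    Binary masks (any object whose ``data`` dtype is bool or uint8 with
    values in {0, 1}) are stored as 8-bit TIFF/raw with values
    ``{0, 255}``; ``read_volume(..., as_mask=True)`` restores ``{0, 1}``.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    if format is None:
        suffix = path.suffix.lower()
        if suffix in (".tif", ".tiff"):
            format = "tiff"
        elif suffix == ".nii" or str(path).lower().endswith(".nii.gz"):
            format = "nifti"
        else:
            format = "raw"

    data = np.asarray(vol.data)
    grid = vol.grid
    depth_offset = float(getattr(vol, "depth_offset_mm", 0.0))
    is_mask = data.dtype == bool or (
        data.dtype == np.uint8 and data.size and data.max(initial=0) <= 1
    )
    out = (data.astype(np.uint8) * 255) if is_mask else data

    sidecar = {
        "shape": list(grid.shape),
        "spacing_mm": list(grid.spacing),
        "dtype": str(out.dtype),
        "depth_offset_mm": depth_offset,
        "binary_mask": bool(is_mask),
    }
    if format == "tiff":
        import tifffile

        tifffile.imwrite(path, out, photometric="minisblack")
        with open(_sidecar_path(path), "w") as fh:
            json.dump(sidecar, fh, indent=1)
    elif format == "nifti":
        import nibabel as nib

        dz, dy, dx = grid.spacing
        img = nib.Nifti1Image(out.transpose(2, 1, 0), affine=np.diag([dx, dy, dz, 1.0]))
        img.header.set_zooms((dx, dy, dz))
        nib.save(img, str(path))
    elif format == "raw":
        out.astype(out.dtype.newbyteorder("<")).tofile(path)
        with open(_sidecar_path(path), "w") as fh:
            json.dump(sidecar, fh, indent=1)
    else:
        raise ValueError(f"unknown volume format: {format!r}")


def _depth_slice_range(vol: OctaVolume, depth_range_mm: Tuple[float, float]) -> np.ndarray:
    lo, hi = depth_range_mm
    if not lo < hi:
        raise ValueError(f"empty depth range: {depth_range_mm}")
    depths = vol.depth_offset_mm + np.arange(vol.grid.shape[0]) * vol.grid.spacing[0]
    idx = np.nonzero((depths >= lo) & (depths < hi))[0]
    if idx.size == 0:
        raise ValueError(f"depth range {depth_range_mm} mm selects no slice")
    return idx


def mip_enface(vol: OctaVolume, depth_range_mm: Optional[Tuple[float, float]] = None) -> np.ndarray:
    """Maximum-intensity projection along depth over ``[lo, hi)`` mm.

    ``depth_range_mm`` defaults to the full depth extent.  Depths are
    absolute (include ``depth_offset_mm``).
    """
    if depth_range_mm is None:
        depth_range_mm = (
            vol.depth_offset_mm,
            vol.depth_offset_mm + vol.grid.extent_mm[0] + 1e-12,
        )
    idx = _depth_slice_range(vol, depth_range_mm)
    return vol.data[idx].max(axis=0)


def depth_color_enface(
    vol: OctaVolume,
    depth_range_mm: Optional[Tuple[float, float]] = None,
    cmap_name: str = "turbo",
) -> np.ndarray:
    """Depth-coded en-face rendering as an RGB float array in [0, 1].

    Hue encodes the depth of the per-column maximal voxel — mapped
    linearly from the start of the fixed colormap (``turbo``) at the
    shallow end of the range to its end at the deep end — and brightness
    encodes that voxel's intensity relative to the image maximum.
    """
    from matplotlib import colormaps

    if depth_range_mm is None:
        depth_range_mm = (
            vol.depth_offset_mm,
            vol.depth_offset_mm + vol.grid.extent_mm[0] + 1e-12,
        )
    idx = _depth_slice_range(vol, depth_range_mm)
    sub = vol.data[idx].astype(np.float64)
    argmax = sub.argmax(axis=0)
    peak = sub.max(axis=0)
    if idx.size > 1:
        frac = argmax / (idx.size - 1)
    else:
        frac = np.zeros_like(argmax, dtype=np.float64)
    cmap = colormaps[cmap_name]
    rgb = np.asarray(cmap(frac))[..., :3]
    vmax = peak.max()
    scale = peak / vmax if vmax > 0 else np.zeros_like(peak)
    return rgb * scale[..., None]


def save_enface_png(image: np.ndarray, path: os.PathLike | str) -> None:
    """Write a 2D grayscale or RGB float image as PNG."""
    import imageio.v3 as iio

    arr = np.asarray(image, dtype=np.float64)
    vmax = arr.max() if arr.size else 0.0
    if vmax > 0:
        arr = arr / vmax
    iio.imwrite(Path(path), (arr * 255).astype(np.uint8))
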