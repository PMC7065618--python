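"""Seeded synthetic OCTA-like volumes with known vessel and lesion ground truth.

Phantoms emulate layered skin vasculature on a depth-cropped analogue of
the native acquisition geometry: a quasi-regular bed of undulating
vessels spanning the full en-face extent, with kind-specific anomalies —
a high-density focus of extra fine vessels for a superficial lesion
(``sbcc``), or a vessel-poor core (with mildly hyperdense surrounding
patches, mimicking perilesional feeder vessels) for a nodular lesion
(``nbcc``).  Intensity is a soft tube profile with multiplicative
speckle and additive Gaussian noise.  All randomness flows from the
single seed, so regeneration is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .volume_io import OctaVolume, VoxelGrid

#: default phantom lattice: 96 x 256 x 256 voxels at (3.3, 31.25, 31.25) um —
#: native axial pitch, en-face pitch widened so an 8 mm field fits several
#: non-overlapping 2.5 mm analysis ROIs around an off-centre lesion, and
#: chosen so the 2.5 mm ROI, its 1.75 mm stride, and the 0.25 mm vessel
#: pitch are all integer numbers of pixels (keeps the healthy bed's
#: per-ROI density quantization noise low)
DEFAULT_PHANTOM_GRID = VoxelGrid((96, 256, 256), (0.0033, 0.03125, 0.03125))


@dataclass
class PhantomSpec:
    kind: str = "healthy"  # healthy | sbcc | nbcc | single_tube | tube_set
    grid: VoxelGrid = field(default_factory=lambda: DEFAULT_PHANTOM_GRID)
    background_vessel_spacing_mm: float = 0.25
    vessel_radius_range_mm: Tuple[float, float] = (0.034, 0.046)
    #: depth half-thickness of the rasterized flow signal; OCTA vessels are
    #: much thinner in depth than in-plane, and a near-isotropic voxel
    #: footprint keeps the thinning result a curve rather than a sheet
    vessel_z_radius_mm: float = 0.007
    lesion_vessel_z_radius_mm: float = 0.0045
    lesion_center_mm: Optional[Tuple[float, float]] = None  # (y, x); None = centre
    lesion_radius_mm: float = 1.0
    lesion_density_multiplier: Optional[float] = None  # None: 3.5 sbcc, 0.15 nbcc
    #: perilesional feeder patches of nodular phantoms
    hotspot_multiplier: float = 3.0
    hotspot_radius_mm: float = 1.0
    speckle_scale: float = 0.15
    gaussian_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("healthy", "sbcc", "nbcc", "single_tube", "tube_set"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.lesion_density_multiplier is None:
            self.lesion_density_multiplier = {"sbcc": 3.5, "nbcc": 0.15}.get(self.kind, 1.0)
        if self.lesion_density_multiplier <= 0:
            raise ValueError("lesion_density_multiplier must be > 0")
        if self.kind == "sbcc" and self.lesion_density_multiplier <= 1:
            raise ValueError("sbcc phantoms need lesion_density_multiplier > 1")
        if self.kind == "nbcc" and self.lesion_density_multiplier >= 1:
            raise ValueError("nbcc phantoms need lesion_density_multiplier < 1")
        ext = self.grid.extent_mm
        if self.lesion_center_mm is not None and self.kind in ("sbcc", "nbcc"):
            cy, cx = self.lesion_center_mm
            if not (0 < cy < ext[1] and 0 < cx < ext[2]):
                raise ValueError("lesion centre outside volume")


@dataclass
class PhantomTruth:
    kind: str
    vessel_mask: np.ndarray
    centerlines: List[np.ndarray]  # (n, 3) mm paths
    centerline_radii_mm: List[float]
    lesion_mask_2d: Optional[np.ndarray] = None
    lesion_centroid_mm: Optional[Tuple[float, float]] = None


# ----------------------------------------------------------------------
# analytic centreline paths

def make_path(kind: str, params: Optional[dict] = None, seed: int = 0) -> np.ndarray:
    """Sampled 3D centreline path (mm, (z, y, x) columns) of a given shape.

    Kinds and their defaults:

    * ``straight`` — ``start`` to ``end``, ``n`` samples. DM = 1, SOAM = 0.
    * ``sine`` — along +x starting at a crest (``y = amplitude *
      cos(2 pi x / wavelength)``), so each full period carries exactly two
      en-face inflections.
    * ``helix`` — axis along z; constant turning rate
      ``curvature = r / (r^2 + c^2)`` with ``c = pitch / (2 pi)``.
    * ``random_walk`` — smoothed seeded random walk.
    """
    p = dict(params or {})
    if kind == "straight":
        start = np.asarray(p.get("start", (0.0, 0.0, 0.0)), dtype=np.float64)
        end = np.asarray(p.get("end", (0.0, 0.0, 5.0)), dtype=np.float64)
        n = int(p.get("n", 50))
        if n < 2:
            raise ValueError("straight path needs n >= 2")
        t = np.linspace(0.0, 1.0, n)[:, None]
        return start[None, :] * (1 - t) + end[None, :] * t
    if kind == "sine":
        start = np.asarray(p.get("start", (0.0, 0.0, 0.0)), dtype=np.float64)
        amplitude = float(p.get("amplitude", 0.2))
        wavelength = float(p.get("wavelength", 1.0))
        length = float(p.get("length", wavelength))
        n = int(p.get("n", 100))
        x = np.linspace(0.0, length, n)
        y = amplitude * np.cos(2 * np.pi * x / wavelength)
        z = np.zeros_like(x)
        return start[None, :] + np.column_stack([z, y - amplitude, x])
    if kind == "helix":
        center = np.asarray(p.get("center", (0.0, 1.0, 1.0)), dtype=np.float64)
        radius = float(p.get("radius", 0.5))
        pitch = float(p.get("pitch", 1.0))
        turns = float(p.get("turns", 2.0))
        n = int(p.get("n", 500))
        if radius <= 0 or n < 3:
            raise ValueError("helix needs radius > 0 and n >= 3")
        theta = np.linspace(0.0, 2 * np.pi * turns, n)
        z = center[0] + pitch * theta / (2 * np.pi)
        y = center[1] + radius * np.sin(theta)
        x = center[2] + radius * np.cos(theta)
        return np.column_stack([z, y, x])
    if kind == "random_walk":
        start = np.asarray(p.get("start", (0.0, 0.0, 0.0)), dtype=np.float64)
        step = float(p.get("step", 0.05))
        n = int(p.get("n", 100))
        rng = np.random.default_rng(seed)
        steps = rng.normal(size=(n - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        pts = np.vstack([[0, 0, 0], np.cumsum(steps * step, axis=0)]) + start
        # light smoothing so the walk resembles a vessel, not white noise
        for _ in range(2):
            pts[1:-1] = 0.5 * pts[1:-1] + 0.25 * (pts[:-2] + pts[2:])
        return pts
    raise ValueError(f"unknown path kind {kind!r}")


def helix_turning_rate(radius: float, pitch: float) -> float:
    """Closed-form tangent turning rate (curvature) of a helix, rad/mm."""
    c = pitch / (2 * np.pi)
    return radius / (radius**2 + c**2)


# ----------------------------------------------------------------------
# rasterization

def rasterize_tube(
    path_mm: np.ndarray,
    radius_mm: float,
    grid: VoxelGrid,
    z_radius_mm: Optional[float] = None,
) -> np.ndarray:
    """Binary volume of voxels within ``radius_mm`` of the polyline.

    Distances are physical (anisotropic-aware).  ``z_radius_mm`` gives
    the tube an elliptical cross-section (flattened along depth), which
    mimics the thin depth extent of OCTA flow signal.  Raises if the
    path leaves the volume or the radius is below half the smallest
    spacing.
    """
    spacing = np.asarray(grid.spacing)
    if radius_mm < min(grid.spacing) / 2:
        raise ValueError(
            f"radius {radius_mm} mm is below half the minimum spacing {min(grid.spacing)} mm"
        )
    rz = radius_mm if z_radius_mm is None else float(z_radius_mm)
    path = np.asarray(path_mm, dtype=np.float64)
    ext = np.asarray(grid.extent_mm)
    if (path < -1e-9).any() or (path > ext[None, :] + 1e-9).any():
        raise ValueError("path exits the volume")

    # resample the polyline at <= half-min-spacing steps
    seglen = np.linalg.norm(np.diff(path, axis=0), axis=1)
    samples = [path[0]]
    step = min(grid.spacing) / 2
    for a, b, L in zip(path[:-1], path[1:], seglen):
        if L == 0:
            continue
        k = max(1, int(math.ceil(L / step)))
        t = np.linspace(0, 1, k + 1)[1:, None]
        samples.append(a[None, :] * (1 - t) + b[None, :] * t)
    centers = np.vstack([s if s.ndim == 2 else s[None, :] for s in samples])

    # precompute the anisotropic (possibly z-flattened) ball of voxel offsets
    semi = np.array([rz, radius_mm, radius_mm])
    nmax = np.maximum(1, np.ceil(semi / spacing).astype(int))
    oz, oy, ox = np.meshgrid(
        np.arange(-nmax[0], nmax[0] + 1),
        np.arange(-nmax[1], nmax[1] + 1),
        np.arange(-nmax[2], nmax[2] + 1),
        indexing="ij",
    )
    offs = np.column_stack([oz.ravel(), oy.ravel(), ox.ravel()])
    d2 = (((offs * spacing[None, :]) / semi[None, :]) ** 2).sum(axis=1)
    offs = offs[d2 <= 1.0 + 1e-12]

    vox_centers = np.floor(centers / spacing[None, :]).astype(np.int64)
    vol = np.zeros(grid.shape, dtype=np.uint8)
    idx = (vox_centers[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    ok = np.all((idx >= 0) & (idx < np.asarray(grid.shape)[None, :]), axis=1)
    idx = idx[ok]
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    return vol


# ----------------------------------------------------------------------
# full phantoms

def _bed_paths(spec: PhantomSpec, rng: np.random.Generator) -> List[np.ndarray]:
    """Quasi-regular bed of undulating vessels crossing the full extent."""
    ext = spec.grid.extent_mm
    zmid = ext[0] * 0.5
    spacing = spec.background_vessel_spacing_mm
    paths = []
    n_samp = 160
    # vessels along x at regular y offsets, and along y at regular x offsets;
    # the lattice spans the full extent so every ROI sees the same tube
    # count, and the undulation wavelength divides the 2.5 mm ROI evenly
    # so the in-ROI path length is independent of phase
    for axis in (1, 2):
        other = 2 if axis == 1 else 1
        n_vessels = int(ext[axis] / spacing) + 1
        for k in range(n_vessels):
            off = (k + 0.5) * spacing
            if off >= ext[axis]:
                continue
            run = np.linspace(0.0, ext[other] - 1e-6, n_samp)
            phase = rng.uniform(0, 2 * np.pi)
            wob = 0.25 * spacing * np.sin(2 * np.pi * run / 1.25 + phase)
            depth = zmid + 0.15 * ext[0] * np.sin(2 * np.pi * run / 1.25 + rng.uniform(0, 2 * np.pi))
            pts = np.empty((n_samp, 3))
            pts[:, 0] = np.clip(depth, 0.05 * ext[0], 0.95 * ext[0])
            pts[:, axis] = np.clip(off + wob, 0.0, ext[axis] - 1e-6)
            pts[:, other] = run
            paths.append(pts)
    return paths


def _lesion_disk(spec: PhantomSpec) -> Tuple[np.ndarray, Tuple[float, float]]:
    # default lesion centre is off-centre so that a healthy reference
    # region remains in the far part of the field
    ext = spec.grid.extent_mm
    center = spec.lesion_center_mm or (0.35 * ext[1], 0.35 * ext[2])
    yy = (np.arange(spec.grid.shape[1]) + 0.5) * spec.grid.spacing[1]
    xx = (np.arange(spec.grid.shape[2]) + 0.5) * spec.grid.spacing[2]
    dist2 = (yy[:, None] - center[0]) ** 2 + (xx[None, :] - center[1]) ** 2
    return dist2 <= spec.lesion_radius_mm**2, center


def _patch_paths(
    spec: PhantomSpec,
    rng: np.random.Generator,
    center: Tuple[float, float],
    radius_mm: float,
    multiplier: float,
) -> List[np.ndarray]:
    """Fine extra vessels confined to a disk, raising the local centreline
    density by ``multiplier`` over the background bed."""
    ext = spec.grid.extent_mm
    r = radius_mm
    base_len_per_area = 2.0 / spec.background_vessel_spacing_mm  # mm of vessel per mm^2
    extra = (multiplier - 1.0) * base_len_per_area * math.pi * r * r
    paths = []
    total = 0.0
    n_samp = 60
    while total < extra:
        ang = rng.uniform(0, 2 * np.pi)
        rad = r * math.sqrt(rng.uniform(0, 0.85))
        cy = center[0] + rad * math.sin(ang)
        cx = center[1] + rad * math.cos(ang)
        seg_len = min(0.8 * r, rng.uniform(0.4, 0.9))
        direction = rng.uniform(0, 2 * np.pi)
        run = np.linspace(-seg_len / 2, seg_len / 2, n_samp)
        wob = 0.05 * np.sin(2 * np.pi * run / 0.4 + rng.uniform(0, 2 * np.pi))
        y = cy + run * math.sin(direction) + wob * math.cos(direction)
        x = cx + run * math.cos(direction) - wob * math.sin(direction)
        # keep inside the patch disk and the volume
        keep = (y - center[0]) ** 2 + (x - center[1]) ** 2 <= (0.95 * r) ** 2
        keep &= (y > 0) & (y < ext[1]) & (x > 0) & (x < ext[2])
        if keep.sum() < 8:
            continue
        z = ext[0] * (0.5 + 0.15 * np.sin(2 * np.pi * run / 1.1 + rng.uniform(0, 2 * np.pi)))
        pts = np.column_stack([z[keep], y[keep], x[keep]])
        paths.append(pts)
        total += float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    return paths


def _extra_lesion_paths(
    spec: PhantomSpec, rng: np.random.Generator, center: Tuple[float, float]
) -> List[np.ndarray]:
    """Extra fine vessels of a superficial (vessel-rich) lesion."""
    return _patch_paths(
        spec, rng, center, spec.lesion_radius_mm, spec.lesion_density_multiplier
    )


def _hotspot_paths(
    spec: PhantomSpec, rng: np.random.Generator, center: Tuple[float, float]
) -> List[np.ndarray]:
    """Hyperdense feeder patches far from a nodular (vessel-poor) core.

    Nodular lesions are fed by dilated perilesional vessels; several
    distinct dense patches away from the core reproduce the hallmark
    that a high-density threshold yields multiple disjoint areas.
    """
    ext = spec.grid.extent_mm
    margin = 1.1
    corners = [
        (margin, ext[2] - margin),
        (ext[1] - margin, margin),
        (ext[1] - margin, ext[2] - margin),
    ]
    paths = []
    for cy, cx in corners:
        paths.extend(
            _patch_paths(spec, rng, (cy, cx), spec.hotspot_radius_mm, spec.hotspot_multiplier)
        )
    return paths


def make_phantom(spec: PhantomSpec) -> Tuple[OctaVolume, PhantomTruth]:
    """Generate a seeded phantom volume and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    lo_r, hi_r = spec.vessel_radius_range_mm

    zr = spec.vessel_z_radius_mm
    if spec.kind == "single_tube":
        ext = grid.extent_mm
        path = make_path(
            "straight",
            {"start": (ext[0] / 2, ext[1] / 2, 0.02), "end": (ext[0] / 2, ext[1] / 2, ext[2] - 0.02)},
        )
        paths, radii, z_radii = [path], [hi_r], [zr]
        lesion_disk, center = None, None
    elif spec.kind == "tube_set":
        ext = grid.extent_mm
        paths, radii, z_radii = [], [], []
        n = 3
        for k in range(n):
            y = (k + 1) * ext[1] / (n + 1)
            paths.append(
                make_path(
                    "straight", {"start": (ext[0] / 2, y, 0.02), "end": (ext[0] / 2, y, ext[2] - 0.02)}
                )
            )
            radii.append(lo_r + (hi_r - lo_r) * k / max(1, n - 1))
            z_radii.append(zr)
        lesion_disk, center = None, None
    else:
        paths = _bed_paths(spec, rng)
        radii = list(rng.uniform(lo_r, hi_r, size=len(paths)))
        z_radii = [zr] * len(paths)
        lesion_disk, center = None, None
        if spec.kind in ("sbcc", "nbcc"):
            lesion_disk, center = _lesion_disk(spec)
        if spec.kind == "sbcc":
            extra = _extra_lesion_paths(spec, rng, center)
            paths.extend(extra)
            radii.extend(rng.uniform(lo_r, lo_r * 1.3, size=len(extra)))
            z_radii.extend([spec.lesion_vessel_z_radius_mm] * len(extra))
        elif spec.kind == "nbcc":
            # cull background centreline points inside the vessel-poor core
            culled, culled_radii, culled_zr = [], [], []
            keep_frac = spec.lesion_density_multiplier
            for pts, r in zip(paths, radii):
                d2 = (pts[:, 1] - center[0]) ** 2 + (pts[:, 2] - center[1]) ** 2
                inside = d2 <= spec.lesion_radius_mm**2
                if not inside.any():
                    culled.append(pts)
                    culled_radii.append(r)
                    culled_zr.append(zr)
                    continue
                # keep only a fraction of in-core pieces: split path at core boundary
                for run in _runs(~inside):
                    if run.size >= 8:
                        culled.append(pts[run])
                        culled_radii.append(r)
                        culled_zr.append(zr)
                if keep_frac > 0 and rng.uniform() < keep_frac:
                    for run in _runs(inside):
                        if run.size >= 8:
                            culled.append(pts[run])
                            culled_radii.append(r)
                            culled_zr.append(zr)
            paths, radii, z_radii = culled, culled_radii, culled_zr
            hot = _hotspot_paths(spec, rng, center)
            paths.extend(hot)
            radii.extend(rng.uniform(lo_r, hi_r, size=len(hot)))
            z_radii.extend([zr] * len(hot))

    mask = np.zeros(grid.shape, dtype=np.uint8)
    for pts, r, rz in zip(paths, radii, z_radii):
        mask |= rasterize_tube(pts, float(r), grid, z_radius_mm=float(rz))

    profile = ndimage.gaussian_filter(mask.astype(np.float64), sigma=(1.0, 0.7, 0.7))
    pmax = profile.max()
    if pmax > 0:
        profile /= pmax
    speckle = 1.0 + spec.speckle_scale * (rng.exponential(1.0, size=grid.shape) - 1.0)
    noise = rng.normal(0.0, spec.gaussian_sigma, size=grid.shape)
    data = np.clip(profile * speckle + noise, 0.0, None)

    truth = PhantomTruth(
        kind=spec.kind,
        vessel_mask=mask,
        centerlines=paths,
        centerline_radii_mm=[float(r) for r in radii],
        lesion_mask_2d=lesion_disk,
        lesion_centroid_mm=center,
    )
    return OctaVolume(data=data, grid=grid), truth


def _runs(flags: np.ndarray) -> List[np.ndarray]:
    """Index arrays of maximal True runs."""
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append(np.arange(start, i))
            start = None
    if start is not None:
        runs.append(np.arange(start, len(flags)))
    return runs


def true_centerline_density(
    truth: PhantomTruth, grid: VoxelGrid, region_mask_2d: np.ndarray
) -> float:
    """Ground-truth centreline length (mm) per en-face area (mm^2) in a region."""
    area = float(region_mask_2d.sum()) * grid.spacing[1] * grid.spacing[2]
    if area == 0:
        return 0.0
    total = 0.0
    for pts in truth.centerlines:
        iy = np.clip((pts[:, 1] / grid.spacing[1]).astype(int), 0, grid.shape[1] - 1)
        ix = np.clip((pts[:, 2] / grid.spacing[2]).astype(int), 0, grid.shape[2] - 1)
        inside = region_mask_2d[iy, ix]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        total += float(seg[inside[:-1] & inside[1:]].sum())
    return total / area
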