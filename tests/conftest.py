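import numpy as np
import pytest

from octa_lesion.config import PipelineConfig
from octa_lesion.synthetic_phantom import PhantomSpec
from octa_lesion.volume_io import OctaVolume, VoxelGrid

#: coarse-depth analogue of the default phantom grid: identical 8 mm
#: en-face geometry, 10 um axial pitch, so a full pipeline run takes
#: seconds instead of half a minute (used by the multi-seed end-to-end
#: sweeps; single-seed runs use the full-resolution default grid)
FAST_GRID = VoxelGrid((32, 256, 256), (0.0099, 0.03125, 0.03125))

#: VD on the fast grid is ~3x the native-scale VD (30 instead of 91
#: depth slices in each ROI denominator), so the absolute presence limit
#: scales by the same factor
FAST_VD_STD_LIM = 1.2e-4


def fast_phantom_spec(kind: str, seed: int) -> PhantomSpec:
    kw = dict(
        kind=kind,
        seed=seed,
        grid=FAST_GRID,
        vessel_z_radius_mm=0.015,
        lesion_vessel_z_radius_mm=0.010,
    )
    if kind == "sbcc":
        kw["lesion_density_multiplier"] = 5.0
    if kind == "nbcc":
        kw["hotspot_multiplier"] = 4.0
    return PhantomSpec(**kw)


def fast_pipeline_config() -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.detection.vd_std_lim = FAST_VD_STD_LIM
    return cfg


@pytest.fixture
def iso_grid():
    """Small isotropic grid for geometric unit tests."""
    return VoxelGrid((32, 32, 32), (0.02, 0.02, 0.02))


def tube_volume(shape, spacing, center_zy, radius_vox, axis=2, value=1.0):
    """Axis-aligned solid tube as an OctaVolume (intensity phantom)."""
    grid = VoxelGrid(shape, spacing)
    idx = np.indices(shape)
    others = [a for a in range(3) if a != axis]
    d2 = sum((idx[a] - c) ** 2 for a, c in zip(others, center_zy))
    data = np.where(d2 <= radius_vox**2, value, 0.0)
    return OctaVolume(data=data, grid=grid)


def tube_mask(shape, center_zy, radius_vox, axis=2):
    idx = np.indices(shape)
    others = [a for a in range(3) if a != axis]
    d2 = sum((idx[a] - c) ** 2 for a, c in zip(others, center_zy))
    return (d2 <= radius_vox**2).astype(np.uint8)
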