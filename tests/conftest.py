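"""Shared fixtures: small digitized shapes and phantom/cohort builders."""

from __future__ import annotations

import numpy as np
import pytest

from frailsvd import PipelineConfig, VoxelGrid
from frailsvd.wmh import Lesion


def voxel_ball(radius: float, spacing=(1.0, 1.0, 1.0), margin: int = 2) -> np.ndarray:
    """Boolean mask of a digitized ball (voxel-center inclusion)."""
    spacing = np.asarray(spacing, float)
    half = np.ceil(radius / spacing).astype(int) + margin
    shape = 2 * half + 1
    idx = np.indices(shape).astype(float)
    coords = [(idx[a] - half[a]) * spacing[a] for a in range(3)]
    return coords[0] ** 2 + coords[1] ** 2 + coords[2] ** 2 <= radius**2


def voxel_ellipsoid(radii, spacing=(1.0, 1.0, 1.0), margin: int = 2) -> np.ndarray:
    radii = np.asarray(radii, float)
    spacing = np.asarray(spacing, float)
    half = np.ceil(radii / spacing).astype(int) + margin
    shape = 2 * half + 1
    idx = np.indices(shape).astype(float)
    coords = [(idx[a] - half[a]) * spacing[a] for a in range(3)]
    return sum((coords[a] / radii[a]) ** 2 for a in range(3)) <= 1.0


def mask_to_lesion(mask: np.ndarray) -> Lesion:
    return Lesion(voxel_indices=np.argwhere(mask))


def mask_to_grid(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> VoxelGrid:
    return VoxelGrid(np.asarray(mask, float), spacing_mm=np.asarray(spacing, float))


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def ball_r8() -> np.ndarray:
    return voxel_ball(8.0)


# deterministic hypothesis runs
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("det", derandomize=True, deadline=None)
_hyp_settings.load_profile("det")
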