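"""Volumetric containers and imaging I/O.

The pipeline's carrier type is :class:`VoxelGrid`, a 3D scalar field with an
anisotropic voxel spacing and a NIfTI-style voxel-to-world affine.  All
geometry downstream (distance rules, surface areas, volumes) is computed in
world millimetres derived from the affine; nothing is ever measured in voxel
units.  Coordinates follow the RAS convention of the affine as stored; no
reorientation is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: scipy structuring elements for the three standard 3D connectivities
_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class VoxelGrid:
    """A 3D scalar field with voxel spacing in mm and a voxel-to-world affine.

    Parameters
    ----------
    data:
        3D array.  Masks hold {0, 1}; probability maps hold values in [0, 1];
        quantified maps (CBF) hold arbitrary non-negative reals.
    affine:
        4x4 voxel-to-world transform.  If omitted, a diagonal affine is built
        from ``spacing_mm``.
    spacing_mm:
        Per-axis voxel size in mm.  Derived from the affine when an affine is
        given; defaults to isotropic 1 mm otherwise.
    """

    data: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]
    spacing_mm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"VoxelGrid requires 3D data, got {self.data.ndim}D "
                f"with shape {self.data.shape}"
            )
        if self.affine is None:
            spacing = (
                np.ones(3) if self.spacing_mm is None else np.asarray(self.spacing_mm, float)
            )
            if np.any(spacing <= 0):
                raise ValueError(f"voxel spacing must be positive, got {spacing}")
            self.affine = np.diag([*spacing, 1.0])
        else:
            self.affine = np.asarray(self.affine, float)
            if self.affine.shape != (4, 4):
                raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        # spacing always re-derived from the affine so the two cannot disagree
        self.spacing_mm = np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))
        if np.any(self.spacing_mm <= 0):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        """New grid with the same geometry but different data."""
        return VoxelGrid(data=data, affine=self.affine.copy())


def read_volume(path) -> VoxelGrid:
    """Read a NIfTI-1/2 volume into a :class:`VoxelGrid`.

    Raises
    ------
    ValueError
        If the image is not 3D (trailing singleton dimensions are squeezed
        first, so a 64x64x64x1 file is accepted).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    # squeeze trailing singleton dims (some converters write 3D data as 4D)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got {data.ndim}D data "
            f"with shape {data.shape}"
        )
    return VoxelGrid(data=np.asarray(data, float), affine=np.asarray(img.affine))


def write_volume(grid: VoxelGrid, path) -> None:
    """Write a grid as NIfTI; spacing and affine survive a round trip."""
    img = nib.Nifti1Image(np.asarray(grid.data, np.float32), grid.affine)
    img.header.set_zooms(tuple(grid.spacing_mm))
    nib.save(img, str(path))


def threshold_probability(prob: VoxelGrid, t: float = 0.10) -> VoxelGrid:
    """Binarize a probability map at threshold ``t`` (inclusive: keep >= t).

    The inclusive convention keeps voxels printed exactly at the boundary
    value; the number of retained voxels is logged.
    """
    if not 0.0 < t < 1.0:
        raise ValueError(f"probability threshold must lie in (0, 1), got {t}")
    data = np.asarray(prob.data, float)
    if data.min() < 0 or data.max() > 1:
        raise ValueError(
            f"probability map values must lie in [0, 1], "
            f"got range [{data.min():.3g}, {data.max():.3g}]"
        )
    mask = (data >= t).astype(np.uint8)
    logger.info("threshold_probability: t=%.3g retained %d voxels", t, int(mask.sum()))
    return prob.with_data(mask)


def apply_exclusion_mask(mask: VoxelGrid, exclusion: VoxelGrid) -> VoxelGrid:
    """Remove exclusion-mask voxels (e.g. manually delineated cortical
    infarcts) from a binary mask: output = mask AND NOT exclusion."""
    if not mask.same_geometry(exclusion):
        raise ValueError(
            "exclusion mask geometry mismatch: "
            f"shapes {mask.shape} vs {exclusion.shape}"
        )
    out = (np.asarray(mask.data, bool) & ~np.asarray(exclusion.data, bool)).astype(
        np.uint8
    )
    removed = int(mask.data.sum() - out.sum())
    logger.info("apply_exclusion_mask: removed %d voxels", removed)
    return mask.with_data(out)


class ComponentSet(NamedTuple):
    """Connected components of a binary mask plus dropped-voxel bookkeeping."""

    components: list[np.ndarray]  # each an (n_i, 3) integer index array
    n_dropped_voxels: int  # voxels in components below the size floor


def connected_components(
    mask: VoxelGrid, connectivity: int = 26, min_lesion_voxels: int = 2
) -> ComponentSet:
    """Extract connected components (candidate lesions) from a binary mask.

    Components smaller than ``min_lesion_voxels`` are dropped (single-voxel
    components have degenerate surfaces); their voxel count is returned so
    that ``sum(component sizes) + n_dropped == mask.sum()`` always holds.
    """
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    binary = np.asarray(mask.data, bool)
    labels, n = ndimage.label(binary, structure=_CONNECTIVITY_STRUCTS[connectivity])
    components: list[np.ndarray] = []
    dropped = 0
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        if len(idx) < min_lesion_voxels:
            dropped += len(idx)
        else:
            components.append(idx)
    if dropped:
        logger.info(
            "connected_components: dropped %d voxels in components below "
            "%d voxels", dropped, min_lesion_voxels,
        )
    return ComponentSet(components=components, n_dropped_voxels=dropped)
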