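"""Synthetic 3D image phantoms for the WMH and perfusion pipelines.

Phantoms supply what real study data would: a WMH probability map, a
lateral-ventricle mask, and (for ASL) a ΔM/M0 pair consistent with a chosen
CBF field — together with exact ground truth (category, analytic volume,
convex-reference shape values) so every downstream measurement can be
checked against a known answer.

Lesions are rasterized by voxel-center inclusion with probability 0.9 inside
and 0.0 outside (optionally Gaussian-blurred for threshold testing), which
keeps the analytic truth exact before smoothing.  The ``perturbed_blob``
family is a ball whose radius is modulated by seeded spherical-harmonic
noise; its amplitude is the single complexity dial used by the monotonicity
properties of the shape features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, special

from .grid import VoxelGrid
from .perfusion import AcquisitionParams

SHAPE_FAMILIES = ("ball", "ellipsoid", "perturbed_blob", "plus_cross", "line")

#: spherical-harmonic degrees used for blob surface roughening; the upper
#: degree is high enough that the grid can resolve the induced concavities
BLOB_HARMONIC_DEGREES = range(2, 13)

#: the harmonic field is scaled by this many standard deviations, so that a
#: unit perturbation amplitude corresponds to the field's typical extreme
#: rather than its seed-dependent maximum
BLOB_FIELD_SIGMAS = 3.0


@dataclass
class LesionSpec:
    """Parametric description of one synthetic lesion.

    ``radii_mm`` is interpreted per family: ball and perturbed_blob use
    ``radii_mm[0]`` as the (base) radius; ellipsoid uses all three semi-axes;
    plus_cross uses ``radii_mm[0]`` as arm half-length and ``radii_mm[1]``
    as arm half-thickness; line uses ``radii_mm[0]`` as half-length along
    the first axis.
    """

    shape_family: str
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    perturbation_amplitude: float = 0.0
    target_category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.shape_family not in SHAPE_FAMILIES:
            raise ValueError(
                f"shape_family must be one of {SHAPE_FAMILIES}, "
                f"got {self.shape_family!r}"
            )
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("radii_mm must be positive")
        if self.perturbation_amplitude < 0:
            raise ValueError("perturbation_amplitude must be >= 0")


@dataclass
class VentricleSpec:
    """Parametric lateral-ventricle stand-in: a slab filling the low end of
    the first axis up to ``slab_extent_mm``, or an ellipsoid."""

    kind: str = "slab"
    slab_extent_mm: float = 10.0
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radii_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)

    def __post_init__(self) -> None:
        if self.kind not in ("slab", "ellipsoid"):
            raise ValueError("ventricle kind must be 'slab' or 'ellipsoid'")


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ventricle_geometry: VentricleSpec = field(default_factory=VentricleSpec)
    lesion_specs: list[LesionSpec] = field(default_factory=list)
    lesion_probability: float = 0.9
    blur_sigma_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape must be >= 16 voxels per axis")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")


def _voxel_center_coords(shape, spacing):
    """World-mm coordinates of voxel centers, one array per axis."""
    idx = np.indices(shape, dtype=float)
    return [idx[a] * spacing[a] for a in range(3)]


def _harmonic_field(theta, phi, coeffs):
    """Real linear combination of spherical harmonics over the given degrees."""
    out = np.zeros_like(theta)
    i = 0
    for l in BLOB_HARMONIC_DEGREES:
        for m in range(-l, l + 1):
            y = special.sph_harm_y(l, abs(m), theta, phi)
            out += coeffs[i] * (y.real if m >= 0 else y.imag)
            i += 1
    return out


def rasterize_lesion(
    spec: LesionSpec, grid_shape, spacing_mm, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask of one lesion by voxel-center inclusion."""
    spacing = np.asarray(spacing_mm, float)
    x, y, z = _voxel_center_coords(grid_shape, spacing)
    cx, cy, cz = spec.center_mm
    dx, dy, dz = x - cx, y - cy, z - cz
    rx, ry, rz = spec.radii_mm

    if spec.shape_family == "ball":
        return dx**2 + dy**2 + dz**2 <= rx**2
    if spec.shape_family == "ellipsoid":
        return (dx / rx) ** 2 + (dy / ry) ** 2 + (dz / rz) ** 2 <= 1.0
    if spec.shape_family == "perturbed_blob":
        r = np.sqrt(dx**2 + dy**2 + dz**2) + 1e-12
        ncoef = sum(2 * l + 1 for l in BLOB_HARMONIC_DEGREES)
        coeffs = rng.normal(size=ncoef)
        amp = spec.perturbation_amplitude
        mask = r <= rx * (1.0 - amp)  # certainly inside
        if amp > 0:
            # the angular field only matters inside the modulation band
            band = (r > rx * (1.0 - amp)) & (r <= rx * (1.0 + amp))
            rb = r[band]
            theta = np.arccos(np.clip(dz[band] / rb, -1.0, 1.0))
            phi = np.arctan2(dy[band], dx[band])
            f = _harmonic_field(theta, phi, coeffs)
            sigma = f.std()
            if sigma > 0:
                f = np.clip(f / (BLOB_FIELD_SIGMAS * sigma), -1.0, 1.0)
            mask = mask.copy()
            mask[band] = rb <= rx * (1.0 + amp * f)
        return mask
    if spec.shape_family == "plus_cross":
        half_len, half_th = rx, ry
        arm_x = (np.abs(dx) <= half_len) & (np.abs(dy) <= half_th) & (np.abs(dz) <= half_th)
        arm_y = (np.abs(dy) <= half_len) & (np.abs(dx) <= half_th) & (np.abs(dz) <= half_th)
        arm_z = (np.abs(dz) <= half_len) & (np.abs(dx) <= half_th) & (np.abs(dy) <= half_th)
        return arm_x | arm_y | arm_z
    # line: one voxel thick along the first axis
    return (
        (np.abs(dx) <= rx)
        & (np.abs(dy) <= spacing[1] / 2.0)
        & (np.abs(dz) <= spacing[2] / 2.0)
    )


def _rasterize_ventricle(spec: VentricleSpec, grid_shape, spacing_mm) -> np.ndarray:
    x, y, z = _voxel_center_coords(grid_shape, spacing_mm)
    if spec.kind == "slab":
        return x <= spec.slab_extent_mm
    cx, cy, cz = spec.center_mm
    rx, ry, rz = spec.radii_mm
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


#: closed-form volumes, where the family has one
def analytic_volume_mm3(spec: LesionSpec) -> Optional[float]:
    rx, ry, rz = spec.radii_mm
    if spec.shape_family == "ball":
        return 4.0 / 3.0 * np.pi * rx**3
    if spec.shape_family == "ellipsoid":
        return 4.0 / 3.0 * np.pi * rx * ry * rz
    return None


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[VoxelGrid, VoxelGrid, list[dict]]:
    """Generate (probability map, ventricle mask, per-lesion ground truth).

    Ground-truth records carry each lesion's intended category, voxel count,
    analytic volume where closed-form, and convex-reference shape values
    where the family guarantees them (amplitude-0 blobs, balls, ellipsoids
    are convex; a line has box-counting dimension 1).

    Raises
    ------
    ValueError
        If two lesions overlap (their ground truth would be ambiguous) or a
        lesion touches the grid boundary (it would be clipped).
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm, float)

    claimed = np.zeros(shape, np.int32)
    truth: list[dict] = []
    for i, lesion_spec in enumerate(spec.lesion_specs):
        mask = rasterize_lesion(lesion_spec, shape, spacing, rng)
        if not mask.any():
            raise ValueError(f"lesion {i} rasterized to zero voxels")
        edge = (
            mask[0].any() or mask[-1].any()
            or mask[:, 0].any() or mask[:, -1].any()
            or mask[:, :, 0].any() or mask[:, :, -1].any()
        )
        if edge:
            raise ValueError(f"lesion {i} touches the grid boundary")
        if (claimed[mask] > 0).any():
            raise ValueError(f"lesion {i} overlaps an earlier lesion")
        claimed[mask] = i + 1

        convex = lesion_spec.shape_family in ("ball", "ellipsoid") or (
            lesion_spec.shape_family == "perturbed_blob"
            and lesion_spec.perturbation_amplitude == 0.0
        )
        truth.append(
            {
                "lesion": i,
                "shape_family": lesion_spec.shape_family,
                "target_category": lesion_spec.target_category,
                "n_voxels": int(mask.sum()),
                "volume_ml": float(mask.sum() * np.prod(spacing) / 1000.0),
                "analytic_volume_mm3": analytic_volume_mm3(lesion_spec),
                "solidity_ref": 1.0 if convex else None,
                "convexity_ref": 1.0 if convex else None,
                "concavity_index_ref": 1.0 if convex else None,
                "fractal_dimension_ref": (
                    1.0 if lesion_spec.shape_family == "line" else None
                ),
            }
        )

    prob = np.where(claimed > 0, spec.lesion_probability, 0.0)
    if spec.blur_sigma_mm > 0:
        prob = ndimage.gaussian_filter(prob, sigma=spec.blur_sigma_mm / spacing)
        prob = np.clip(prob, 0.0, 1.0)

    vent = _rasterize_ventricle(spec.ventricle_geometry, shape, spacing)
    affine = np.diag([*spacing, 1.0])
    return (
        VoxelGrid(prob, affine=affine),
        VoxelGrid(vent.astype(np.uint8), affine=affine),
        truth,
    )


def generate_asl_phantom(
    cbf_truth: VoxelGrid,
    params: AcquisitionParams | None = None,
    gm_mask: VoxelGrid | None = None,
    wm_mask: VoxelGrid | None = None,
    m0_value: float = 1000.0,
) -> tuple[VoxelGrid, VoxelGrid]:
    """Invert the single-compartment model: ΔM/M0 images whose quantification
    recovers ``cbf_truth`` to round-off.

    ``gm_mask``/``wm_mask`` are accepted for signature symmetry with real
    pipelines (the CBF field is typically piecewise-constant over them) but
    the inversion itself is voxelwise and mask-free.
    """
    params = params or AcquisitionParams()
    if m0_value <= 0:
        raise ValueError("m0_value must be positive")
    cbf = np.asarray(cbf_truth.data, float)
    if (cbf < 0).any():
        raise ValueError("cbf_truth must be non-negative")
    m0 = np.full(cbf.shape, float(m0_value))
    delta_m = cbf * m0 / params.scaling_factor
    return cbf_truth.with_data(delta_m), cbf_truth.with_data(m0)
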