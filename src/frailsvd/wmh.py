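"""WMH lesion classification, 3D shape morphometry and per-subject aggregation.

Each 26-connected white-matter-hyperintensity component is classified by its
Euclidean distance (in mm, anisotropy-aware) to the lateral ventricles:

* **periventricular** — every voxel within the distance rule (default 10 mm),
* **confluent** — spanning from within the rule to beyond it,
* **deep** — entirely beyond it.

Shape descriptors are computed per lesion from a triangulated surface
(marching cubes at the 0.5 isosurface, optionally Laplacian-smoothed) and its
convex hull: solidity, convexity and a concavity index for periventricular/
confluent lesions, eccentricity for deep lesions, and a box-counting fractal
dimension of the lesion boundary for both.  Per-patient means within the
periventricular/confluent group and within the deep group are the inputs to
the statistical analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .config import PipelineConfig
from .grid import VoxelGrid
from .perfusion import PerfusionResult

logger = logging.getLogger(__name__)

PERIVENTRICULAR = "periventricular"
CONFLUENT = "confluent"
DEEP = "deep"
CATEGORIES = (PERIVENTRICULAR, CONFLUENT, DEEP)
#: integer codes used in the category-labeled lesion map
CATEGORY_CODES = {PERIVENTRICULAR: 1, CONFLUENT: 2, DEEP: 3}

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class LesionShapeMetrics:
    """Shape descriptors of a single lesion; ``None`` marks a metric that is
    undefined for the lesion (degenerate hull, too small for box counting)."""

    volume_ml: float
    surface_mm2: Optional[float] = None
    hull_volume_ml: Optional[float] = None
    hull_surface_mm2: Optional[float] = None
    solidity: Optional[float] = None
    convexity: Optional[float] = None
    concavity_index: Optional[float] = None
    fractal_dimension: Optional[float] = None
    eccentricity: Optional[float] = None
    degenerate: bool = False


@dataclass
class Lesion:
    """One connected WMH component."""

    voxel_indices: np.ndarray  # (n, 3) integer grid indices
    category: Optional[str] = None
    min_distance_mm: Optional[float] = None
    max_distance_mm: Optional[float] = None
    metrics: Optional[LesionShapeMetrics] = None

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)


@dataclass
class SubjectFeatures:
    """Per-subject SVD feature vector.

    Volumes partition exactly: ``vol_total_ml == vol_pvconf_ml + vol_deep_ml``.
    Shape features are per-patient means over lesions of the relevant
    category group; a subject with no lesions in a group has zero volume and
    missing (NaN) shape means there.
    """

    vol_total_ml: float
    vol_pvconf_ml: float
    vol_deep_ml: float
    solidity_pvconf: float = math.nan
    convexity_pvconf: float = math.nan
    concavity_index_pvconf: float = math.nan
    fractal_dimension_pvconf: float = math.nan
    eccentricity_deep: float = math.nan
    fractal_dimension_deep: float = math.nan
    n_lesions: int = 0
    n_lesions_pvconf: int = 0
    n_lesions_deep: int = 0
    icv_ml: float = math.nan
    lacunar_present: Optional[bool] = None
    gm_cbf: float = math.nan
    deepwm_cbf: float = math.nan
    spatial_cov: float = math.nan

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["lacunar_present"] = (
            None if self.lacunar_present is None else bool(self.lacunar_present)
        )
        return d


# ---------------------------------------------------------------------------
# classification

def classify_lesions(
    lesions: Sequence[np.ndarray | Lesion],
    ventricle_mask: VoxelGrid,
    pv_distance_mm: float = 10.0,
) -> list[Lesion]:
    """Assign each lesion a periventricular/confluent/deep category.

    Distances are from lesion voxel centers to the nearest ventricle voxel
    center, computed with an anisotropy-aware Euclidean distance transform in
    mm.  The distance rule is inclusive on the near side (within = ``<=``)
    and strict on the far side (beyond = ``>``).
    """
    vent = np.asarray(ventricle_mask.data, bool)
    if not vent.any():
        raise ValueError("ventricle mask is empty; cannot classify lesions")
    dist = ndimage.distance_transform_edt(
        ~vent, sampling=ventricle_mask.spacing_mm
    )
    out: list[Lesion] = []
    for item in lesions:
        lesion = item if isinstance(item, Lesion) else Lesion(voxel_indices=np.asarray(item))
        idx = lesion.voxel_indices
        d = dist[idx[:, 0], idx[:, 1], idx[:, 2]]
        dmin, dmax = float(d.min()), float(d.max())
        if dmax <= pv_distance_mm:
            lesion.category = PERIVENTRICULAR
        elif dmin <= pv_distance_mm:
            lesion.category = CONFLUENT
        else:
            lesion.category = DEEP
        lesion.min_distance_mm = dmin
        lesion.max_distance_mm = dmax
        out.append(lesion)
    return out


def category_map(lesions: Sequence[Lesion], like: VoxelGrid) -> VoxelGrid:
    """Integer-coded lesion map (1 = periventricular, 2 = confluent, 3 = deep)."""
    data = np.zeros(like.shape, np.int16)
    for lesion in lesions:
        if lesion.category is None:
            continue
        idx = lesion.voxel_indices
        data[idx[:, 0], idx[:, 1], idx[:, 2]] = CATEGORY_CODES[lesion.category]
    return like.with_data(data)


# ---------------------------------------------------------------------------
# volume and surface

def lesion_volume_ml(lesion: Lesion | np.ndarray, spacing_mm) -> float:
    """Voxel count x voxel volume, in ml (1 ml = 1000 mm3)."""
    n = lesion.n_voxels if isinstance(lesion, Lesion) else len(lesion)
    if n == 0:
        raise ValueError("empty lesion has no volume")
    return n * float(np.prod(np.asarray(spacing_mm, float))) / 1000.0


def _lesion_subvolume(idx: np.ndarray) -> np.ndarray:
    """Tight boolean subvolume of the lesion, 1-voxel pad on every side."""
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    sub = np.zeros(hi - lo + 3, bool)
    off = idx - lo + 1
    sub[off[:, 0], off[:, 1], off[:, 2]] = True
    return sub


def _is_degenerate(idx: np.ndarray) -> bool:
    """Collinear/coplanar voxel-center sets cannot support a 3D hull."""
    if len(idx) < 4:
        return True
    centered = idx - idx.mean(axis=0)
    return np.linalg.matrix_rank(centered, tol=1e-8) < 3


def build_surface(
    lesion: Lesion | np.ndarray,
    spacing_mm,
    smooth_iterations: int = 20,
    smooth_lambda: float = 0.5,
) -> Optional[trimesh.Trimesh]:
    """Triangulated closed surface of a lesion at the 0.5 isosurface, in mm.

    Laplacian smoothing (default 20 passes) removes the voxelization
    staircase whose excess area would otherwise break the identity that a
    convex shape matches its own hull.  Returns ``None`` for degenerate
    (collinear/coplanar) lesions, which are flagged rather than meshed.
    """
    idx = lesion.voxel_indices if isinstance(lesion, Lesion) else np.asarray(lesion)
    if _is_degenerate(idx):
        return None
    sub = _lesion_subvolume(idx)
    verts, faces, _, _ = measure.marching_cubes(
        sub.astype(np.float32), level=0.5, spacing=tuple(np.asarray(spacing_mm, float))
    )
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    if smooth_iterations > 0:
        trimesh.smoothing.filter_laplacian(
            mesh, lamb=smooth_lambda, iterations=smooth_iterations
        )
    return mesh


# ---------------------------------------------------------------------------
# shape-feature formula strategies
#
# Each strategy maps (V, A, V_hull, A_hull) to (solidity, convexity,
# concavity_index) and must return (1, 1, 1) for a convex shape.  A single
# registry entry keeps the algebra swappable as one config choice.

ShapeFormula = Callable[[float, float, float, float], tuple[float, float, float]]


def _hull_ratio_formulas(
    v: float, a: float, v_hull: float, a_hull: float
) -> tuple[float, float, float]:
    solidity = v / v_hull
    convexity = a / a_hull  # >= 1 for rough shapes
    concavity_index = (a / a_hull) * (v_hull / v) ** (1.0 / 3.0)
    return solidity, convexity, concavity_index


SHAPE_FORMULA_STRATEGIES: dict[str, ShapeFormula] = {
    "hull_ratio": _hull_ratio_formulas,
}


def shape_features(
    lesion: Lesion | np.ndarray,
    spacing_mm,
    config: PipelineConfig | None = None,
) -> LesionShapeMetrics:
    """All shape descriptors of one lesion.

    Degenerate lesions keep their voxel-count volume but have every
    hull-based feature missing.  Fractal dimension and eccentricity are
    computed from the voxel set directly and have their own validity rules.
    """
    config = config or PipelineConfig()
    idx = lesion.voxel_indices if isinstance(lesion, Lesion) else np.asarray(lesion)
    spacing = np.asarray(spacing_mm, float)
    metrics = LesionShapeMetrics(volume_ml=lesion_volume_ml(idx, spacing))

    mesh = build_surface(
        idx, spacing, config.smooth_iterations, config.smooth_lambda
    )
    if mesh is None:
        metrics.degenerate = True
        logger.info("shape_features: degenerate lesion of %d voxels", len(idx))
    else:
        hull = mesh.convex_hull
        v, a = float(mesh.volume), float(mesh.area)
        v_hull, a_hull = float(hull.volume), float(hull.area)
        metrics.surface_mm2 = a
        metrics.hull_volume_ml = v_hull / 1000.0
        metrics.hull_surface_mm2 = a_hull
        formula = SHAPE_FORMULA_STRATEGIES[config.shape_formula_strategy]
        metrics.solidity, metrics.convexity, metrics.concavity_index = formula(
            v, a, v_hull, a_hull
        )

    metrics.fractal_dimension = fractal_dimension(idx, config.fd_box_sizes)
    metrics.eccentricity = eccentricity(idx, spacing)
    return metrics


# ---------------------------------------------------------------------------
# fractal dimension

def boundary_voxels(sub: np.ndarray) -> np.ndarray:
    """Lesion voxels with at least one background 6-neighbor."""
    return sub & ~ndimage.binary_erosion(sub, structure=_STRUCT6)


def _box_count(boundary: np.ndarray, size: int) -> int:
    pad = [(0, (-d) % size) for d in boundary.shape]
    b = np.pad(boundary, pad)
    blocks = b.reshape(
        b.shape[0] // size, size, b.shape[1] // size, size, b.shape[2] // size, size
    )
    return int(blocks.any(axis=(1, 3, 5)).sum())


def fractal_dimension(
    lesion: Lesion | np.ndarray, box_sizes: Sequence[int] = (1, 2, 4, 8, 16)
) -> Optional[float]:
    """Minkowski–Bouligand dimension of the lesion boundary.

    Boxes of each edge length that intersect the boundary voxel set are
    counted on the tight bounding box; the estimate is the least-squares
    slope of log N(s) against log (1/s).  Box sizes larger than the lesion
    extent are skipped; lesions spanning fewer than two of the smallest
    boxes get a missing value.  The estimate is ~1 for a line, ~2 for the
    boundary shell of a smooth blob.
    """
    idx = lesion.voxel_indices if isinstance(lesion, Lesion) else np.asarray(lesion)
    if len(idx) < 2:
        return None
    sub = _lesion_subvolume(idx)[1:-1, 1:-1, 1:-1]  # tight, no pad
    boundary = boundary_voxels(np.pad(sub, 1))[1:-1, 1:-1, 1:-1]
    extent = max(boundary.shape)
    sizes = sorted({int(s) for s in box_sizes if 1 <= s <= extent})
    if len(sizes) < 2:
        return None
    counts = np.array([_box_count(boundary, s) for s in sizes])
    if counts[0] < 2:
        return None
    slope = np.polyfit(-np.log(sizes), np.log(counts), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# eccentricity

def eccentricity(
    lesion: Lesion | np.ndarray, spacing_mm
) -> Optional[float]:
    """Elongation from principal moments of the mm voxel-center cloud.

    With covariance eigenvalues λ1 >= λ2 >= λ3, eccentricity is
    sqrt(1 − λ3/λ1): 0 for an isotropic (ball-like) lesion, approaching 1
    for a needle.  Missing for degenerate (< 4 voxels or non-3D) lesions.
    """
    idx = lesion.voxel_indices if isinstance(lesion, Lesion) else np.asarray(lesion)
    if _is_degenerate(idx):
        return None
    coords = idx * np.asarray(spacing_mm, float)
    cov = np.cov(coords, rowvar=False)
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    if eigvals[0] <= 0:
        return None
    return float(np.sqrt(1.0 - eigvals[-1] / eigvals[0]))


# ---------------------------------------------------------------------------
# per-subject aggregation

def _nanmean(values: list[float]) -> float:
    vals = [v for v in values if v is not None and np.isfinite(v)]
    return float(np.mean(vals)) if vals else math.nan


def aggregate_subject(
    lesions: Sequence[Lesion],
    spacing_mm,
    icv_ml: float = math.nan,
    lacunar_present: Optional[bool] = None,
    perfusion: Optional[PerfusionResult] = None,
) -> SubjectFeatures:
    """Pool categorized, measured lesions into one subject feature vector.

    Periventricular and confluent lesions are pooled for volume and for the
    shape means (solidity, convexity, concavity index, fractal dimension);
    deep lesions contribute eccentricity and fractal dimension.  Lesions are
    weighted equally in the means.  Volumes are conserved exactly:
    total = pv/confluent + deep.
    """
    spacing = np.asarray(spacing_mm, float)
    pvconf = [l for l in lesions if l.category in (PERIVENTRICULAR, CONFLUENT)]
    deep = [l for l in lesions if l.category == DEEP]
    unknown = [l for l in lesions if l.category not in CATEGORIES]
    if unknown:
        raise ValueError(f"{len(unknown)} lesions have no category; classify first")

    vol_pvconf = sum(lesion_volume_ml(l, spacing) for l in pvconf)
    vol_deep = sum(lesion_volume_ml(l, spacing) for l in deep)

    def _metric(group: list[Lesion], name: str) -> float:
        return _nanmean(
            [getattr(l.metrics, name) for l in group if l.metrics is not None]
        )

    feats = SubjectFeatures(
        vol_total_ml=vol_pvconf + vol_deep,
        vol_pvconf_ml=vol_pvconf,
        vol_deep_ml=vol_deep,
        solidity_pvconf=_metric(pvconf, "solidity"),
        convexity_pvconf=_metric(pvconf, "convexity"),
        concavity_index_pvconf=_metric(pvconf, "concavity_index"),
        fractal_dimension_pvconf=_metric(pvconf, "fractal_dimension"),
        eccentricity_deep=_metric(deep, "eccentricity"),
        fractal_dimension_deep=_metric(deep, "fractal_dimension"),
        n_lesions=len(pvconf) + len(deep),
        n_lesions_pvconf=len(pvconf),
        n_lesions_deep=len(deep),
        icv_ml=icv_ml,
        lacunar_present=lacunar_present,
    )
    if perfusion is not None:
        feats.gm_cbf = perfusion.gm_cbf if perfusion.gm_cbf is not None else math.nan
        feats.deepwm_cbf = (
            perfusion.deepwm_cbf if perfusion.deepwm_cbf is not None else math.nan
        )
        feats.spatial_cov = (
            perfusion.spatial_cov if perfusion.spatial_cov is not None else math.nan
        )
    return feats


def measure_lesions(
    lesions: Sequence[Lesion],
    spacing_mm,
    config: PipelineConfig | None = None,
) -> list[Lesion]:
    """Attach :class:`LesionShapeMetrics` to every lesion in place."""
    config = config or PipelineConfig()
    for lesion in lesions:
        lesion.metrics = shape_features(lesion, spacing_mm, config)
    return list(lesions)


# ---------------------------------------------------------------------------
# end-to-end per-subject extraction

def extract_subject_features(
    prob_map: VoxelGrid,
    ventricle_mask: VoxelGrid,
    exclusion_mask: Optional[VoxelGrid] = None,
    config: PipelineConfig | None = None,
    icv_ml: float = math.nan,
    lacunar_present: Optional[bool] = None,
    perfusion: Optional[PerfusionResult] = None,
) -> tuple[SubjectFeatures, list[Lesion]]:
    """Full morphometry for one subject from a WMH probability map.

    Threshold -> optional exclusion mask -> connected components ->
    distance classification -> per-lesion shape metrics -> per-subject
    aggregation.  Returns the feature vector and the measured lesions.
    """
    from .grid import apply_exclusion_mask, connected_components, threshold_probability

    config = config or PipelineConfig()
    mask = threshold_probability(prob_map, config.prob_threshold)
    if exclusion_mask is not None:
        mask = apply_exclusion_mask(mask, exclusion_mask)
    comps = connected_components(
        mask, connectivity=config.connectivity,
        min_lesion_voxels=config.min_lesion_voxels,
    )
    lesions = classify_lesions(
        [Lesion(voxel_indices=idx) for idx in comps.components],
        ventricle_mask,
        config.pv_distance_mm,
    )
    measure_lesions(lesions, mask.spacing_mm, config)
    feats = aggregate_subject(
        lesions, mask.spacing_mm, icv_ml=icv_ml,
        lacunar_present=lacunar_present, perfusion=perfusion,
    )
    return feats, lesions


def lesion_table(lesions: Sequence[Lesion], spacing_mm) -> "pd.DataFrame":
    """Per-lesion feature table (one row per lesion)."""
    import pandas as pd

    rows = []
    for i, lesion in enumerate(lesions):
        m = lesion.metrics
        rows.append(
            {
                "lesion": i,
                "category": lesion.category,
                "n_voxels": lesion.n_voxels,
                "volume_ml": lesion_volume_ml(lesion, spacing_mm),
                "min_distance_mm": lesion.min_distance_mm,
                "max_distance_mm": lesion.max_distance_mm,
                **(
                    {
                        "surface_mm2": m.surface_mm2,
                        "solidity": m.solidity,
                        "convexity": m.convexity,
                        "concavity_index": m.concavity_index,
                        "fractal_dimension": m.fractal_dimension,
                        "eccentricity": m.eccentricity,
                        "degenerate": m.degenerate,
                    }
                    if m is not None
                    else {}
                ),
            }
        )
    return pd.DataFrame(rows)


def convex_hull_metrics(points_mm: np.ndarray) -> tuple[float, float]:
    """Convex-hull volume (mm^3) and surface area (mm^2) of a point cloud,
    using the same hull engine as the mesh pipeline."""
    pts = np.asarray(points_mm, float)
    if _is_degenerate(pts):
        raise ValueError("point set is degenerate; no 3D hull")
    hull = trimesh.Trimesh(vertices=pts, process=False).convex_hull
    return float(hull.volume), float(hull.area)
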