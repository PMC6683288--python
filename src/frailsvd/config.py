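"""Pipeline configuration with YAML round trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .perfusion import AcquisitionParams


@dataclass
class PipelineConfig:
    """Tunable parameters of the imaging pipeline.

    prob_threshold:
        Probability-map binarization threshold (inclusive); default 0.10.
    pv_distance_mm:
        Periventricular distance rule in mm: lesions entirely within this
        distance of the lateral ventricles are periventricular, lesions
        spanning the boundary confluent, lesions entirely beyond it deep.
    connectivity:
        Lesion connectivity (6, 18 or 26); 26 is standard for sparse masks.
    min_lesion_voxels:
        Components below this size are dropped (logged, not silently lost).
    fd_box_sizes:
        Box edge lengths (voxels) for box-counting fractal dimension.
    smooth_iterations:
        Laplacian smoothing passes applied to the marching-cubes surface
        before area measurement (0 disables); raw staircase surfaces
        overestimate area and break the convex-baseline identity.
    shape_formula_strategy:
        Named formula set for solidity/convexity/concavity index; see
        :mod:`frailsvd.wmh`.
    """

    prob_threshold: float = 0.10
    pv_distance_mm: float = 10.0
    connectivity: int = 26
    min_lesion_voxels: int = 2
    fd_box_sizes: tuple[int, ...] = (1, 2, 4, 8, 16)
    smooth_iterations: int = 20
    smooth_lambda: float = 0.5
    shape_formula_strategy: str = "hull_ratio"
    cbf_constants: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self) -> None:
        if not 0 < self.prob_threshold < 1:
            raise ValueError("prob_threshold must lie in (0, 1)")
        if self.pv_distance_mm <= 0:
            raise ValueError("pv_distance_mm must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        self.fd_box_sizes = tuple(int(s) for s in self.fd_box_sizes)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["fd_box_sizes"] = list(self.fd_box_sizes)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "cbf_constants" in d and isinstance(d["cbf_constants"], dict):
            d["cbf_constants"] = AcquisitionParams(**d["cbf_constants"])
        return cls(**d)
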