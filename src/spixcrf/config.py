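"""Run configuration: every pipeline tunable with its default, plus
lossless YAML round-tripping and a provenance stamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone

import yaml

from . import __version__

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunables of the segmentation pipeline.

    Superpixel defaults follow the common parameterization for this kind of
    slice data: the candidate count is swept over 40..200 in steps of 20
    (training-set Dice selects the winner), compactness 40, 10 SLIC
    iterations; RLCP uses the four principal directions and fractal features
    four binary channels; the CRF optimizer runs at most 50 iterations.
    """

    # superpixels
    n_superpixels: int = 200
    sweep_superpixels: bool = False
    superpixel_grid: list[int] = field(default_factory=lambda: list(range(40, 201, 20)))
    compactness: float = 40.0
    slic_iters: int = 10
    max_hops: int = 2

    # features
    curvature_mode: str = "standard"        # or "as_printed"
    curvature_sigma: float = 1.0
    entropy_bins: int = 32
    lbp_points: int = 8
    lbp_radius: int = 1
    glrl_levels: int = 16
    fractal_channels: int = 4

    # structure learning
    n_draws_struct: int = 200
    lambda_struct: float = 20.0
    struct_max_iter: int = 500
    zero_tol: float = 1e-6
    graph_mode: str = "learned"             # or "rag"

    # CRF
    lambda1: float = 2.0
    lambda2: float = 1.0
    crf_max_iter: int = 50
    infer_mode: str = "icm"                 # or "exact"

    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_superpixels < 1 or self.slic_iters < 1 or self.max_hops < 1:
            raise ValueError("counts must be positive")
        if self.lambda_struct < 0 or self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalties must be >= 0")
        if self.curvature_mode not in ("standard", "as_printed"):
            raise ValueError("curvature_mode must be 'standard' or 'as_printed'")
        if self.graph_mode not in ("learned", "rag"):
            raise ValueError("graph_mode must be 'learned' or 'rag'")
        if self.infer_mode not in ("icm", "exact"):
            raise ValueError("infer_mode must be 'icm' or 'exact'")
        if self.fractal_channels != 4:
            raise ValueError("fractal feature extraction is defined for 4 channels")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "config_hash": self.config_hash(),
        }
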