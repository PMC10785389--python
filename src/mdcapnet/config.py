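"""Pipeline configuration.

All published constants of the method ship as defaults, so a zero-argument
run reproduces the published configuration: the sequence-level weights
(0.80/0.15/0.05 for precursor/mature/seed), the per-metric binarization
thresholds xi, the six fusion weights, and the semantic contribution factor
delta = 0.5.  Everything is overridable from a flat YAML document.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional

import yaml

from .types import SIMILARITY_METRICS

__all__ = ["WalkParams", "SolverParams", "EvalParams", "PipelineConfig"]


@dataclass
class WalkParams:
    """Biased second-order random-walk and skip-gram parameters.

    p is the return parameter, q the in-out parameter of the second-order
    walk; p = q = 1 reduces to an unbiased first-order walk.
    """

    p: float = 1.0
    q: float = 1.0
    dimension: int = 64
    walk_length: int = 40
    walks_per_node: int = 20
    window: int = 5
    negative: int = 5
    epochs: int = 5
    learning_rate: float = 0.25

    def validate(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("walk parameters p and q must be positive")
        if self.dimension < 2:
            raise ValueError("embedding dimension must be >= 2")
        if min(self.walk_length, self.walks_per_node, self.window, self.negative,
               self.epochs) < 1:
            raise ValueError("walk/skip-gram sizes must be >= 1")


@dataclass
class SolverParams:
    """IRLS solver parameters for the graph-regularized objective."""

    mu: float = 1.0  # diagonal of the label-fitting matrix U
    eps: float = 1e-8  # smoothing floor for the reweighted graph
    tol: float = 1e-6
    max_iter: int = 100
    row_normalize: bool = False

    def validate(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.eps <= 0 or self.tol <= 0 or self.max_iter < 1:
            raise ValueError("invalid solver parameters")


@dataclass
class EvalParams:
    folds: int = 10
    test_fraction: float = 0.2
    negative_ratio: Optional[int] = None  # None = all non-disease pairs
    random_seed: int = 0

    def validate(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.negative_ratio is not None and self.negative_ratio < 1:
            raise ValueError("negative_ratio must be >= 1")


# published defaults, in canonical metric order (seq, expr, gip, pathway, gene, tf)
_DEFAULT_XI = {"seq": 0.75, "expr": 0.91, "gip": 0.3, "pathway": 0.60,
               "gene": 0.97, "tf": 0.95}
_DEFAULT_FUSION = {"seq": 0.15, "expr": 0.1, "gip": 0.05, "pathway": 0.25,
                   "gene": 0.2, "tf": 0.25}


def _desk_scale_walks() -> WalkParams:
    # reduced sampling effort for the ~100-node graphs the pipeline runs on
    return WalkParams(dimension=32, walk_length=20, walks_per_node=10, epochs=3)


@dataclass
class PipelineConfig:
    sequence_weights: Dict[str, float] = field(
        default_factory=lambda: {"precursor": 0.80, "mature": 0.15, "seed": 0.05}
    )
    binarization_thresholds: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_XI)
    )
    fusion_weights: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FUSION)
    )
    delta: float = 0.5  # semantic contribution factor
    link_probability: float = 0.95  # imputation acceptance cutoff pi
    embedding: WalkParams = field(default_factory=_desk_scale_walks)
    solver: SolverParams = field(default_factory=SolverParams)
    evaluation: EvalParams = field(default_factory=EvalParams)
    imputation_enabled: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, weights in (("sequence_weights", self.sequence_weights),
                              ("fusion_weights", self.fusion_weights)):
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"{name} must be nonnegative")
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {sum(weights.values())})")
        if set(self.fusion_weights) != set(SIMILARITY_METRICS):
            raise ValueError("fusion_weights must cover exactly the six metrics")
        if set(self.binarization_thresholds) != set(SIMILARITY_METRICS):
            raise ValueError("binarization_thresholds must cover the six metrics")
        for m, xi in self.binarization_thresholds.items():
            if not 0 < xi < 1:
                raise ValueError(f"threshold for {m!r} must be in (0,1), got {xi}")
        if not 0 < self.delta < 1:
            raise ValueError("delta must be in (0, 1)")
        if not 0 < self.link_probability <= 1:
            raise ValueError("link_probability must be in (0, 1]")
        self.embedding.validate()
        self.solver.validate()
        self.evaluation.validate()

    # -- flat YAML round trip ------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (("embedding", WalkParams), ("solver", SolverParams),
                         ("evaluation", EvalParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
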