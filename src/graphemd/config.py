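"""Pipeline configuration: a flat YAML document plus CLI overrides."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All knobs of the prepare/distances/analyze pipeline.

    ``thresholds`` are the distance cutoffs at which the matrix is
    binarized and clusters are read off (presets 0.075 and 0.1);
    ``outlier_k`` the number of standard deviations for the outlier rule;
    ``epsilon_floor``, when set, floors non-positive expression instead of
    erroring. CLI flags override any value loaded from file.
    """

    network: str | None = None
    expression: str | None = None
    labels: str | None = None
    out_dir: str = "graphemd_out"
    dedup_policy: str = "error"
    epsilon_floor: float | None = None
    thresholds: list[float] = field(default_factory=lambda: [0.075, 0.1])
    outlier_k: float = 2.0
    solver: str = "highs"
    seed: int = 42
    workers: int = 1
    heatmap_order: str = "input"

    def __post_init__(self):
        if any(t <= 0 for t in self.thresholds):
            raise ValueError("thresholds must be positive")

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "PipelineConfig":
        """Build from an optional YAML file; non-None overrides win."""
        data: dict = {}
        if path is not None:
            with open(path) as fh:
                loaded = yaml.safe_load(fh) or {}
            known = {f.name for f in fields(cls)}
            unknown = set(loaded) - known
            if unknown:
                raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
            data.update(loaded)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def digest(self) -> str:
        """Stable hash of the configuration, for run logs."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
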