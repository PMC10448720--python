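"""Pipeline configuration.

Defaults follow the published analysis choices: BH FDR 0.15, Butina
similarity cutoff 0.70, classification threshold 0.5, and an eleven-decade
concentration grid from 1 pM to 100 mM.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class PipelineConfig:
    curve_fits: Optional[str] = None
    labels: Optional[str] = None
    ke_map: Optional[str] = None
    css: Optional[str] = None
    smiles: Optional[str] = None

    points_per_decade: int = 10
    fdr: float = 0.15
    ke_aggregation: str = "mean"  # or "sum-rescaled"
    similarity_cutoff: float = 0.70
    unrealizable_threshold: float = 0.05
    logistic_C: float = 1.0
    logistic_penalize: bool = True
    threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.points_per_decade < 1:
            raise ValueError("points_per_decade must be >= 1")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError("fdr must lie in [0, 1]")
        if self.ke_aggregation not in ("mean", "sum-rescaled"):
            raise ValueError("ke_aggregation must be 'mean' or 'sum-rescaled'")
        if not 0.0 <= self.similarity_cutoff <= 1.0:
            raise ValueError("similarity_cutoff must lie in [0, 1]")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Stable digest of the configuration for the run manifest."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the master seed and the stage name."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:8], "big") % (2**31)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**raw)
        config.validate()
        return config
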