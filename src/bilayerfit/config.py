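"""Run configuration: defaults, YAML round-trip, and reproducibility hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    """Pipeline-wide parameters; defaults match the reference analysis
    conventions (Δ error model, χ² cutoff, 50% equilibration discard)."""

    bin_width: float = 0.25  # Å
    qz_max: float = 0.8  # Å⁻¹
    qz_step: float = 0.005  # Å⁻¹
    delta_breakpoint: float = 0.6  # Å⁻¹
    delta_low: float = 0.05
    delta_high: float = 0.1
    cutoff: float = 3.4
    analysis_fraction: float = 0.5  # fraction of frames discarded as equilibration
    water_density: float = 0.333  # e/Å³
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Short stable hash of the configuration, for run logging."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
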