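"""Shared pipeline configuration with the study's default constants."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    """Defaults for every stage of the PB analysis pipeline.

    identity_cutoff_matrix : % — pairs at or above are excluded from
        substitution-matrix estimation (strict <)
    identity_cutoff_indels : % — same rule for the indel survey
    conserved_distance : angstrom — aligned C-alpha pairs within this are the
        conserved core
    gap_penalty : per gap position in PB Smith-Waterman alignment
    pseudocount : added to every substitution count cell
    accessibility_cutoffs : % RSA thresholds for burial classification
    z_threshold : di-PBs with Z above this are preferred indel sites
    tie_tolerance : angstrom — |delta rmsd| treated as "same" in benchmarks
    """

    identity_cutoff_matrix: float = 40.0
    identity_cutoff_indels: float = 80.0
    conserved_distance: float = 3.0
    gap_penalty: float = -5.0
    pseudocount: float = 1.0
    accessibility_cutoffs: tuple[float, ...] = (7.0, 15.0, 25.0)
    stratified_cutoff: float = 25.0
    exposed_min_residues: int = 3
    min_flank: int = 3
    z_threshold: float = 2.0
    tie_tolerance: float = 0.01
    min_resolution: float | None = 2.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("identity_cutoff_matrix", "identity_cutoff_indels",
                     "conserved_distance", "pseudocount", "z_threshold",
                     "tie_tolerance"):
            if getattr(self, name) is not None and getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.conserved_distance <= 0:
            raise ValueError("conserved-core distance must be positive")
        if self.min_flank < 1:
            raise ValueError("min_flank must be at least 1")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        payload["accessibility_cutoffs"] = list(self.accessibility_cutoffs)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        payload["accessibility_cutoffs"] = tuple(payload.get(
            "accessibility_cutoffs", cls.accessibility_cutoffs))
        return cls(**payload)
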