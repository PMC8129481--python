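"""Flat YAML run configuration shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All stage defaults in one place.

    Defaults follow the published analysis where a value is stated there:
    67% replicate presence (as 4-of-6, i.e. 2/3), 2 peptides minimum, BH
    FDR, genome-wide significance 5e-8, clumping r^2 0.1, and Bonferroni
    denominators 3283 (aptamer panel) and 41 (cytokine panel).
    """

    # LFQ stage
    lfq_presence_frac: float = 2.0 / 3.0
    lfq_min_peptides: int = 2
    lfq_impute_percentile: float = 1.0
    lfq_log_transform: bool = True
    lfq_q_discovery: float = 1e-4
    lfq_alpha: float = 0.05
    # PRM stage
    prm_r2_qc: float = 0.98
    prm_weighting: str | None = None
    # MR stage
    mr_p_threshold: float = 5e-8
    mr_r2_threshold: float = 0.1
    mr_alpha: float = 0.05
    mr_m_somascan: int = 3283
    mr_m_cytokine: int = 41
    mr_random_effects: bool = False
    # run plumbing
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
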