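"""Pipeline configuration: every tunable with its default, range-checked.

The defaults are the method's published operating point: QC at 1000
genes/cell and mito fraction < 0.30, gene filter at mean log expression
> 4.5, clipping at +/-3, 100-gene moving average, +/-0.15 noise floor
and arm-event threshold, 15-cell donor-balanced reference sampling,
top-2/3 position selection with k=15 graph clustering for subclones,
top-20% metrics with median+2SD cutoffs for classification, and the two
DE thresholds (log2FC > 0.5 with Bonferroni-adjusted p < 0.05;
log2FC >= 1 with raw p < 0.05).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    qc_min_genes: int = 1000
    qc_max_mito: float = 0.30
    gene_expr_cutoff: float = 4.5
    clip_bound: float = 3.0
    window: int = 100
    noise_floor: float = 0.15
    ref_min_cells: int = 15
    ref_sample_n: int = 15
    subclone_fraction: float = 2.0 / 3.0
    k_neighbors: int = 15
    arm_threshold: float = 0.15
    top_gene_frac: float = 0.2
    top_cell_frac: float = 0.2
    sd_multiplier: float = 2.0
    de_lfc_min: float = 0.5
    de_alpha: float = 0.05
    recurrent_lfc_min: float = 1.0
    recurrent_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.qc_min_genes >= 0, "qc_min_genes must be >= 0"),
            (0 <= self.qc_max_mito <= 1, "qc_max_mito must be in [0, 1]"),
            (self.clip_bound > 0, "clip_bound must be > 0"),
            (self.window >= 1, "window must be >= 1"),
            (self.noise_floor > 0, "noise_floor must be > 0"),
            (self.ref_sample_n >= 1, "ref_sample_n must be >= 1"),
            (
                self.ref_sample_n <= self.ref_min_cells,
                "ref_sample_n must be <= ref_min_cells",
            ),
            (0 < self.subclone_fraction <= 1, "subclone_fraction must be in (0, 1]"),
            (self.k_neighbors >= 1, "k_neighbors must be >= 1"),
            (self.arm_threshold > 0, "arm_threshold must be > 0"),
            (0 < self.top_gene_frac <= 1, "top_gene_frac must be in (0, 1]"),
            (0 < self.top_cell_frac <= 1, "top_cell_frac must be in (0, 1]"),
            (self.sd_multiplier >= 0, "sd_multiplier must be >= 0"),
            (0 < self.de_alpha <= 1, "de_alpha must be in (0, 1]"),
            (0 < self.recurrent_alpha <= 1, "recurrent_alpha must be in (0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the global seed and the stage name.

        Stable across stage reordering; always below 2**31.
        """
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_dict(json.loads(Path(path).read_text()))


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")
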