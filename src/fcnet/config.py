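"""Pipeline configuration with YAML round-tripping.

Defaults reproduce the study conditions the pipeline targets: a 112-node
parcellation, automatic group-level sparsity selection plus an 8-26% grid
in 1% steps for range analyses, 10,000-permutation nulls, residualise-then-
rectify edge processing, the subgraph local-efficiency form, rank-sum
comparison of node-averaged metrics, a 2.5-MAD outlier screen, and FDR
q = 0.05 over the 16-subtest family.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = ["PipelineConfig", "default_sparsity_grid"]


def default_sparsity_grid() -> list[float]:
    """8% to 26% inclusive in 1% steps (19 levels)."""
    return [round(float(s), 2) for s in np.arange(0.08, 0.2601, 0.01)]


@dataclass
class PipelineConfig:
    # paths
    timeseries_dir: str = "timeseries"
    subject_table: str = "subjects.tsv"
    node_table: str | None = None  # None -> packaged 112-region table
    output_dir: str = "results"
    # sparsity handling
    sparsity_mode: str = "auto_select"  # {"auto_select", "fixed", "range"}
    fixed_sparsity: float = 0.262
    sparsity_grid: list[float] = field(default_factory=default_sparsity_grid)
    # statistics
    n_perm: int = 10_000
    master_seed: int = 0
    global_test: str = "ranksum"  # {"ranksum", "t"}
    fdr_q: float = 0.05
    mad_multiplier: float = 2.5
    # processing switches
    residualize_before_rectify: bool = True
    eloc_variant: str = "subgraph"  # {"subgraph", "toolbox"}

    def validate(self) -> None:
        if self.sparsity_mode not in ("auto_select", "fixed", "range"):
            raise ValueError(f"unknown sparsity_mode {self.sparsity_mode!r}")
        if self.global_test not in ("ranksum", "t"):
            raise ValueError(f"unknown global_test {self.global_test!r}")
        if self.eloc_variant not in ("subgraph", "toolbox"):
            raise ValueError(f"unknown eloc_variant {self.eloc_variant!r}")
        if not 0 < self.fixed_sparsity <= 1:
            raise ValueError("fixed_sparsity must be in (0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")
        if list(self.sparsity_grid) != sorted(set(self.sparsity_grid)):
            raise ValueError("sparsity_grid must be strictly increasing")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def content_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
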