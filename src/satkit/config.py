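"""Pipeline configuration: the handful of constants the whole analysis hangs on.

Defaults encode the study conditions: annotate monomer variants up to 45%
divergence from the consensus, bin landscapes at 1% divergence, call peaks at
50% above neighboring bins, extract 1,000-bp flanks, count reads at a single
mismatch against the dimer, subsample 100 monomers for phylogenies, and
require query coverage strictly exceeding 50% for taxonomic presence.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

logger = logging.getLogger("satkit")


@dataclass
class PipelineConfig:
    max_divergence: float = 0.45
    bin_width: float = 0.01
    peak_factor: float = 1.5
    flank_length: int = 1000
    mismatch_limit: int = 1
    subsample_n: int = 100
    coverage_threshold: float = 0.5
    rng_seed: int = 0
    # secondary knobs (documented in docs/methods.md)
    gap_tolerance: int | None = None  # None -> 1 x monomer length per family
    peak_rule: str = "prominence"  # or "adjacent"
    clade_age_bound: float | None = None  # upper bound (MY) for single-taxon families
    tree_dialect: str = "branch_lengths"  # or "node_labels"

    def __post_init__(self) -> None:
        if not 0 <= self.max_divergence <= 1:
            raise ValueError("max_divergence must be in [0, 1]")
        if not 0 < self.bin_width <= 1:
            raise ValueError("bin_width must be in (0, 1]")
        if self.peak_factor <= 0:
            raise ValueError("peak_factor must be positive")
        if self.flank_length <= 0:
            raise ValueError("flank_length must be positive")
        if self.mismatch_limit < 0:
            raise ValueError("mismatch_limit must be >= 0")
        if self.subsample_n <= 0:
            raise ValueError("subsample_n must be positive")
        if not 0 <= self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must be in [0, 1]")
        if self.peak_rule not in ("prominence", "adjacent"):
            raise ValueError("peak_rule must be 'prominence' or 'adjacent'")
        if self.tree_dialect not in ("branch_lengths", "node_labels"):
            raise ValueError("tree_dialect must be 'branch_lengths' or 'node_labels'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config; keyword arguments (e.g. CLI flags) override keys."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.log_resolved()
        return cfg

    def log_resolved(self) -> None:
        """Echo the fully resolved configuration (reproducibility contract)."""
        logger.info("resolved config: %s", dataclasses.asdict(self))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
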