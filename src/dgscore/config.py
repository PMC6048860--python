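"""Pipeline configuration: every tunable threshold with its default.

Defaults mirror the published analysis settings: segmentation calls gains at
mean log2-ratio >= +0.15 and losses at <= -0.15, segments are kept only when
their FDR-adjusted significance is <= 1e-05, span >= 1 kb and >= 10 probes,
a region is recurrent when altered in >= 10% of patients (ceil rule), the
expression-concordance Welch test uses one-sided alpha 0.05, patient altered
gene sets take the top 100 + bottom 100 cross-sample ranks, common AGS
membership needs recurrence in >= 5 patients, drivers are called at NEA
z > 2, and the bootstrap uses 50 replicates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from dgscore.errors import InvalidConfigError


@dataclass
class PipelineConfig:
    # segmentation & CNA filtering
    gain_threshold: float = 0.15
    loss_threshold: float = -0.15
    max_fdr: float = 1e-05
    min_length_bp: int = 1000
    min_probes: int = 10
    recurrence_fraction: float = 0.10
    penalty: float = 3.0  # multiplier on sigma^2 * log(n) in the changepoint search

    # gene sets
    concordance_alpha: float = 0.05
    ags_top_n: int = 100
    common_ags_min_recurrence: int = 5

    # network enrichment
    nea_null_kind: str = "hypergeometric"  # or degree_product / edge_permutation
    nea_n_permutations: int = 1000
    z_threshold: float = 2.0
    ags_pooling: str = "union"  # pooled-union common AGS vs separate-then-union

    # scoring / survival
    dgscore_mode: str = "all"
    dgscore_continuous: bool = False

    # bootstrap
    bootstrap_B: int = 50
    bootstrap_p_null: Optional[float] = None  # None -> observed drivers / annotated genes

    seed: int = 0

    # file paths (optional; used by the CLI / run_pipeline)
    probe_map: Optional[str] = None
    log_ratios: Optional[str] = None
    expression: Optional[str] = None
    gene_annotation: Optional[str] = None
    network: Optional[str] = None
    clinical: Optional[str] = None
    literature_genes: Optional[str] = None
    outdir: Optional[str] = None

    def validate(self) -> "PipelineConfig":
        if not (self.gain_threshold > 0 > self.loss_threshold):
            raise InvalidConfigError("need gain_threshold > 0 > loss_threshold")
        if not (0 < self.recurrence_fraction < 1):
            raise InvalidConfigError("recurrence_fraction must lie in (0,1)")
        if not (0 < self.concordance_alpha < 1):
            raise InvalidConfigError("concordance_alpha must lie in (0,1)")
        if self.ags_top_n < 1 or self.common_ags_min_recurrence < 1:
            raise InvalidConfigError("AGS sizes must be positive")
        if self.nea_null_kind not in ("hypergeometric", "degree_product", "edge_permutation"):
            raise InvalidConfigError(f"unknown null kind {self.nea_null_kind!r}")
        if self.bootstrap_B < 1:
            raise InvalidConfigError("bootstrap_B must be >= 1")
        if self.penalty <= 0:
            raise InvalidConfigError("penalty must be positive")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Short stable digest of the configuration, stamped into outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text) or {}
        return cls.from_dict(d)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
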