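"""Pipeline configuration: every threshold the analysis uses, in one place.

Defaults equal the screen's published operating points (0.1 tpm expression
floor; cpm floors 5 and 1; >= 3 guides per TSS; hit FDR < 0.1; stringent
non-hit FDR > 0.9 with >= 9 guides; BH FDR 0.10 for feature comparisons;
k = 2 clusters; 400/100/1000 bp and 1 Mb windows; 10 guides per TSS;
500 x 10 scrambled controls). Everything is overridable from YAML and the
resolved config is echoed into every output directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class PipelineConfig:
    # expression
    tpm_threshold: float = 0.1
    expression_mode: str = "lineage_mean"  # or "any_sample"
    # filtering
    day0_cpm_min: float = 5.0
    undiff_cpm_min: float = 1.0
    min_guides_per_tss: int = 3
    # hit calling
    fdr_hit: float = 0.1
    fdr_stringent_nonhit: float = 0.9
    min_stringent_guides: int = 9
    pseudocount: float = 0.5
    robust_null: bool = False
    em_restarts: int = 5
    # feature comparison
    bh_fdr: float = 0.10
    # clustering
    k_clusters: int = 2
    kmeans_restarts: int = 10
    # windows (bp)
    cage_tss_assign_window: int = 400
    cage_count_window: int = 100
    promoter_window: int = 1000
    enhancer_window: int = 1_000_000
    # library design
    guides_per_tss: int = 10
    n_scramble_seeds: int = 500
    n_per_seed: int = 10
    promoter_rule_partner: str = "tss"  # or "gene_start"
    # seeds
    rng_seed: int = 0
    # stage toggles
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "expression": True, "library": True,
        "screen": True, "features": True, "cluster": True,
    })

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
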