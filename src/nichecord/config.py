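"""Pipeline configuration.

Defaults follow common Visium-scale practice: counts-per-10,000 natural
log1p normalization, spot QC at 5000 < total < 35,000 with <= 20%
mitochondrial reads and genes detected in >= 10 spots, 2000 highly
variable genes, 1000-permutation ligand-receptor test at alpha 0.05, and
10 subsampled datasets for the cell-count control.  Every value is a
plain attribute so CLI flags and YAML files can override any of them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # normalization
    target_sum: float = 1e4
    log_base: str = "e"  # {"e", "2"}

    # spot QC
    qc_min_counts: float = 5000
    qc_max_counts: float = 35000
    qc_max_mito_pct: float = 20.0
    qc_min_spots_per_gene: int = 10
    mito_prefix: str = "MT-"

    # gene selection
    n_hvg: int = 2000
    mapping_n_hvg: int = 500
    gene_scope: str = "all"  # cosine/DEG scope: {"all", "hvg"}

    # mapping
    mapping_cost: str = "pearson"  # {"pearson", "spearman"}
    mapping_greedy: bool = False

    # spatial grouping
    group_mode: str = "region"  # {"region", "scoexp"}
    focal_type: str | None = None
    scoexp_sigma: float | None = None  # None -> median pairwise distance
    scoexp_k: int = 3
    scoexp_min_module_size: int = 10
    scoexp_n_hvg: int = 100
    score_n_bins: int = 24
    score_n_controls: int = 100

    # differential expression
    fc_threshold: float = 1.5        # Wilcoxon gate, linear scale
    lfc_threshold: float = 1.5       # pseudobulk gate, log2 scale
    alpha: float = 0.05
    n_pseudoreps: int = 3
    deg_methods: tuple = ("wilcoxon", "pseudobulk")

    # cell-cell communication
    n_permutations: int = 1000
    expr_prop: float = 0.1
    min_cells: int = 10
    direction_mode: str = "both_summed"
    include_sibling: bool = True
    include_autocrine: bool = True

    # subsampling control
    run_subsampling: bool = True
    n_subsample_datasets: int = 10

    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("target_sum", "fc_threshold", "lfc_threshold", "expr_prop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_hvg", "n_permutations", "n_pseudoreps", "n_subsample_datasets",
                     "min_cells", "scoexp_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.log_base not in ("e", "2"):
            raise ValueError("log_base must be 'e' or '2'")
        self.seed = int(self.seed)
        self.deg_methods = tuple(self.deg_methods)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["deg_methods"] = list(d["deg_methods"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)
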