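"""Simulation and pipeline configuration objects.

``SimConfig`` holds every knob of the synthetic-data generators; the defaults
define the desk-scale study conditions used by the end-to-end demo. All
validation happens in ``validate()`` / ``__post_init__`` so downstream code can
assume a consistent configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import List, Tuple


class ConfigError(ValueError):
    """Raised for invalid configuration values (with field-level messages)."""


@dataclass
class SimConfig:
    seed: int = 0

    # --- gene annotation / atlas ---
    n_genes: int = 2000
    n_clusters: int = 12
    n_superclusters: int = 4
    n_dissections: int = 8
    marker_frac: float = 0.12       # fraction of genes that are cluster markers
    marker_fold: float = 8.0        # fold-change of marker mean in home cluster
    n_chroms: int = 8               # chr1..chr{n_chroms}, must be <= 22
    chrom_length: int = 20_000_000  # bp per synthetic chromosome
    emhc_frac: float = 0.05         # fraction of genes flagged extended-MHC
    noncoding_frac: float = 0.05    # fraction with a non-protein-coding biotype
    clumped: bool = False           # place TSS in clumps (co-occurrence tests)
    clump_size: int = 5             # genes per clump when clumped
    neuronal_frac: float = 0.6      # fraction of superclusters labeled neuronal
    nb_dispersion: float = 10.0     # NB shape; aggregated pseudobulk counts
                                    # over many nuclei are only mildly overdispersed
    mean_depth: float = 50.0        # mean baseline counts per gene per cluster
    cells_per_dissection: int = 2000
    alpha_neuronal: float = 0.3     # Dirichlet concentration, neuronal clusters
    alpha_nonneuronal: float = 5.0  # Dirichlet concentration, non-neuronal
    dissection_bias: float = 8.0    # home-dissection boost for neuronal clusters

    # --- GWAS / haplotype panel ---
    n_snps: int = 5000
    n_individuals: int = 2000
    n_panel: int = 400              # reference-panel sample size for LD scores
    ld_block_size: int = 10         # SNPs per independent LD block
    block_rho: float = 0.5          # within-block genotype correlation
    h2: float = 0.3                 # total SNP-heritability of the trait
    enrich_tau: float = 1.0         # per-SNP variance multiplier inside annotation

    # --- fMRI ---
    n_rois: int = 20
    ts_length: int = 120
    n_cases: int = 24
    n_controls: int = 24
    delta_pairs: List[Tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        errs = []
        for name in ("n_genes", "n_clusters", "n_superclusters", "n_dissections",
                     "n_snps", "n_individuals", "n_panel", "ld_block_size",
                     "n_rois", "ts_length", "n_cases", "n_controls",
                     "chrom_length", "clump_size", "cells_per_dissection"):
            if getattr(self, name) <= 0:
                errs.append(f"{name}: must be > 0, got {getattr(self, name)}")
        if self.n_clusters < self.n_superclusters:
            errs.append("n_clusters: must be >= n_superclusters")
        for name in ("marker_frac", "emhc_frac", "noncoding_frac", "neuronal_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name}: must be in [0, 1], got {v}")
        if not 1 <= self.n_chroms <= 22:
            errs.append(f"n_chroms: must be in [1, 22], got {self.n_chroms}")
        if not 0.0 <= self.block_rho < 1.0:
            errs.append(f"block_rho: must be in [0, 1), got {self.block_rho}")
        if not 0.0 < self.h2 < 1.0:
            errs.append(f"h2: must be in (0, 1), got {self.h2}")
        if self.enrich_tau < 0:
            errs.append(f"enrich_tau: must be >= 0, got {self.enrich_tau}")
        if self.marker_fold <= 0:
            errs.append(f"marker_fold: must be > 0, got {self.marker_fold}")
        for pair in self.delta_pairs:
            i, j, _ = pair
            if not (0 <= i < self.n_rois and 0 <= j < self.n_rois and i != j):
                errs.append(f"delta_pairs: invalid ROI pair {pair} for n_rois={self.n_rois}")
        if errs:
            raise ConfigError("; ".join(errs))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["delta_pairs"] = [list(p) for p in self.delta_pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "delta_pairs" in d:
            d["delta_pairs"] = [tuple(p) for p in d["delta_pairs"]]
        return cls(**d)


@dataclass
class ClassifierConfig:
    """Connectivity classifier settings (spec: cross-entropy training + AUC eval).

    ``backend`` is 'mlp' (2-hidden-layer feed-forward net) or 'logistic'.
    """
    backend: str = "mlp"
    hidden: Tuple[int, int] = (16, 8)
    max_iter: int = 400
    alpha: float = 1e-3           # L2 penalty
    learning_rate: float = 1e-3   # MLP only
    seed: int = 0

    def __post_init__(self):
        if self.backend not in ("mlp", "logistic"):
            raise ConfigError(f"backend: must be 'mlp' or 'logistic', got {self.backend!r}")
        if self.max_iter <= 0:
            raise ConfigError("max_iter: must be > 0")


@dataclass
class PipelineConfig:
    """Top-level pipeline configuration (validated before any stage runs)."""
    seed: int = 0
    out_dir: str = "pipeline_out"
    log_level: str = "INFO"
    sim: SimConfig = field(default_factory=SimConfig)
    window_kb: float = 100.0
    ld_window_snps: int = 50
    n_jackknife_blocks: int = 100
    exclude_dissections: List[str] = field(default_factory=list)
    bin_kb: float = 100.0
    n_folds: int = 3
    n_permutations: int = 100
    min_rois: int = 2
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def validate(self) -> None:
        errs = []
        if self.seed is None:
            errs.append("seed: required")
        if self.window_kb < 0:
            errs.append("window_kb: must be >= 0")
        if self.ld_window_snps <= 0:
            errs.append("ld_window_snps: must be > 0")
        if self.n_jackknife_blocks < 2:
            errs.append("n_jackknife_blocks: must be >= 2")
        if self.bin_kb <= 0:
            errs.append("bin_kb: must be > 0")
        if self.n_folds < 2:
            errs.append("n_folds: must be >= 2")
        if self.n_permutations < 2:
            errs.append("n_permutations: must be >= 2")
        if self.min_rois < 2:
            errs.append("min_rois: must be >= 2")
        try:
            self.sim.validate()
        except ConfigError as e:
            errs.append(f"sim: {e}")
        if errs:
            raise ConfigError("; ".join(errs))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        d["classifier"]["hidden"] = list(self.classifier.hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "seed" not in d:
            raise ConfigError("seed: required field is missing")
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "classifier" in d:
            cd = dict(d["classifier"])
            if "hidden" in cd:
                cd["hidden"] = tuple(cd["hidden"])
            d["classifier"] = ClassifierConfig(**cd)
        cfg = cls(**d)
        cfg.validate()
        return cfg
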