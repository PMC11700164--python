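"""Synthetic-data generators with planted ground truth.

Every downstream stage of the package consumes data produced here: a gene
annotation, a gene x cell-cluster count matrix with a cluster -> supercluster
hierarchy and dissection compositions, GWAS summary statistics with a matched
LD reference panel, and case/control ROI time series. Each generator plants a
recoverable signal (cluster marker genes, variance-enriched SNP annotations,
differential connectivity pairs) recorded in a :class:`GroundTruth` object, so
the whole chain has parameter-recovery tests.

Modelling choices (see the methods note for rationale):

* LD is block-diagonal with equicorrelated blocks; genotypes are standardized
  Gaussians. Expected LD scores then have the closed form 1 + (B-1) * rho^2.
* Counts are negative-binomial with a shared dispersion; marker genes have
  their mean multiplied by ``marker_fold`` in their home cluster.
* Dissection compositions are Dirichlet-multinomial; neuronal clusters get a
  sparse concentration plus a "home dissection" boost so they concentrate in
  one dissection, non-neuronal clusters spread evenly.
* Case covariance = control covariance with an additive shift on the planted
  ROI pairs, eigenvalue-clipped back to positive definite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig
from ._utils import stage_rng

ANNOTATION_COLUMNS = ["gene", "chrom", "start", "end", "tss", "strand", "biotype", "emhc"]


@dataclass
class GroundTruth:
    """Planted signals of a simulated dataset."""
    marker_genes: Dict[str, Set[str]] = field(default_factory=dict)
    enriched_annotation: str | None = None
    differential_pairs: List[Tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "marker_genes": {k: sorted(v) for k, v in self.marker_genes.items()},
            "enriched_annotation": self.enriched_annotation,
            "differential_pairs": [list(p) for p in self.differential_pairs],
        }


@dataclass
class HaplotypePanel:
    """Standardized reference genotypes used to estimate LD scores.

    ``genotypes`` is samples x SNPs; ``snps`` matches the sumstats SNP order.
    """
    genotypes: np.ndarray
    snps: pd.DataFrame  # columns: snp, chrom, pos

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class ConnectivityDataset:
    """Per-subject ROI time series with case/control labels."""
    series: List[np.ndarray]        # each (ts_length, n_rois)
    labels: np.ndarray              # 1 = case, 0 = control
    subject_ids: List[str]
    roi_meta: pd.DataFrame          # columns: roi, name, group, hemisphere

    @property
    def n_rois(self) -> int:
        return self.series[0].shape[1]

    @property
    def n_subjects(self) -> int:
        return len(self.series)


# ---------------------------------------------------------------------------
# gene annotation


def generate_gene_annotation(config: SimConfig) -> pd.DataFrame:
    """Simulate a BED-like gene annotation table.

    Genes are placed on chr1..chr{n_chroms} with 0-based half-open [start, end)
    coordinates, a TSS at the strand-appropriate end, a biotype, and an
    extended-MHC flag on a configurable fraction. With ``clumped=True`` genes
    are placed in clumps of several TSS per 100 kb to exercise the genomic
    co-occurrence analysis.
    """
    config.validate()
    rng = stage_rng(config.seed, "annotation")
    n = config.n_genes
    chroms = np.array([f"chr{i + 1}" for i in range(config.n_chroms)])
    chrom_idx = rng.integers(0, config.n_chroms, size=n)

    lengths = rng.integers(2_000, 100_000, size=n)
    max_start = config.chrom_length - lengths - 1
    if np.any(max_start <= 0):
        raise ConfigError("chrom_length too small for simulated gene lengths")
    if config.clumped:
        n_clumps = max(1, n // config.clump_size)
        centers = rng.integers(0, config.chrom_length - 200_000, size=(config.n_chroms, n_clumps))
        clump_of_gene = rng.integers(0, n_clumps, size=n)
        offsets = rng.integers(0, 50_000, size=n)
        starts = centers[chrom_idx, clump_of_gene] + offsets
        starts = np.minimum(starts, max_start)
    else:
        starts = (rng.random(n) * max_start).astype(np.int64)
    ends = starts + lengths
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    tss = np.where(strands == "+", starts, ends - 1)
    emhc = rng.random(n) < config.emhc_frac
    biotype = np.where(rng.random(n) < config.noncoding_frac, "lncRNA", "protein_coding")

    ann = pd.DataFrame(
        {
            "gene": [f"g{i:05d}" for i in range(n)],
            "chrom": chroms[chrom_idx],
            "start": starts.astype(np.int64),
            "end": ends.astype(np.int64),
            "tss": tss.astype(np.int64),
            "strand": strands,
            "biotype": biotype,
            "emhc": emhc,
        }
    )
    return ann.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# expression atlas


def generate_atlas(
    config: SimConfig, annotation: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a gene x cluster count matrix plus hierarchy and compositions.

    Returns ``(counts, hierarchy, composition, truth)``:

    * counts: genes x clusters negative-binomial counts; marker genes of
      cluster k have their mean multiplied by ``marker_fold`` in k.
    * hierarchy: cluster, supercluster, neuronal flag.
    * composition: cluster x dissection cell counts (Dirichlet-multinomial);
      neuronal cluster k is biased toward dissection ``k mod n_dissections``.
    * truth: marker gene sets per cluster.
    """
    config.validate()
    n_markers_total = int(round(config.marker_frac * config.n_genes))
    if n_markers_total < config.n_clusters:
        raise ConfigError(
            f"marker_frac x n_genes = {n_markers_total} < n_clusters = {config.n_clusters}; "
            "cannot plant at least one marker per cluster"
        )
    rng = stage_rng(config.seed, "atlas")
    if annotation is None:
        genes = [f"g{i:05d}" for i in range(config.n_genes)]
    else:
        genes = list(annotation["gene"])
        if len(genes) != config.n_genes:
            raise ConfigError("annotation does not match config.n_genes")
    clusters = [f"c{k:03d}" for k in range(config.n_clusters)]

    # baseline per-gene mean expression, lognormal across genes
    base_mean = config.mean_depth * rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    mu = np.tile(base_mean[:, None], (1, config.n_clusters))

    marker_idx = rng.choice(config.n_genes, size=n_markers_total, replace=False)
    home = np.arange(n_markers_total) % config.n_clusters
    mu[marker_idx, home] *= config.marker_fold

    # NB with shape r: variance mu + mu^2/r
    r = config.nb_dispersion
    counts = rng.negative_binomial(n=r, p=r / (r + mu))
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=clusters)

    # hierarchy: clusters assigned round-robin to superclusters; a supercluster
    # is neuronal if its index falls in the first neuronal_frac share
    super_of = np.arange(config.n_clusters) % config.n_superclusters
    n_neuronal_sc = int(round(config.neuronal_frac * config.n_superclusters))
    neuronal_sc = np.zeros(config.n_superclusters, dtype=bool)
    neuronal_sc[:n_neuronal_sc] = True
    hierarchy = pd.DataFrame(
        {
            "cluster": clusters,
            "supercluster": [f"sc{super_of[k]:02d}" for k in range(config.n_clusters)],
            "neuronal": neuronal_sc[super_of],
        }
    )

    # dissection compositions; neuronal cluster with neuronal rank r is biased
    # toward its home dissection r mod n_dissections (dissection-specific
    # neuronal composition), non-neuronal clusters spread evenly
    comp = np.zeros((config.n_clusters, config.n_dissections), dtype=np.int64)
    neuronal_cluster = hierarchy["neuronal"].to_numpy()
    home_dissection = np.full(config.n_clusters, -1)
    home_dissection[neuronal_cluster] = (
        np.arange(int(neuronal_cluster.sum())) % config.n_dissections
    )
    for d in range(config.n_dissections):
        alpha = np.where(neuronal_cluster, config.alpha_neuronal, config.alpha_nonneuronal).astype(float)
        alpha = np.where(home_dissection == d, config.alpha_neuronal * config.dissection_bias, alpha)
        w = rng.dirichlet(alpha)
        comp[:, d] = rng.multinomial(config.cells_per_dissection, w)
    composition = pd.DataFrame(
        comp,
        index=pd.Index(clusters, name="cluster"),
        columns=[f"d{d:02d}" for d in range(config.n_dissections)],
    )

    truth = GroundTruth(
        marker_genes={
            clusters[k]: {genes[g] for g, h in zip(marker_idx, home) if h == k}
            for k in range(config.n_clusters)
        }
    )
    return counts_df, hierarchy, composition, truth


# ---------------------------------------------------------------------------
# GWAS


def _draw_block_genotypes(
    rng: np.random.Generator, n: int, m: int, block: int, rho: float
) -> np.ndarray:
    """Standardized genotypes with equicorrelated LD blocks (corr rho).

    Mixing is done in place on a (n, n_blocks, block) view to avoid large
    temporaries (the matrices reach hundreds of MB at study sizes).
    """
    n_blocks = int(np.ceil(m / block))
    m_pad = n_blocks * block
    shared = rng.standard_normal((n, n_blocks), dtype=np.float32)
    x = rng.standard_normal((n, m_pad), dtype=np.float32)
    xv = x.reshape(n, n_blocks, block)
    xv *= np.sqrt(1.0 - rho, dtype=np.float32)
    xv += np.sqrt(rho, dtype=np.float32) * shared[:, :, None]
    return np.ascontiguousarray(x[:, :m]) if m_pad != m else x


def _snp_table(config: SimConfig) -> pd.DataFrame:
    """Evenly spaced SNP map over the synthetic chromosomes."""
    m = config.n_snps
    per_chrom = int(np.ceil(m / config.n_chroms))
    spacing = max(1, config.chrom_length // (per_chrom + 1))
    idx = np.arange(m)
    chrom = np.array([f"chr{i // per_chrom + 1}" for i in idx])
    pos = (idx % per_chrom + 1) * spacing
    return pd.DataFrame({"snp": [f"rs{j}" for j in idx], "chrom": chrom, "pos": pos})


def simulate_sumstats(
    config: SimConfig,
    membership: np.ndarray,
    rng: np.random.Generator,
    snps: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One GWAS realisation: effects, phenotype and marginal z-scores.

    Causal effects are N(0, sigma2) for background SNPs and
    N(0, enrich_tau * sigma2) inside the annotation, rescaled so the realised
    genetic variance equals h2; phenotype noise has variance 1 - h2. Marginal
    z-scores come from per-SNP simple regression.
    """
    m = config.n_snps
    membership = np.asarray(membership, dtype=bool)
    if membership.shape != (m,):
        raise ValueError(f"membership must index SNPs 1..{m}")
    x = _draw_block_genotypes(rng, config.n_individuals, m, config.ld_block_size, config.block_rho)
    var = np.where(membership, config.enrich_tau, 1.0)
    beta = rng.standard_normal(m) * np.sqrt(var)
    g = x @ beta.astype(np.float32)
    g_var = g.var()
    if g_var <= 0:
        raise ValueError("degenerate genetic values (zero variance)")
    g *= np.sqrt(config.h2 / g_var)
    y = g + rng.standard_normal(config.n_individuals).astype(np.float32) * np.sqrt(1.0 - config.h2)

    # per-SNP simple regression z-scores via correlations (single-pass
    # moments; the genotype matrix is large at study sizes)
    n = config.n_individuals
    s1 = x.sum(axis=0, dtype=np.float64)
    s2 = np.einsum("ij,ij->j", x, x, dtype=np.float64)
    xm = s1 / n
    xs = np.sqrt(np.maximum(s2 / n - xm**2, 1e-12))
    ym = y.mean()
    ys = y.std()
    r = (x.T @ y / n - xm * ym) / (xs * ys)
    r = np.clip(r, -0.999999, 0.999999)
    z = r * np.sqrt((n - 2) / (1.0 - r**2))

    tab = snps.copy() if snps is not None else _snp_table(config)
    tab["a1"] = "A"
    tab["a2"] = "G"
    tab["z"] = z.astype(float)
    tab["n"] = n
    return tab


def generate_gwas(
    config: SimConfig, annotation_snps: np.ndarray
) -> tuple[pd.DataFrame, HaplotypePanel]:
    """Simulate GWAS summary statistics plus an LD reference panel.

    ``annotation_snps`` is the boolean membership vector of the enriched
    annotation (variance multiplier ``enrich_tau`` per member SNP).
    """
    config.validate()
    membership = np.asarray(annotation_snps, dtype=bool)
    if membership.shape != (config.n_snps,):
        raise ValueError(f"annotation_snps must index SNPs 1..{config.n_snps}")
    rng = stage_rng(config.seed, "gwas")
    snps = _snp_table(config)
    sumstats = simulate_sumstats(config, membership, rng, snps)
    panel_x = _draw_block_genotypes(
        rng, config.n_panel, config.n_snps, config.ld_block_size, config.block_rho
    )
    return sumstats, HaplotypePanel(genotypes=panel_x, snps=snps)


# ---------------------------------------------------------------------------
# fMRI


def _base_covariance(rng: np.random.Generator, r: int) -> np.ndarray:
    """Random well-conditioned SPD matrix with moderate off-diagonal structure."""
    a = rng.standard_normal((r, max(2, r // 4)))
    cov = a @ a.T / a.shape[1] * 0.3 + np.eye(r)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def _clip_psd(cov: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    w, v = np.linalg.eigh((cov + cov.T) / 2.0)
    if w.min() >= eps:
        return cov
    w = np.clip(w, eps, None)
    out = (v * w) @ v.T
    if np.linalg.eigvalsh(out).min() <= 0:
        raise ValueError("covariance not positive-definite after projection")
    return out


def generate_fmri(config: SimConfig) -> tuple[ConnectivityDataset, GroundTruth]:
    """Simulate case/control ROI time series.

    Controls draw i.i.d. time points from MVN(0, base); cases from the base
    covariance additively shifted on ``delta_pairs`` and projected back to
    positive definite. Planted pairs are recorded in the ground truth, and the
    involved ROIs carry the group tag "flagged" in ``roi_meta``.
    """
    config.validate()
    rng = stage_rng(config.seed, "fmri")
    r = config.n_rois
    base = _base_covariance(rng, r)
    case = base.copy()
    for i, j, delta in config.delta_pairs:
        case[i, j] += delta
        case[j, i] += delta
    case = _clip_psd(case)
    base = _clip_psd(base)

    chol_ctrl = np.linalg.cholesky(base)
    chol_case = np.linalg.cholesky(case)

    series: list[np.ndarray] = []
    labels = np.concatenate([np.ones(config.n_cases, int), np.zeros(config.n_controls, int)])
    for lab in labels:
        chol = chol_case if lab == 1 else chol_ctrl
        ts = rng.standard_normal((config.ts_length, r)) @ chol.T
        series.append(ts)
    subject_ids = [f"case{i:03d}" for i in range(config.n_cases)] + [
        f"ctrl{i:03d}" for i in range(config.n_controls)
    ]
    flagged = {i for p in config.delta_pairs for i in p[:2]}
    roi_meta = pd.DataFrame(
        {
            "roi": np.arange(r),
            "name": [f"ROI{i:02d}" for i in range(r)],
            "group": ["flagged" if i in flagged else "other" for i in range(r)],
            "hemisphere": ["L" if i < r // 2 else "R" for i in range(r)],
        }
    )
    truth = GroundTruth(differential_pairs=[(int(i), int(j)) for i, j, _ in config.delta_pairs])
    return ConnectivityDataset(series, labels, subject_ids, roi_meta), truth
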