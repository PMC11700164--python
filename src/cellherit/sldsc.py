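"""Compact stratified LD-score regression engine.

Estimates per-annotation SNP-heritability coefficients by regressing GWAS
chi-square statistics on annotation-stratified LD scores:

    E[chi2_j] = 1 + intercept + N * sum_c tau_c * l(j, c)

where l(j, c) = sum_k r2_jk a_c(k) is the annotation-stratified LD score of
SNP j. The model here is deliberately reduced: the design holds the base
annotation (all SNPs) plus the target annotation and any conditional
annotations, rather than a large baseline model. Fitting is two-step weighted
least squares with a free intercept; the standard error of the target
coefficient comes from a delete-a-block jackknife over contiguous SNP blocks,
and the one-sided enrichment p-value is the upper normal tail of
z = tau_hat / se.

The public surface is the `StratifiedLDRegression` model whose ``fit()``
returns an `SLDSCResults`, plus functional wrappers (`sldsc_fit`,
`conditional_scan`, `fdr_adjust`) and annotation/LD-score builders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_fdr
from .simulate import HaplotypePanel

BASE = "base"


@dataclass
class SnpMembership:
    """Named 0/1 SNP membership vector of one annotation."""
    name: str
    indicator: np.ndarray

    def __post_init__(self):
        self.indicator = np.asarray(self.indicator, dtype=bool)

    @property
    def n_snps(self) -> int:
        return self.indicator.size


@dataclass
class LDScoreTable:
    """Stratified LD scores plus the memberships they were computed from.

    ``scores``/``memberships`` are SNP x annotation frames; both always carry
    the 'base' annotation (all SNPs).
    """
    scores: pd.DataFrame
    memberships: pd.DataFrame
    n_monomorphic: int = 0

    @property
    def annotations(self) -> List[str]:
        return list(self.scores.columns)


@dataclass
class EnrichmentResult:
    trait: str
    annotation: str
    tau_hat: float
    se: float
    z: float
    p_one_sided: float
    enrichment_ratio: float
    conditioned_on: str | None = None
    fdr: float | None = None
    intercept: float = np.nan


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait": r.trait,
                "annotation": r.annotation,
                "tau_hat": r.tau_hat,
                "se": r.se,
                "z": r.z,
                "p_one_sided": r.p_one_sided,
                "enrichment_ratio": r.enrichment_ratio,
                "conditioned_on": r.conditioned_on,
                "fdr": r.fdr,
                "intercept": r.intercept,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# annotation construction


def build_annotation(
    tdep_genes: Iterable[str],
    annotation: pd.DataFrame,
    snps: pd.DataFrame,
    window_kb: float = 100.0,
    name: str = "annot",
) -> SnpMembership:
    """SNP membership from gene windows.

    SNP j is a member iff its position falls in [start - window, end + window)
    of any listed gene on the same chromosome (window clipped at 0).
    """
    genes = set(tdep_genes)
    if not genes:
        raise ValueError("empty gene set")
    if window_kb < 0:
        raise ValueError("window_kb must be >= 0")
    ann = annotation.set_index("gene")
    missing = genes - set(ann.index)
    if missing:
        raise ValueError(f"genes absent from annotation: {sorted(missing)[:10]}")
    sub = ann.loc[sorted(genes)]
    window = int(round(window_kb * 1000))

    member = np.zeros(len(snps), dtype=bool)
    pos = snps["pos"].to_numpy()
    chroms = snps["chrom"].to_numpy()
    for chrom, grp in sub.groupby("chrom"):
        lo = np.maximum(grp["start"].to_numpy() - window, 0)
        hi = grp["end"].to_numpy() + window
        order = np.argsort(lo)
        lo, hi = lo[order], hi[order]
        # merge overlapping intervals
        merged_lo, merged_hi = [lo[0]], [hi[0]]
        for a, b in zip(lo[1:], hi[1:]):
            if a <= merged_hi[-1]:
                merged_hi[-1] = max(merged_hi[-1], b)
            else:
                merged_lo.append(a)
                merged_hi.append(b)
        on_chrom = chroms == chrom
        p = pos[on_chrom]
        idx = np.searchsorted(np.asarray(merged_lo), p, side="right") - 1
        ok = idx >= 0
        ok[ok] &= p[ok] < np.asarray(merged_hi)[idx[ok]]
        member[on_chrom] = ok
    return SnpMembership(name=name, indicator=member)


# ---------------------------------------------------------------------------
# LD scores


def compute_ld_scores(
    panel: HaplotypePanel,
    annotations: Sequence[SnpMembership],
    window_snps: int = 50,
) -> LDScoreTable:
    """Stratified LD scores from a reference panel.

    For SNP j and annotation c, l(j, c) sums the bias-adjusted squared
    correlation r2_adj = r2 - (1 - r2)/(n - 2) over annotated SNPs within
    ``window_snps`` of j (inclusive of j itself); negative adjusted values are
    floored at 0. Monomorphic SNPs contribute 0 with a warning count.
    """
    n, m = panel.genotypes.shape
    if n < 3:
        raise ValueError("panel must have at least 3 samples")
    x = np.asarray(panel.genotypes, dtype=np.float32)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    mono = sd <= 0
    n_mono = int(mono.sum())
    if n_mono:
        warnings.warn(f"{n_mono} monomorphic SNPs contribute 0 to LD scores")
    sd_safe = np.where(mono, 1.0, sd)
    xs = (x - mu) / sd_safe
    xs[:, mono] = 0.0

    names = [BASE] + [a.name for a in annotations if a.name != BASE]
    mem = {BASE: np.ones(m, dtype=bool)}
    for a in annotations:
        if a.indicator.size != m:
            raise ValueError(f"annotation {a.name!r} length {a.indicator.size} != {m} SNPs")
        if a.name != BASE:
            mem[a.name] = a.indicator.copy()
    amat = np.column_stack([mem[c] for c in names]).astype(np.float32)

    scores = np.zeros((m, len(names)), dtype=np.float64)
    chunk = 1024
    for start in range(0, m, chunk):
        stop = min(start + chunk, m)
        lo = max(0, start - window_snps)
        hi = min(m, stop + window_snps)
        r = xs[:, start:stop].T @ xs[:, lo:hi] / n
        r2 = r**2
        r2adj = r2 - (1.0 - r2) / (n - 2)
        np.clip(r2adj, 0.0, None, out=r2adj)
        # mask pairs outside the window
        jj = np.arange(start, stop)[:, None]
        kk = np.arange(lo, hi)[None, :]
        r2adj[np.abs(jj - kk) > window_snps] = 0.0
        scores[start:stop] = r2adj.astype(np.float64) @ amat[lo:hi]
    scores[mono] = 0.0

    idx = pd.Index(panel.snps["snp"], name="snp")
    return LDScoreTable(
        scores=pd.DataFrame(scores, index=idx, columns=names),
        memberships=pd.DataFrame({c: mem[c] for c in names}, index=idx),
        n_monomorphic=n_mono,
    )


# ---------------------------------------------------------------------------
# the regression model


class StratifiedLDRegression:
    """Stratified LD-score regression of GWAS chi-square on LD scores.

    Parameters
    ----------
    sumstats : DataFrame with columns snp, z, n (chrom/pos optional).
    ld : LDScoreTable covering all sumstats SNPs.
    target : name of the annotation whose coefficient is tested.
    conditional : additional annotation names included in the design.
    n_blocks : jackknife blocks (contiguous SNP blocks).
    """

    def __init__(
        self,
        sumstats: pd.DataFrame,
        ld: LDScoreTable,
        target: str,
        conditional: Sequence[str] = (),
        n_blocks: int = 200,
        trait: str = "trait",
    ):
        self.sumstats = sumstats
        self.ld = ld
        self.target = target
        self.conditional = [c for c in conditional if c != BASE]
        self.n_blocks = int(n_blocks)
        self.trait = trait
        self._validate()

    def _validate(self) -> None:
        if self.target not in self.ld.annotations:
            raise ValueError(f"target annotation {self.target!r} not in LD table")
        for c in self.conditional:
            if c not in self.ld.annotations:
                raise ValueError(f"conditional annotation {c!r} not in LD table")
        missing = set(self.sumstats["snp"]) - set(self.ld.scores.index)
        if missing:
            raise ValueError(f"LD table does not cover {len(missing)} sumstats SNPs")
        m = len(self.sumstats)
        if m < 2 * self.n_blocks:
            raise ValueError(
                f"{m} SNPs < 2 x n_blocks = {2 * self.n_blocks}; reduce n_blocks"
            )

    def _design(self):
        ss = self.sumstats
        annots = [BASE, self.target] + self.conditional
        l = self.ld.scores.loc[ss["snp"], annots].to_numpy()
        # all-zero conditional LD-score columns carry no information; drop them
        # (conditioning on an empty annotation leaves the fit unchanged)
        keep = [0, 1] + [
            k for k in range(2, len(annots)) if l[:, k].std() > 0
        ]
        annots = [annots[k] for k in keep]
        l = l[:, keep]
        if l[:, 1].std() <= 0:
            raise ValueError(f"target annotation {self.target!r} has constant LD scores")
        nvec = ss["n"].to_numpy(dtype=float)
        chi2 = ss["z"].to_numpy(dtype=float) ** 2
        if not np.all(np.isfinite(chi2)):
            raise ValueError("non-finite z-scores in sumstats")
        x = np.column_stack([np.ones(len(ss)), l * nvec[:, None]])
        # collinearity check on the annotation columns
        cols = x[:, 1:]
        if cols.shape[1] >= 2:
            corr = np.corrcoef(cols, rowvar=False)
            hit = np.triu(np.abs(corr), k=1) > 1 - 1e-10
            if hit.any():
                ii, jj = np.where(hit)
                names = [annots[i] for i in ii] + [annots[j] for j in jj]
                raise ValueError(
                    f"singular design: collinear annotations {sorted(set(names))}"
                )
        return x, chi2, l[:, 0], annots

    @staticmethod
    def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(x * sw[:, None], y * sw, rcond=None)
        return beta

    def fit(self) -> "SLDSCResults":
        x, chi2, l_base, annots = self._design()
        m = x.shape[0]
        # step 1: LD weights only
        w = 1.0 / np.maximum(l_base, 1.0)
        beta0 = self._wls(x, chi2, w)
        # step 2: add heteroskedasticity weights from predicted E[chi2]
        pred = np.maximum(x @ beta0, 1.0)
        w2 = 1.0 / (np.maximum(l_base, 1.0) * 2.0 * pred**2)
        beta = self._wls(x, chi2, w2)

        # delete-a-block jackknife for all coefficients
        p = x.shape[1]
        edges = np.linspace(0, m, self.n_blocks + 1).astype(int)
        sw = np.sqrt(w2)
        xw = x * sw[:, None]
        yw = chi2 * sw
        xtx = xw.T @ xw
        xty = xw.T @ yw
        jack = np.empty((self.n_blocks, p))
        for b in range(self.n_blocks):
            s, e = edges[b], edges[b + 1]
            xb = xw[s:e]
            xtx_b = xtx - xb.T @ xb
            xty_b = xty - xb.T @ yw[s:e]
            jack[b] = np.linalg.solve(xtx_b, xty_b)
        jmean = jack.mean(axis=0)
        jvar = (self.n_blocks - 1) / self.n_blocks * ((jack - jmean) ** 2).sum(axis=0)
        se = np.sqrt(jvar)

        taus = dict(zip(annots, beta[1:]))
        ses = dict(zip(annots, se[1:]))
        t_idx = annots.index(self.target) + 1
        tau_t, se_t = beta[t_idx], se[t_idx]
        z = tau_t / se_t if se_t > 0 else np.inf * np.sign(tau_t)
        p_one = float(stats.norm.sf(z))
        p_one = min(max(p_one, np.finfo(float).tiny), 1.0)

        ratio = self._enrichment_ratio(taus)
        return SLDSCResults(
            model=self,
            taus=taus,
            tau_se=ses,
            intercept=float(beta[0]),
            tau_hat=float(tau_t),
            se=float(se_t),
            z=float(z),
            p_one_sided=p_one,
            enrichment_ratio=ratio,
            jackknife=jack,
            annot_names=annots,
        )

    def _enrichment_ratio(self, taus: Dict[str, float]) -> float:
        """(share of h2 in target) / (share of SNPs in target) from fitted taus."""
        mem = self.ld.memberships.loc[self.sumstats["snp"]]
        per_snp = np.zeros(len(mem))
        for name, tau in taus.items():
            per_snp += tau * mem[name].to_numpy(dtype=float)
        per_snp = np.clip(per_snp, 0.0, None)  # negative per-SNP h2 is unphysical
        total = per_snp.sum()
        in_t = mem[self.target].to_numpy(dtype=bool)
        m_t = in_t.sum()
        if total <= 0 or m_t == 0:
            return np.nan
        return float((per_snp[in_t].sum() / total) / (m_t / len(mem)))


@dataclass
class SLDSCResults:
    """Fitted stratified LD-score regression.

    Carries the per-annotation coefficients, the target's jackknife SE,
    one-sided enrichment p-value and enrichment ratio. ``summary()`` returns a
    per-annotation table.
    """
    model: StratifiedLDRegression
    taus: Dict[str, float]
    tau_se: Dict[str, float]
    intercept: float
    tau_hat: float
    se: float
    z: float
    p_one_sided: float
    enrichment_ratio: float
    jackknife: np.ndarray
    annot_names: List[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "annotation": name,
                "tau_hat": self.taus[name],
                "se": self.tau_se[name],
                "z": self.taus[name] / self.tau_se[name] if self.tau_se[name] > 0 else np.nan,
                "is_target": name == self.model.target,
            }
            for name in self.annot_names
        ]
        return pd.DataFrame(rows)

    def as_enrichment_result(self) -> EnrichmentResult:
        cond = ",".join(self.model.conditional) or None
        return EnrichmentResult(
            trait=self.model.trait,
            annotation=self.model.target,
            tau_hat=self.tau_hat,
            se=self.se,
            z=self.z,
            p_one_sided=self.p_one_sided,
            enrichment_ratio=self.enrichment_ratio,
            conditioned_on=cond,
            intercept=self.intercept,
        )


def sldsc_fit(
    sumstats: pd.DataFrame,
    ld: LDScoreTable,
    target: str,
    conditional: Sequence[str] = (),
    n_blocks: int = 200,
    trait: str = "trait",
) -> EnrichmentResult:
    """Convenience wrapper: fit and return the target's enrichment result."""
    model = StratifiedLDRegression(sumstats, ld, target, conditional, n_blocks, trait)
    return model.fit().as_enrichment_result()


# ---------------------------------------------------------------------------
# multiple testing and conditional models


def fdr_adjust(
    results: Sequence[EnrichmentResult], group_by: str = "trait"
) -> List[EnrichmentResult]:
    """Benjamini-Hochberg FDR within each group (default: per trait)."""
    df = results_frame(results)
    for _, idx in df.groupby(group_by).groups.items():
        adj = bh_fdr(df.loc[idx, "p_one_sided"].to_numpy())
        for i, a in zip(idx, adj):
            results[i].fdr = float(a)
    return list(results)


def conditional_scan(
    sumstats: pd.DataFrame,
    ld_builder: Callable[[Sequence[str]], LDScoreTable],
    tdep_sets: Mapping[str, Set[str]],
    pairs: Sequence[tuple],
    n_blocks: int = 200,
    trait: str = "trait",
) -> List[EnrichmentResult]:
    """Pairwise conditional S-LDSC fits.

    For each (target, condition) pair the condition's annotation is added to
    the model and the target's conditional p reported; pairs with
    condition None (the diagonal) give the unconditional result.
    """
    out: List[EnrichmentResult] = []
    for target, condition in pairs:
        if target not in tdep_sets:
            raise ValueError(f"no TDEP annotation for target {target!r}")
        if condition is not None and condition == target:
            raise ValueError(f"target {target!r} conditioned on itself")
        if condition is not None and condition not in tdep_sets:
            raise ValueError(f"no TDEP annotation for condition {condition!r}")
        names = [target] if condition is None else [target, condition]
        ld = ld_builder(names)
        res = sldsc_fit(
            sumstats, ld, target,
            conditional=[] if condition is None else [condition],
            n_blocks=n_blocks, trait=trait,
        )
        out.append(res)
    return out
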