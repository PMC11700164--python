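"""Hypergeometric gene-set enrichment and genomic co-occurrence of TDEP genes.

Gene-set enrichment is the classical one-sided (over-representation)
hypergeometric test of a query gene set against named target sets, always
relative to a fixed background. The co-occurrence analysis tiles chromosomes
with fixed-width bins (default 100 kb), counts protein-coding TSS (nTss) and
TDEP TSS per cell type (nTdep) per bin, regresses nTdep on nTss per cell type
and inspects the internally studentized residuals: bins with residual > 3
carry far more TDEP TSS than the local gene density explains.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Set

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import OLSInfluence

from ._utils import bh_fdr


def hypergeometric_enrichment(
    query: Set[str],
    targets: Mapping[str, Iterable[str]],
    background: Set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric p per target set, BH FDR across targets.

    Targets are intersected with the background before testing; the query
    must be a subset of the background.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    m = len(background)
    n_query = len(query)
    rows = []
    for name, genes in targets.items():
        tset = set(genes) & background
        k = len(tset)
        overlap = len(query & tset)
        # P(X >= overlap), X ~ Hypergeom(M=m, K=k, n=n_query)
        p = float(stats.hypergeom.sf(overlap - 1, m, k, n_query))
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size": k,
                "query_size": n_query,
                "background_size": m,
                "p_hypergeometric": min(max(p, np.finfo(float).tiny), 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p_hypergeometric"].to_numpy())
    return out


def hypergeometric_enrichment_many(
    queries: Mapping[str, Set[str]],
    targets: Mapping[str, Iterable[str]],
    background: Set[str],
) -> pd.DataFrame:
    """Vectorized all-queries x all-targets enrichment scan.

    Equivalent to calling :func:`hypergeometric_enrichment` per query but
    computed via indicator-matrix products, so tens of thousands of target
    sets stay fast. FDR is applied across targets within each query.
    """
    from scipy import sparse

    bg = sorted(background)
    if not bg:
        raise ValueError("empty background")
    index = {g: i for i, g in enumerate(bg)}
    tnames = list(targets)
    rows, cols = [], []
    for j, name in enumerate(tnames):
        idx = [index[g] for g in targets[name] if g in index]
        rows.extend(idx)
        cols.extend([j] * len(idx))
    tmat = sparse.csc_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, cols)),
        shape=(len(bg), len(tnames)),
    )
    tsizes = np.asarray(tmat.sum(axis=0)).ravel()

    frames = []
    m = len(bg)
    for qname, q in queries.items():
        if not set(q) <= background:
            raise ValueError(f"query {qname!r} not a subset of the background")
        qvec = np.zeros(len(bg), dtype=np.int32)
        qvec[[index[g] for g in q]] = 1
        overlaps = np.asarray(qvec @ tmat).ravel()
        p = stats.hypergeom.sf(overlaps - 1, m, tsizes, int(qvec.sum()))
        frames.append(
            pd.DataFrame(
                {
                    "query": qname,
                    "set": tnames,
                    "overlap": overlaps,
                    "set_size": tsizes,
                    "query_size": int(qvec.sum()),
                    "background_size": m,
                    "p_hypergeometric": np.clip(p, np.finfo(float).tiny, 1.0),
                    "fdr": bh_fdr(np.clip(p, np.finfo(float).tiny, 1.0)),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# genomic bins


def bin_genome(
    annotation: pd.DataFrame,
    background: Set[str],
    tdep_sets: Mapping[str, Set[str]],
    bin_kb: float = 100.0,
    chrom_lengths: Mapping[str, int] | None = None,
    exclude_bins: Set[tuple] | None = None,
) -> pd.DataFrame:
    """Assign background TSS to fixed-width bins and count TDEP TSS per set.

    Bins start at position 0 per chromosome (half-open; TSS assigned by floor
    division). Returns one row per bin that the chromosome tiling defines,
    with nTss and one nTdep_<name> column per TDEP set. ``exclude_bins`` is an
    optional {(chrom, bin_start)} mask (e.g. all-N regions).
    """
    if bin_kb <= 0:
        raise ValueError("bin_kb must be > 0")
    width = int(round(bin_kb * 1000))
    ann = annotation.set_index("gene")
    missing = set(background) - set(ann.index)
    if missing:
        raise ValueError(f"background genes missing TSS annotation: {sorted(missing)[:10]}")
    sub = ann.loc[sorted(background)]
    if chrom_lengths:
        for chrom, grp in sub.groupby("chrom"):
            if chrom in chrom_lengths and (grp["tss"] >= chrom_lengths[chrom]).any():
                bad = grp.index[grp["tss"] >= chrom_lengths[chrom]][:5]
                raise ValueError(
                    f"TSS beyond declared length of {chrom}: {list(bad)}"
                )

    rows = []
    tnames = list(tdep_sets)
    for chrom, grp in sub.groupby("chrom"):
        length = (chrom_lengths or {}).get(chrom, int(grp["tss"].max()) + 1)
        n_bins = int(np.ceil(length / width))
        bins = (grp["tss"].to_numpy() // width).astype(int)
        ntss = np.bincount(bins, minlength=n_bins)
        ntdep = {}
        for name in tnames:
            members = grp.index.isin(tdep_sets[name] & background)
            ntdep[name] = np.bincount(bins[members], minlength=n_bins)
        for b in range(n_bins):
            key = (chrom, b * width)
            if exclude_bins and key in exclude_bins:
                continue
            row = {"chrom": chrom, "bin_start": b * width, "nTss": int(ntss[b])}
            for name in tnames:
                row[f"nTdep_{name}"] = int(ntdep[name][b])
            rows.append(row)
    return pd.DataFrame(rows)


def random_tss_expectation(
    n_bins: int, n_tss: int, n_trials: int = 1000, seed: int = 0
) -> dict:
    """Empty-bin fraction under uniform placement of TSS with replacement.

    Per trial, ``n_tss`` bins are drawn uniformly with replacement; the
    fraction of bins receiving zero draws is recorded. The closed form of the
    mean is (1 - 1/n_bins)^n_tss.
    """
    if n_bins <= 0 or n_trials <= 0:
        raise ValueError("n_bins and n_trials must be > 0")
    if n_tss < 0:
        raise ValueError("n_tss must be >= 0")
    rng = np.random.default_rng(seed)
    fractions = np.empty(n_trials)
    for t in range(n_trials):
        hits = rng.integers(0, n_bins, size=n_tss)
        occupied = np.unique(hits).size if n_tss else 0
        fractions[t] = (n_bins - occupied) / n_bins
    return {
        "fractions": fractions,
        "mean": float(fractions.mean()),
        "sd": float(fractions.std(ddof=1)) if n_trials > 1 else 0.0,
        "expected": float((1 - 1 / n_bins) ** n_tss),
    }


def cooccurrence_residuals(
    bins: pd.DataFrame, flag_threshold: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per cell type, studentized residuals of nTdep ~ nTss over occupied bins.

    Only bins with nTss >= 1 enter the regressions. Returns (residual table,
    Spearman correlation matrix of residual vectors, boolean flag table of
    bins with residual > ``flag_threshold``).
    """
    occupied = bins[bins["nTss"] >= 1].reset_index(drop=True)
    ntss = occupied["nTss"].to_numpy(dtype=float)
    if occupied.empty or np.ptp(ntss) == 0:
        raise ValueError("degenerate regression: constant nTss across occupied bins")
    tcols = [c for c in bins.columns if c.startswith("nTdep_")]
    if not tcols:
        raise ValueError("no nTdep columns in bin table")
    x = sm.add_constant(ntss)
    resid: Dict[str, np.ndarray] = {}
    for col in tcols:
        fit = sm.OLS(occupied[col].to_numpy(dtype=float), x).fit()
        resid[col.removeprefix("nTdep_")] = OLSInfluence(fit).resid_studentized_internal
    resid_df = pd.DataFrame(resid)
    resid_df.insert(0, "chrom", occupied["chrom"])
    resid_df.insert(1, "bin_start", occupied["bin_start"])

    names = list(resid)
    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            rho = stats.spearmanr(resid[a], resid[names[j]]).statistic
            corr.iloc[i, j] = corr.iloc[j, i] = rho
    flags = resid_df[names] > flag_threshold
    flags = pd.concat([resid_df[["chrom", "bin_start"]], flags], axis=1)
    return resid_df, corr, flags
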