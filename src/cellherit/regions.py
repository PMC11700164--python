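"""Regional aggregation of cluster-level enrichment to anatomical dissections.

A dissection's enrichment Z-score is the composition-weighted sum of the
cluster-level Z-scores over its neuronal clusters,

    Z_d = sum_k pct_{k,d} * Z_k,

where pct_{k,d} is the proportion of cluster k among the neuronal cells of
dissection d. The one-sided p treats Z_d as standard normal (a convention:
the weights shrink the null variance below 1 while positive inter-cluster
correlation inflates it; see the methods note), and BH FDR runs across
dissections per trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_fdr


@dataclass
class DissectionComposition:
    """Cluster x dissection composition.

    ``counts`` are retained-cluster cell counts, ``pct`` the within-dissection
    proportions (columns sum to 1), ``deciles`` a 1-10 rank-based scaling of
    all proportion entries (display only, never used in the weighted sum).
    """
    counts: pd.DataFrame
    pct: pd.DataFrame
    deciles: pd.DataFrame


def cluster_proportions(
    counts: pd.DataFrame,
    hierarchy: pd.DataFrame,
    neuronal_only: bool = True,
) -> DissectionComposition:
    """Per-dissection cluster proportions over the retained clusters.

    With ``neuronal_only`` (default) non-neuronal clusters are dropped before
    normalizing, so pct_{k,d} is the share of cluster k among the neuronal
    cells of dissection d. Dissections with zero retained cells are excluded
    with a warning.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("composition counts must be nonnegative")
    hier = hierarchy.set_index("cluster")
    missing = counts.index.difference(hier.index)
    if len(missing):
        raise ValueError(f"clusters missing from hierarchy: {list(missing)}")
    if neuronal_only:
        keep = hier.loc[counts.index, "neuronal"].astype(bool)
        retained = counts.loc[keep[keep].index]
    else:
        retained = counts
    totals = retained.sum(axis=0)
    dead = totals[totals <= 0].index
    if len(dead):
        warnings.warn(f"dissections with zero retained cells excluded: {list(dead)}")
        retained = retained.drop(columns=dead)
        totals = totals.drop(dead)
    pct = retained / totals

    # display deciles over all (cluster, dissection) entries, rank-based
    flat = retained.to_numpy().ravel().astype(float)
    ranks = stats.rankdata(flat, method="average") / flat.size
    dec = np.ceil(ranks * 10).clip(1, 10).astype(int)
    deciles = pd.DataFrame(
        dec.reshape(retained.shape), index=retained.index, columns=retained.columns
    )
    return DissectionComposition(counts=retained, pct=pct, deciles=deciles)


def dissection_enrichment(
    comp: DissectionComposition,
    cluster_z: Mapping[str, float],
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Composition-weighted dissection Z-scores with one-sided p and BH FDR.

    ``exclude`` lists dissections to drop before testing (curation list).
    """
    pct = comp.pct.drop(columns=[d for d in exclude if d in comp.pct.columns])
    missing = [k for k in pct.index if k not in cluster_z]
    if missing:
        raise ValueError(f"clusters without a Z-score: {missing}")
    zvec = np.array([cluster_z[k] for k in pct.index])
    z_d = pct.T.to_numpy() @ zvec
    p = stats.norm.sf(z_d)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {"dissection": pct.columns, "z": z_d, "p_one_sided": p, "fdr": bh_fdr(p)}
    )
    return out.reset_index(drop=True)
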