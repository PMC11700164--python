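"""Expression specificity: TPM, expression proportion (EP) and TDEP selection.

The specificity score chain is:

* TPM per cell type:  Exp[g, c] = counts[g, c] * 1e6 / sum_g counts[g, c]
* expression proportion:  EP[g, c] = Exp[g, c] / sum_c Exp[g, c]
* TDEP (top decile expression proportion): per cell type, the genes whose EP
  reaches the 90th percentile of EP over all background genes AND whose TPM
  exceeds 1. The decile threshold is computed before the TPM filter, so TDEP
  sets can shrink below the decile cap.

The background is the set of protein-coding, autosomal, non-eMHC genes
expressed (TPM > 1) in at least one cluster-level cell type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Set

import numpy as np
import pandas as pd

AUTOSOMES = {f"chr{i}" for i in range(1, 23)}


@dataclass
class SpecificityTable:
    """Per (gene, cell type) TPM / EP / TDEP values.

    All three frames share the same gene index and cell-type columns; ``ep``
    and ``tdep`` are filled by :func:`expression_proportion` and
    :func:`select_tdep`.
    """
    tpm: pd.DataFrame
    ep: pd.DataFrame | None = None
    tdep: pd.DataFrame | None = None

    @property
    def genes(self) -> pd.Index:
        return self.tpm.index

    @property
    def cell_types(self) -> pd.Index:
        return self.tpm.columns


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("gene and cell-type identifiers must be unique")
    if (counts.to_numpy() < 0).any():
        raise ValueError("expression counts must be nonnegative")


def normalize_tpm(counts: pd.DataFrame) -> SpecificityTable:
    """Depth-normalize a gene x cell-type count matrix to TPM (column sums 1e6)."""
    _check_counts(counts)
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"cell types with zero total counts: {list(zero.index)}")
    tpm = counts * 1e6 / totals
    return SpecificityTable(tpm=tpm)


def expression_proportion(spec: SpecificityTable) -> SpecificityTable:
    """Fill EP = TPM / (row sum of TPM); genes with zero total get EP 0."""
    tpm = spec.tpm
    row = tpm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ep = tpm.div(row, axis=0)
    ep[row <= 0] = 0.0
    spec.ep = ep
    return spec


def filter_background(counts: pd.DataFrame, annotation: pd.DataFrame) -> Set[str]:
    """Background gene set: protein-coding, autosomal, non-eMHC, expressed.

    "Expressed" means TPM > 1 in at least one of the (cluster-level) cell
    types of ``counts``. Every expression gene must have an annotation record.
    """
    _check_counts(counts)
    ann = annotation.set_index("gene")
    missing = counts.index.difference(ann.index)
    if len(missing):
        raise ValueError(f"genes missing from annotation: {sorted(missing)[:10]}"
                         f"{' ...' if len(missing) > 10 else ''}")
    ann = ann.loc[counts.index]
    tpm = normalize_tpm(counts).tpm
    expressed = (tpm > 1).any(axis=1)
    keep = (
        (ann["biotype"] == "protein_coding")
        & ann["chrom"].isin(AUTOSOMES)
        & ~ann["emhc"].astype(bool)
        & expressed
    )
    return set(counts.index[keep])


def select_tdep(
    spec: SpecificityTable, background: Iterable[str], decile: float = 0.9
) -> Dict[str, Set[str]]:
    """Per cell type, the TDEP gene set.

    The threshold is the ``decile`` quantile (default 90th percentile) of EP
    over ALL background genes for that cell type; a gene is TDEP when its
    EP >= threshold (ties at the boundary included) and its TPM > 1.
    """
    if spec.ep is None:
        raise ValueError("EP not filled; call expression_proportion first")
    background = sorted(set(background) & set(spec.genes))
    if len(background) < 10:
        raise ValueError(f"background has {len(background)} genes; at least 10 required")
    ep = spec.ep.loc[background]
    tpm = spec.tpm.loc[background]
    thresholds = ep.quantile(decile, axis=0)
    mask = (ep >= thresholds) & (tpm > 1)
    spec.tdep = mask.reindex(index=spec.genes, fill_value=False)
    return {ct: set(ep.index[mask[ct]]) for ct in spec.cell_types}


def aggregate_to_superclusters(counts: pd.DataFrame, hierarchy: pd.DataFrame) -> pd.DataFrame:
    """Sum cluster counts into supercluster counts (TPM is then recomputed on
    the aggregate rather than averaging cluster EPs)."""
    mapping = hierarchy.set_index("cluster")["supercluster"]
    missing = counts.columns.difference(mapping.index)
    if len(missing):
        raise ValueError(f"clusters missing from hierarchy: {list(missing)}")
    return counts.T.groupby(mapping.loc[counts.columns]).sum().T


def jaccard_matrix(tdep_sets: Mapping[str, Set[str]]) -> pd.DataFrame:
    """Symmetric Jaccard-index matrix of TDEP sets (diagonal 1).

    J(A, B) = |A & B| / |A | B|; two empty sets get 0 by convention.
    """
    names = list(tdep_sets)
    if len(names) < 2:
        raise ValueError("at least 2 sets required")
    out = np.eye(len(names))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            sa, sb = tdep_sets[a], tdep_sets[names[j]]
            union = len(sa | sb)
            out[i, j] = out[j, i] = (len(sa & sb) / union) if union else 0.0
    return pd.DataFrame(out, index=names, columns=names)


def jaccard_pairs(tdep_sets: Mapping[str, Set[str]]) -> pd.DataFrame:
    """Long-format unique off-diagonal pairs of the Jaccard matrix."""
    mat = jaccard_matrix(tdep_sets)
    rows = [
        {"a": mat.index[i], "b": mat.columns[j], "jaccard": mat.iat[i, j]}
        for i in range(len(mat)) for j in range(i + 1, len(mat))
    ]
    return pd.DataFrame(rows)
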