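"""Readers and writers for the package's on-disk formats.

All tables are TSV with header rows; expression matrices are accepted either
as a single TSV (genes x cell types) or as MatrixMarket ``.mtx`` with row and
column id files; TDEP sets are one gene-list file per cell type plus a JSON
index; ROI time series are one TSV per subject with a labels table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Mapping, Set

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simulate import ANNOTATION_COLUMNS, ConnectivityDataset, GroundTruth


# --- expression matrices ---------------------------------------------------


def write_expression_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_mtx(counts: pd.DataFrame, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.rows.tsv`` / ``.cols.tsv``."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix) + ".mtx", sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index, name="gene").to_csv(
        str(prefix) + ".rows.tsv", sep="\t", index=False
    )
    pd.Series(counts.columns, name="cell_type").to_csv(
        str(prefix) + ".cols.tsv", sep="\t", index=False
    )


def read_expression_mtx(prefix: str | Path) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = spio.mmread(str(prefix) + ".mtx").toarray()
    genes = pd.read_csv(str(prefix) + ".rows.tsv", sep="\t")["gene"]
    cols = pd.read_csv(str(prefix) + ".cols.tsv", sep="\t")["cell_type"]
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=list(cols))


def read_expression(path: str | Path) -> pd.DataFrame:
    """Dispatch on extension: ``.mtx`` (with sibling id files) or TSV."""
    path = Path(path)
    if path.suffix == ".mtx":
        return read_expression_mtx(str(path)[: -len(".mtx")])
    return read_expression_tsv(path)


# --- annotation / sumstats -------------------------------------------------


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    ann["emhc"] = ann["emhc"].astype(bool)
    return ann


def write_sumstats(ss: pd.DataFrame, path: str | Path) -> None:
    ss.to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read a sumstats TSV; derives z from beta/se when z is absent."""
    ss = pd.read_csv(path, sep="\t")
    if "z" not in ss.columns:
        if {"beta", "se"} <= set(ss.columns):
            ss["z"] = ss["beta"] / ss["se"]
        else:
            raise ValueError("sumstats must provide z or beta+se columns")
    required = {"snp", "chrom", "pos", "z", "n"}
    missing = required - set(ss.columns)
    if missing:
        raise ValueError(f"sumstats file missing columns: {sorted(missing)}")
    return ss


# --- TDEP sets -------------------------------------------------------------


def write_tdep_sets(tdep: Mapping[str, Set[str]], out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = {}
    for cell_type, genes in tdep.items():
        fname = f"tdep_{cell_type}.txt"
        (out_dir / fname).write_text("\n".join(sorted(genes)) + "\n")
        index[cell_type] = fname
    index_path = out_dir / "tdep_index.json"
    index_path.write_text(json.dumps(index, indent=2))
    return index_path


def read_tdep_sets(index_path: str | Path) -> Dict[str, Set[str]]:
    index_path = Path(index_path)
    index = json.loads(index_path.read_text())
    out = {}
    for cell_type, fname in index.items():
        text = (index_path.parent / fname).read_text().strip()
        out[cell_type] = set(text.split("\n")) if text else set()
    return out


def read_gene_set(path: str | Path) -> Set[str]:
    """One gene id per line."""
    text = Path(path).read_text().strip()
    return set(text.split()) if text else set()


def read_gmt(path: str | Path) -> Dict[str, Set[str]]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    for line in Path(path).read_text().strip().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 3:
            sets[parts[0]] = set(parts[2:])
    return sets


# --- fMRI ------------------------------------------------------------------


def write_fmri_dataset(ds: ConnectivityDataset, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sid, ts in zip(ds.subject_ids, ds.series):
        pd.DataFrame(ts, columns=ds.roi_meta["name"]).to_csv(
            out_dir / f"{sid}.tsv", sep="\t", index=False
        )
    pd.DataFrame({"subject": ds.subject_ids, "label": ds.labels}).to_csv(
        out_dir / "labels.tsv", sep="\t", index=False
    )
    ds.roi_meta.to_csv(out_dir / "roi_meta.tsv", sep="\t", index=False)


def read_fmri_dataset(in_dir: str | Path) -> ConnectivityDataset:
    in_dir = Path(in_dir)
    labels = pd.read_csv(in_dir / "labels.tsv", sep="\t")
    roi_meta = pd.read_csv(in_dir / "roi_meta.tsv", sep="\t")
    series = [
        pd.read_csv(in_dir / f"{sid}.tsv", sep="\t").to_numpy()
        for sid in labels["subject"]
    ]
    return ConnectivityDataset(
        series=series,
        labels=labels["label"].to_numpy(),
        subject_ids=list(labels["subject"]),
        roi_meta=roi_meta,
    )


# --- ground truth ----------------------------------------------------------


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2))


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        marker_genes={k: set(v) for k, v in d.get("marker_genes", {}).items()},
        enriched_annotation=d.get("enriched_annotation"),
        differential_pairs=[tuple(p) for p in d.get("differential_pairs", [])],
    )
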