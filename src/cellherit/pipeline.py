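"""End-to-end orchestration of the synthetic experiment.

``run_pipeline`` executes simulate -> tdep -> enrich (with a conditional
example) -> regions -> genesets/cooccur -> fmri-rfe, writing every stage's
outputs under the configured directory together with a JSON manifest (file
paths, seeds, checksums) and a serialized copy of the validated config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import io as chio
from .config import ConfigError, PipelineConfig
from .fmri import aggregate_fi, make_folds, rfe, topn_enrichment
from .genesets import bin_genome, cooccurrence_residuals, hypergeometric_enrichment_many
from .regions import cluster_proportions, dissection_enrichment
from .simulate import generate_atlas, generate_fmri, generate_gene_annotation, generate_gwas
from .sldsc import (
    build_annotation,
    compute_ld_scores,
    conditional_scan,
    fdr_adjust,
    results_frame,
    sldsc_fit,
)
from .specificity import (
    expression_proportion,
    filter_background,
    jaccard_pairs,
    normalize_tpm,
    select_tdep,
)

log = logging.getLogger("cellherit.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _register(manifest: dict, stage: str, name: str, path: Path) -> None:
    entry = manifest["stages"].setdefault(stage, {"files": {}})
    record = {"path": str(path)}
    if path.suffix != ".png":  # plots are display-only, excluded from checksums
        record["sha256"] = _sha256(path)
    entry["files"][name] = record


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and fully validate a YAML pipeline config, or raise ConfigError."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"invalid YAML in {path}: {e}") from e
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return PipelineConfig.from_dict(raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) the output manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: dict = {"seed": config.seed, "stages": {}, "summary": {}}
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    manifest["config"] = str(out / "config.yaml")

    stage = "simulate"
    try:
        log.info("stage: simulate")
        sim = config.sim
        annotation = generate_gene_annotation(sim)
        counts, hierarchy, composition, truth = generate_atlas(sim, annotation)
        fmri_ds, fmri_truth = generate_fmri(sim)
        truth.differential_pairs = fmri_truth.differential_pairs
        truth.enriched_annotation = hierarchy["cluster"].iloc[0]

        chio.write_annotation(annotation, out / "annotation.tsv")
        chio.write_expression_tsv(counts, out / "expression.tsv")
        hierarchy.to_csv(out / "hierarchy.tsv", sep="\t", index=False)
        composition.to_csv(out / "composition.tsv", sep="\t")
        chio.write_fmri_dataset(fmri_ds, out / "fmri")

        # GWAS: the enriched annotation is the window set of the first
        # cluster's planted marker genes (null when enrich_tau == 1)
        target_cluster = truth.enriched_annotation
        marker_annot = build_annotation(
            truth.marker_genes[target_cluster],
            annotation,
            _snp_map(sim),
            window_kb=config.window_kb,
            name=target_cluster,
        )
        sumstats, panel = generate_gwas(sim, marker_annot.indicator)
        chio.write_sumstats(sumstats, out / "sumstats.tsv")
        np.save(out / "panel.npy", panel.genotypes)
        chio.write_ground_truth(truth, out / "ground_truth.json")
        for name in (
            "annotation.tsv", "expression.tsv", "hierarchy.tsv", "composition.tsv",
            "sumstats.tsv", "ground_truth.json",
        ):
            _register(manifest, stage, name, out / name)

        stage = "tdep"
        log.info("stage: tdep")
        background = filter_background(counts, annotation)
        spec = expression_proportion(normalize_tpm(counts))
        tdep_sets = select_tdep(spec, background)
        spec.tpm.to_csv(out / "tpm.tsv", sep="\t")
        spec.ep.to_csv(out / "ep.tsv", sep="\t")
        chio.write_tdep_sets(tdep_sets, out / "tdep")
        jacc = jaccard_pairs(tdep_sets)
        jacc.to_csv(out / "jaccard_pairs.tsv", sep="\t", index=False)
        for name in ("tpm.tsv", "ep.tsv", "jaccard_pairs.tsv"):
            _register(manifest, stage, name, out / name)
        _register(manifest, stage, "tdep_index.json", out / "tdep" / "tdep_index.json")
        manifest["summary"]["background_size"] = len(background)
        manifest["summary"]["median_jaccard"] = float(jacc["jaccard"].median())

        stage = "enrich"
        log.info("stage: enrich")
        snp_map = sumstats[["snp", "chrom", "pos"]]
        annots = [
            build_annotation(genes, annotation, snp_map, config.window_kb, name=ct)
            for ct, genes in tdep_sets.items()
            if genes
        ]
        ld = compute_ld_scores(panel, annots, window_snps=config.ld_window_snps)
        results = [
            sldsc_fit(sumstats, ld, a.name, n_blocks=config.n_jackknife_blocks,
                      trait="simtrait")
            for a in annots
        ]
        results = fdr_adjust(results)
        res_df = results_frame(results)
        res_df.to_csv(out / "enrichment.tsv", sep="\t", index=False)

        # conditional example: first two clusters against each other + diagonal
        if len(annots) >= 2:
            a, b = annots[0].name, annots[1].name
            def ld_builder(names):
                return compute_ld_scores(
                    panel, [x for x in annots if x.name in names],
                    window_snps=config.ld_window_snps,
                )
            cond = conditional_scan(
                sumstats, ld_builder, tdep_sets,
                [(a, None), (a, b), (b, None), (b, a)],
                n_blocks=config.n_jackknife_blocks, trait="simtrait",
            )
            results_frame(cond).to_csv(out / "conditional.tsv", sep="\t", index=False)
            _register(manifest, stage, "conditional.tsv", out / "conditional.tsv")
        _register(manifest, stage, "enrichment.tsv", out / "enrichment.tsv")
        n_sig = int((res_df["fdr"] <= 0.05).sum())
        manifest["summary"]["n_fdr_significant_clusters"] = n_sig

        stage = "regions"
        log.info("stage: regions")
        comp = cluster_proportions(composition, hierarchy, neuronal_only=True)
        cluster_z = dict(zip(res_df["annotation"], res_df["z"]))
        for cluster in comp.pct.index:  # clusters with empty TDEP sets carry Z=0
            cluster_z.setdefault(cluster, 0.0)
        regional = dissection_enrichment(comp, cluster_z, exclude=config.exclude_dissections)
        regional.to_csv(out / "regional.tsv", sep="\t", index=False)
        comp.deciles.to_csv(out / "composition_deciles.tsv", sep="\t")
        for name in ("regional.tsv", "composition_deciles.tsv"):
            _register(manifest, stage, name, out / name)

        stage = "genesets"
        log.info("stage: genesets")
        marker_targets = {
            f"markers_{k}": v & background for k, v in truth.marker_genes.items()
        }
        queries = {ct: genes & background for ct, genes in tdep_sets.items() if genes}
        gs = hypergeometric_enrichment_many(queries, marker_targets, background)
        gs.to_csv(out / "geneset_enrichment.tsv", sep="\t", index=False)
        bins = bin_genome(annotation, background, tdep_sets, bin_kb=config.bin_kb)
        bins.to_csv(out / "bins.tsv", sep="\t", index=False)
        resid, spearman, flags = cooccurrence_residuals(bins)
        resid.to_csv(out / "cooccurrence_residuals.tsv", sep="\t", index=False)
        spearman.to_csv(out / "cooccurrence_spearman.tsv", sep="\t")
        for name in ("geneset_enrichment.tsv", "bins.tsv",
                     "cooccurrence_residuals.tsv", "cooccurrence_spearman.tsv"):
            _register(manifest, stage, name, out / name)

        stage = "fmri"
        log.info("stage: fmri")
        folds = make_folds(fmri_ds, n_folds=config.n_folds, seed=config.seed)
        traces = [
            rfe(fmri_ds, folds, f, config=config.classifier,
                n_perm=config.n_permutations, min_rois=config.min_rois,
                seed=config.seed + 1000 * (f + 1))
            for f in range(config.n_folds)
        ]
        agg = aggregate_fi(traces)
        pd.DataFrame(agg).to_csv(out / "fi_aggregated.tsv", sep="\t", index=False)
        (out / "rfe_traces.json").write_text(
            json.dumps([t.to_dict() for t in traces], indent=1)
        )
        flagged = fmri_ds.roi_meta.loc[fmri_ds.roi_meta["group"] == "flagged", "roi"]
        if len(flagged):
            topn = topn_enrichment(agg, flagged)
            topn.to_csv(out / "topn_enrichment.tsv", sep="\t", index=False)
            _register(manifest, stage, "topn_enrichment.tsv", out / "topn_enrichment.tsv")
        from .plotting import plot_auc_trace, plot_heatmap

        plot_auc_trace(traces, out / "auc_trace.png")
        plot_heatmap(agg, out / "fi_aggregated.png", title="aggregated FI")
        for name in ("fi_aggregated.tsv", "rfe_traces.json",
                     "auc_trace.png", "fi_aggregated.png"):
            _register(manifest, stage, name, out / name)
        first_run_aucs = [t.runs[0].auc for t in traces]
        manifest["summary"]["mean_first_run_auc"] = float(np.mean(first_run_aucs))
    except Exception as e:  # abort with stage name + partial manifest
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise PipelineError(stage, manifest, e) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("pipeline complete: %s", out / "manifest.json")
    return manifest


def _snp_map(sim) -> pd.DataFrame:
    from .simulate import _snp_table

    return _snp_table(sim)
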