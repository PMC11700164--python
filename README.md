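# cellherit

From cell-type-resolved expression to GWAS heritability enrichment, brain
regions, and connectivity.

`cellherit` is a tested, synthetic-data-first implementation of a chain of
analyses used to connect single-cell expression atlases of the brain to the
genetics and imaging of psychiatric disorders:

1. **TDEP gene specificity** — for each cell type, the genes in the top
   decile of *expression proportion* (EP, a gene's TPM in one cell type
   divided by its summed TPM across cell types) that also pass 1 TPM;
2. **Stratified LD-score regression (S-LDSC)** — each cell type's TDEP
   genes, expanded by ±100 kb, become a SNP annotation; GWAS χ² statistics
   are regressed on annotation-stratified LD scores,
   `E[χ²] = 1 + a + N Σ_c τ_c ℓ(·, c)`, and a one-sided test on the target
   coefficient τ (jackknife SE) asks whether the cell type carries excess
   SNP-heritability, with per-trait FDR and pairwise conditional models;
3. **Regional aggregation** — cluster-level enrichment Z-scores are carried
   to anatomical dissections via neuronal composition weights,
   `Z_d = Σ_k pct_k Z_k`;
4. **Connectivity classification** — a cross-entropy classifier separates
   cases from controls on ROI–ROI Pearson connectivity; each connection is
   scored by gated permutation feature importance
   `FI = mean_e_perm / e_orig` (computed only when the original error falls
   outside the permutation 95% interval), the least-contributing ROI is
   recursively eliminated, FI is aggregated as `FI/max(FI) × AUC` across
   models, and flagged-ROI connections are tested for enrichment among the
   top-n connections.

It also ships hypergeometric gene-set enrichment against a fixed
background and a genomic co-occurrence analysis of TDEP genes in 100 kb
bins (studentized residuals of `nTdep ~ nTss`).

Because the real inputs of such studies (a full human brain atlas, dozens
of GWAS, clinical resting-state fMRI) are not redistributable, the package
includes first-class synthetic-data generators with planted ground truth —
cluster marker genes, a variance-enriched SNP annotation, differential
connectivity pairs — so every stage has parameter-recovery and calibration
tests. The audience is method developers and statistical genetics /
neuroimaging practitioners who want a compact, auditable version of this
pipeline.

## Worked example

Run the end-to-end synthetic experiment (atlas → TDEP → S-LDSC → regions →
gene sets → connectivity RFE) from Python:

```python
from cellherit import PipelineConfig, SimConfig, ClassifierConfig, run_pipeline

cfg = PipelineConfig(
    seed=7, out_dir="demo_out",
    sim=SimConfig(seed=7, n_genes=1500, n_clusters=8, n_superclusters=4,
                  n_snps=8000, n_individuals=8000, n_panel=500,
                  marker_frac=0.2, enrich_tau=15.0, h2=0.5,
                  n_rois=12, ts_length=100, n_cases=16, n_controls=16,
                  delta_pairs=[(1, 5, 0.7)]),
    n_folds=3, n_permutations=60, n_jackknife_blocks=60,
    classifier=ClassifierConfig(backend="logistic", seed=7),
)
manifest = run_pipeline(cfg)
print(manifest["summary"])
```

which runs in well under a minute on one CPU and prints

```
{'background_size': 1337, 'median_jaccard': 0.019011406844106463,
 'n_fdr_significant_clusters': 1, 'mean_first_run_auc': 0.7248148148148147}
```

The simulation plants its enriched annotation on cluster `c000`'s marker
genes and a case/control covariance shift on ROI pair (1, 5). In
`demo_out/enrichment.tsv` the planted cluster tops the ranking and is the
single FDR-significant one:

```
annotation    tau_hat       z  p_one_sided       fdr  enrichment_ratio
      c000   0.000144   4.507    3.289e-06 2.631e-05             4.635
      c007  1.994e-05   1.062       0.1441    0.5763               NaN
      c002   1.13e-05   0.504       0.3071     0.819               NaN
      c005 -8.861e-06 -0.4477       0.6728    0.9761               NaN
```

`tau_hat` is the per-SNP heritability coefficient of the cluster's
annotation, `z = tau_hat / se` its jackknife z-score, `p_one_sided` the
upper-tail enrichment p, and `enrichment_ratio` the share of h² in the
annotation over its share of SNPs (≈1 under the null, NaN when the fitted
per-SNP contributions are all non-positive). The case/control covariance
shift shows up as a held-out AUC of ≈0.72 against the 0.5 chance level.
`demo_out/regional.tsv`, `demo_out/topn_enrichment.tsv` and
`demo_out/rfe_traces.json` carry the downstream regional and connectivity
results, and `demo_out/manifest.json` records every output file with its
checksum and the seeds used.

The same stages are available as a CLI:

```bash
cellherit simulate atlas --out sim --seed 3
cellherit tdep --expr sim/expression.tsv --annotation sim/annotation.tsv --out tdep_out
cellherit pipeline run --config config.yaml
```

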