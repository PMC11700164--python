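# Methods

This note documents the models and procedures implemented in `cellherit`,
the assumptions behind the synthetic-data generators, the parameters that
matter, and the numerical choices made where the design was genuinely open.

## Overview

The package chains four analyses, each of which can also run standalone:

1. **Expression specificity (TDEP).** From a gene × cell-type count matrix,
   compute TPM and expression proportion (EP), and select per cell type the
   genes in the top decile of EP that also exceed 1 TPM.
2. **SNP-heritability enrichment.** Turn each cell type's TDEP gene set into
   a SNP annotation (±100 kb gene windows), compute stratified LD scores
   from a reference panel, and regress GWAS χ² statistics on them to test
   whether the annotation carries excess per-SNP heritability.
3. **Regional aggregation.** Extrapolate cluster-level enrichment Z-scores
   to anatomical dissections by weighting with each dissection's neuronal
   cluster composition.
4. **Connectivity classification.** Classify cases vs controls from ROI–ROI
   Pearson connectivity, score each connection by gated permutation feature
   importance, recursively eliminate the least-contributing ROI, aggregate
   importance across models, and test flagged-ROI connections for
   over-representation among the top-ranked connections.

All stages are exercised end to end on synthetic data with planted ground
truth (marker genes, an enriched annotation, differential ROI pairs), so
every stage has parameter-recovery tests.

## Expression specificity

For raw counts `Raw[g, c]` of gene g in cell type c:

    Exp[g, c] = Raw[g, c] * 1e6 / Σ_g Raw[g, c]        (TPM)
    EP[g, c]  = Exp[g, c] / Σ_c Exp[g, c]              (expression proportion)

Genes with zero total expression get EP 0 (not NaN). The **background** used
by all gene-set arithmetic is the set of protein-coding, autosomal,
non-extended-MHC genes with TPM > 1 in at least one cluster-level cell type.

**TDEP selection.** Per cell type, the threshold is the 90th percentile of
EP over all background genes; a gene is TDEP when EP ≥ threshold *and*
TPM > 1 in that cell type. The decile threshold is computed before the TPM
filter, so TDEP sets can shrink below the decile cap — at full-atlas scale
the cap on an 18,090-gene background is 1,809 genes while typical selected
sets are smaller. Ties at the threshold are included (the ≥ rule); the
quantile uses linear interpolation. Supercluster-level analysis recomputes
TPM on counts summed to superclusters rather than averaging cluster EPs, so
the same equations apply at each level of the hierarchy.

## Stratified LD-score regression

The engine regresses GWAS χ² on annotation-stratified LD scores:

    E[χ²_j] = 1 + a + N Σ_c τ_c ℓ(j, c),   ℓ(j, c) = Σ_k r²_jk 1[k ∈ c]

with a free intercept `1 + a`. The design always contains the base
annotation (all SNPs) plus the target and any conditional annotations — a
deliberately reduced model compared with a full multi-annotation baseline,
sufficient for synthetic data whose confounding structure is known and
documented as a limitation for real data.

* **Annotations** are built from gene windows: SNP j belongs iff its
  position falls in `[start − w, end + w)` of any listed gene on the same
  chromosome, with `w` = 100 kb by default and clipped at 0.
* **LD scores** come from a reference panel: bias-adjusted squared
  correlations `r̂²_adj = r² − (1 − r²)/(n − 2)`, floored at 0, summed over
  SNPs within a window measured in SNP count (the synthetic map has no
  recombination coordinates). Monomorphic SNPs contribute 0 with a warning.
* **Weighted least squares, two steps:** step 1 uses LD weights
  `1/max(ℓ_base, 1)`; step 2 multiplies in heteroskedasticity weights
  `1/(2 max(E[χ²], 1)²)` from the step-1 prediction. This is the standard
  two-step LDSC weighting scheme.
* **Uncertainty:** delete-a-block jackknife over contiguous SNP blocks
  (default 100–200 blocks) for the coefficient SE; `z = τ̂/SE`; the
  enrichment p-value is one-sided in the positive-τ direction.
* **Enrichment ratio:** per-SNP variance contributions `Σ_c τ̂_c a_c(j)`
  are floored at 0 (negative per-SNP heritability is unphysical), and the
  ratio is (share of h² in the annotation) / (share of SNPs in it).
* **FDR:** Benjamini–Hochberg within each trait.
* **Conditional models** add a second cell type's annotation to the design
  and report the target's conditional p; conditioning on an all-zero
  annotation is a no-op (the constant column is dropped), and a target
  conditioned on itself raises a collinearity error.

## Regional aggregation

For dissection d with neuronal-cluster proportions `pct[k, d]`
(counts of cluster k divided by the dissection's total neuronal cells):

    Z_d = Σ_k pct[k, d] · Z_k

The one-sided p treats `Z_d` as standard normal, following the direct
conversion convention. This is a documented approximation: since
Σ pct² < 1 the null variance of the weighted sum is below 1 (conservative),
while positive correlation between cluster Z-scores pushes it above 1
(anti-conservative); the package does not attempt to correct either effect.
Dissections with zero neuronal cells are excluded with a warning, and a
curation-style exclusion list is a config option rather than hard-coded.
Decile scaling of composition entries (rank-based, 1–10) is display-only.

## Gene-set and genomic co-occurrence analysis

Gene-set enrichment is the one-sided (over-representation) hypergeometric
test against the fixed background, targets intersected with the background
first, BH FDR across targets within each query. The vectorized scan uses a
sparse indicator-matrix product so tens of thousands of target sets remain
fast.

The co-occurrence analysis tiles each chromosome with fixed-width bins
(100 kb default, starting at 0, TSS assigned by floor division), counts
protein-coding TSS (`nTss`) and TDEP TSS per cell type (`nTdep`), and for
each cell type fits OLS `nTdep ~ nTss` over bins with `nTss ≥ 1`. The
residuals are *internally studentized* (leverage-adjusted); bins with
residual > 3 are flagged as carrying more TDEP TSS than local gene density
explains, and Spearman correlations between cell types' residual vectors
summarize shared genomic clustering. Note the leverage scaling leaves the
residual mean only approximately zero (≈1e-4 on our fixtures, not exactly
0). The random-expectation helper places TSS uniformly with replacement
into bins and records the empty-bin fraction, whose mean has the closed
form `(1 − 1/n_bins)^n_tss` used as the simulation oracle.

## Connectivity classification

Per subject the feature vector is the strict upper triangle of the ROI×ROI
Pearson correlation matrix of its time series. Cross-validation portions
are class-balanced and stratified by time-series length (subjects dealt
round-robin within class after sorting by length), which reproduces the
10/9/9/9/9 per-class split for 46+46 subjects at 5 folds.

The classifier trains on the cross-entropy objective; two backends satisfy
that contract: a 2-hidden-layer feed-forward network (default, widths
(16, 8)) and L2-regularized logistic regression. Standardization is fitted
on training data only (leakage control). Evaluation is held-out ROC AUC.

**Permutation feature importance (gated).** For each connection, its values
are shuffled across the subjects of the evaluation split `n_perm` times
(default 1000); the permuted cross-entropy errors define a central 95%
interval. If the original error `e_orig` falls outside that interval the
connection is considered contributing and

    FI = mean_e_perm / e_orig,

otherwise FI = 0. Shuffling on the evaluation split is a documented choice
(the split is not dictated by the procedure's definition); under a
pure-noise feature the original arrangement is exchangeable with its
permutations, so the gate opens at the nominal ~5% rate — verified by
simulation (the empirical-percentile interval at `n_perm` = 200 inflates
this to ≈6%, at 1000 it is ≈5.5%).

**Recursive ROI elimination.** Each run trains, evaluates, computes FI,
sums FI over each ROI's connections, and removes the argmin ROI (ties
broken by lowest ROI index), until `min_rois` (default 2) remain. The trace
records every run; per-ROI "preserved runs" is the number of runs the ROI
participated in. **Aggregation:** per model, FI/max(FI) × AUC, summed
elementwise across models. **Top-n enrichment:** connections are ranked
over all R² matrix entries (diagonal fixed at 0, symmetric duplicates
included — so the grid for 76 ROIs is the even n from 2 to 5776, i.e. 2888
tests); a connection is flagged iff either endpoint is flagged; each n gets
an upper-tail hypergeometric p. Cross-dataset reproducibility is the
Pearson correlation of mean preserved-run counts across ROIs.

## Synthetic-data generators

The generators emulate the statistical structure the pipeline consumes, not
the raw modalities:

* **Gene annotation:** genes on chr1..chr{n_chroms} (default 8 chromosomes
  of 20 Mb), uniform or clumped placement, strand-appropriate TSS, a
  configurable extended-MHC flag fraction (default 5%) and non-coding
  biotype fraction (default 5%).
* **Expression atlas:** negative-binomial counts with a gene-level
  lognormal mean and shared dispersion (shape 10 — cluster-level counts are
  pseudobulk aggregates over many nuclei and only mildly overdispersed).
  Each cluster's planted markers have their mean multiplied by
  `marker_fold` in the home cluster. Clusters map round-robin onto
  superclusters; the first ~60% of superclusters are neuronal.
* **Dissection compositions:** Dirichlet-multinomial per dissection;
  neuronal clusters get a sparse concentration (0.3) with the k-th neuronal
  cluster boosted (×8) in its home dissection k mod n_dissections, while
  non-neuronal clusters spread evenly (concentration 5).
* **GWAS:** standardized Gaussian genotypes with equicorrelated LD blocks
  (default 10 SNPs per block, within-block correlation 0.5), so expected
  base LD scores have the closed form `1 + (B−1)ρ²` used as an oracle.
  Causal effects are Gaussian with per-SNP variance multiplied by
  `enrich_tau` inside the annotation, rescaled so the realized genetic
  variance equals `h2`; marginal z-scores come from per-SNP simple
  regression. The reference panel is an independent draw from the same LD
  model.
* **fMRI:** controls draw i.i.d. time points from a multivariate normal
  with a random well-conditioned correlation matrix; cases shift the
  covariance additively on the planted ROI pairs and are eigenvalue-clipped
  back to positive definite.

What the generators do **not** emulate — and hence what passing tests do
not show about real data: realistic human LD (block-equicorrelated vs
empirical LD maps), droplet-level count noise and batch structure, real GO
term dependence, hemodynamic autocorrelation in fMRI time series, and
motion/confound structure. The recovery results demonstrate that the
machinery is correct and calibrated under its stated model, not that the
scientific conclusions transfer to any particular dataset.

## Replicate studies and problem sizes

The type-I error study in `cellherit.experiments` regenerates every input
(annotation, reference panel, LD scores, GWAS) each replicate, so its
rejection rate estimates the marginal error rate; the power and
multi-trait studies hold the reference panel and LD scores fixed across
replicates while redrawing causal effects, noise and GWAS genotypes —
matching practice, where one reference panel serves many traits. The
studies use these sizes:

* type-I error: 500 replicates at 5,000 SNPs, N = 2,000; rejection rate at
  α = 0.05 expected in [0.03, 0.08];
* power: 100 replicates at 20,000 SNPs, N = 5,000, `enrich_tau` = 10,
  `h2` = 0.5, with 4 disjoint null annotations for the per-trait FDR step;
* TDEP recovery: `marker_fold` = 50, recovery measured among
  background-eligible markers (markers excluded by the eMHC/biotype filter
  cannot be selected by construction);
* regional recovery: 6 dissections matching the 6 neuronal clusters at the
  default atlas size, cluster Z = 4 planted on the clusters homed at
  dissection 0;
* fMRI recovery: pairs of independently seeded datasets sharing one planted
  ROI pair (covariance shift 0.8) at 20 ROIs, 24+24 subjects, 3 folds, 100
  permutations, logistic backend; scored on top-1% aggregated-FI membership
  in both datasets and positive cross-dataset preserved-run correlation;
* FI gate calibration: 500 nulls at 1000 permutations each.

The results-reproduction script (`scripts/acceptance.py`) runs the same
studies at moderately reduced replicate counts (300/60/20/6) chosen as its
standard problem sizes; each JSON entry records the size used under `n`.

## Known limitations

* The reduced S-LDSC design (base + target + conditionals) cannot absorb
  confounding from annotations outside the model; with real data a fuller
  baseline is required.
* At desk scale the one-sided enrichment test is mildly conservative:
  over 500 fresh null simulations (5,000 SNPs in 10-SNP LD blocks,
  N = 2,000) the empirical rejection rate at α = 0.05 is ≈0.024–0.030 and
  the null z-scores have mean ≈ −0.13. τ̂ is unbiased and the jackknife SE
  matches the empirical SD of τ̂ to within 1%, but the right-skewed χ²
  noise couples positive τ̂ draws to inflated jackknife SEs, thinning the
  upper tail; with only ~500 independent LD units the effect is visible.
  It is insensitive to one-step vs two-step weighting, to fixing the
  intercept at its step-1 estimate, and to the jackknife block count, and
  the p-values remain KS-indistinguishable from uniform; the effect
  vanishes as the number of independent LD units grows. The test never
  exceeds its nominal level in these simulations.
* The standard-normal convention for dissection Z-scores ignores both the
  variance shrinkage of the weighted sum and inter-cluster correlation.
* The permutation-FI gate tests exchangeability on the evaluation split
  only; with very small evaluation sets the empirical 95% interval is
  noticeably narrow (gate rate ≈6% at 200 permutations).
* Dissection recovery presumes enriched clusters concentrate in a single
  dissection; sparse compositions occasionally concentrate a non-home
  dissection on a planted cluster, which is a premise violation rather than
  an aggregation failure (observed ≈2–5% of replicates).
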