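# Methods

## Model and statistic

The package estimates genetically driven epigenomic effects on gene
expression and propagates them to GWAS phenotypes. Stage 1 regresses each
CpG's methylation on the dosages of SNPs within ±50 kb (elastic net,
mixing 0.5, penalty chosen by 10-fold cross-validation). Stage 2 regresses
each gene's expression on the *predicted* methylation of CpGs within
±500 kb of its TSS. The construction is a two-stage regression in the
instrumental-variable sense: SNPs are the instruments, CpG methylation the
mediator, and only the genetic component of methylation is carried forward.

Applied to GWAS summary statistics, the gene-level z-score is

    z_g = Σ_j w_gj · sd_j · z_cj / σ_g,       z_cj = Σ_k w_jk σ_k z_k / sd_j^pred,

with σ_k the reference-panel dosage SD, sd_j^pred the SD of CpG j's
predicted methylation, and σ_g = sqrt(w_gᵀ Cov w_g). When the CpG
covariance source is the predicted methylation of the training panel the
per-CpG scales cancel and the statistic collapses to the composite-weight
form Σ_k (Σ_j w_gj w_jk) σ_k z_k / σ_g. Under null input z ~ N(0, R) with
R the panel LD of the model SNPs, Var(z_g) = 1 *exactly*, because
cov(M^p) = W_c cov(S) W_cᵀ holds identically for a linear predictor
evaluated on the same panel with a consistent ddof convention (ddof = 1 is
used everywhere). The calibration suite verifies the empirical SD ≈ 1 to
Monte-Carlo accuracy.

### Why the measured-methylation covariance inflates

Substituting the covariance of *measured* methylation must be modeled as a
sequential substitution — the measured SDs rescale the CpG-level terms and
the measured covariance forms the denominator:

    Var(z_g) = ṽᵀ Corr(M^p) ṽ / ṽᵀ Corr(M) ṽ,      ṽ_j = w_gj · sd_j^meas.

Because measured correlations are the genetic correlations attenuated by
the non-genetic variance (Corr(M) ≈ h² · Corr(M^p) off-diagonally for
heritability fraction h²), the ratio exceeds 1 whenever the gene's weights
align with positive predicted-methylation correlations — inflation. The
naive alternative of plugging the measured covariance only into the
denominator would give strict deflation (Σ_meas − Σ_pred is PSD under
independent noise) and does not reproduce the observed behavior; the
sequential form is therefore the one implemented. Conversely, drawing the
null z from N(0, I) while the true model SNPs are in LD underestimates the
variance for genes whose composite weights carry positive LD cross-terms,
deflating the z-scores. Both directions are asserted in the test suite.

## Synthetic data generator

The generator emulates the training-data structure the cascade assumes:

- **Genotypes**: a latent equicorrelated Gaussian per LD block (block size
  10, within-block correlation 0.7 by default) is thresholded at
  Hardy–Weinberg cut points for a MAF drawn uniformly from [0.05, 0.5],
  yielding dosages in {0, 1, 2} with exactly controlled block LD. SNPs sit
  on one synthetic chromosome at 1 kb spacing so that cis-window logic is
  exercised rather than bypassed.
- **Methylation**: each CpG has a sparse cis-genetic component (2 causal
  SNPs by default) plus homoscedastic Gaussian noise scaled so the genetic
  variance fraction equals `h2_cpg`. Neighboring CpGs form clusters of 3
  that share their causal SNPs *and* effect directions, emulating
  co-methylated CpG clusters with shared mQTLs; this gives the genetic
  components of nearby CpGs the positive mutual correlation that makes the
  choice of CpG covariance consequential. Without it, a gene's CpGs are
  essentially uncorrelated and the predicted- vs measured-covariance
  contrast is vacuous.
- **Expression**: each gene has a sparse CpG-mediated component (3 causal
  CpGs by default) plus noise at variance fraction `h2_gene`.
- **GWAS z-scores**: null draws come from N(0, R) for a supplied LD matrix
  (PSD-repaired by eigenvalue clipping at 1e-10 and diagonal
  renormalization, sampled by Cholesky with an eigen-square-root
  fallback); alternative draws use z = R·u + e with e ~ N(0, R), the
  standard propagation of per-SNP non-centrality through LD.

Defaults (1,000 samples, 1,500 SNPs, 150 CpGs, 30 genes) are a desk-scale
stand-in for a cohort in which several hundred subjects carry all three
data types. What the generator does **not** emulate: beta-distributed
methylation values, realistic recombination maps and MAF spectra,
population structure, trans effects, and correlated non-genetic variation
between CpGs (batch/cell-composition confounding). Passing tests therefore
demonstrate the statistical machinery under the model's own assumptions,
not robustness to real-data artifacts.

## Training conventions

- Predictors and responses are mean-centered, not variance-standardized
  (a `standardize` flag exists); weights stay on the centered-dosage scale
  so that σ_k scaling in the cascade is meaningful.
- The elastic-net penalty is chosen by 10-fold CV with the **1-SE rule**
  (largest penalty within one standard error of the CV minimum), the same
  rule glmnet uses when extracting coefficients at its default. The
  CV-minimum rule is available (`lambda_rule="min"`) but leaves spurious
  nonzero weights on null features; with the 1-SE rule pure-noise
  responses collapse to all-zero models and pure-noise expression fails
  the cascade-R² filter in ≥ 90% of genes, which is the behavior the
  retention filter is designed around.
- `cv_r2` is 1 − (CV MSE at the chosen penalty)/var(y), floored at 0; the
  gene retention decision uses the in-sample squared correlation of the
  *sequential* prediction (`cascade_r2 > 0.01`, strict).
- Fold assignment is index-based, so training entry points sort samples by
  id first; results are invariant to input row order.
- Per-SNP penalty factors (the mQTL-p weighting variant,
  min(1, 1e10·p + 0.5)) are applied by rescaling predictor columns, which
  reproduces a weighted L1 penalty exactly; the quadratic half of the
  elastic-net penalty is then weighted quadratically rather than linearly.
- σ_j^c (SD of predicted methylation) is computed on in-sample
  predictions; a CV-held-out variant would differ only by shrinkage of
  the same quadratic form.
- Window boundaries are inclusive (≤); TSS distance ignores strand;
  stage-1 CpGs are not R²-filtered (only all-zero models are unusable).

## Calibration suite

For each gene, R_i is the Pearson correlation of the union of the gene's
weighted stage-1 SNPs in the chosen panel (zero-weight cis SNPs contribute
nothing to the statistic and are omitted from R_i to keep it small),
PSD-repaired as above. Null draws are projected directly through the
correlation square root (z_g = εᵀ(Lᵀc)/σ_g), so per-gene cost is linear in
the number of draws. The mismatch experiment takes R_i from an external
panel while all model terms stay on the training panel; model SNPs missing
from the external panel contribute zero, genes with < 50% coverage are
flagged and skipped, and genes with SD above a configurable 1.2 threshold
are counted as outliers (the outlier cutoff is a reporting convention, not
part of the statistic).

## Enrichment

Gene z-scores are modeled as z = Cα + x_l β_l + ε, ε ~ N(0, s²Σ): C is an
intercept plus the number of selected (CpG, SNP) pairs per gene (pairs
with nonzero weight product; a strict-positive variant is available), x_l
a binary set indicator (retained at intersection size 10–200) or a
continuous per-gene covariate, and Σ the OAS-shrunk correlation of an
expression matrix over the tested genes. OAS is implemented from the
closed form ρ = min(1, [(1−2/q)tr(S²)+tr(S)²] / [(n+1−2/q)(tr(S²)−tr(S)²/q)])
with target (tr S/q)·I; the scikit-learn implementation deliberately drops
the 2/q terms, so it serves only as a directional cross-check in tests.
Σ is treated as known up to a scalar estimated from the GLS residuals on
q−d−1 degrees of freedom; the set test is one-sided for β_l > 0 (the
competitive-test convention; two-sided available). GLS is computed by
Cholesky whitening + OLS, with the factorization shared across sets of a
collection. FDR is Benjamini–Hochberg within each collection, and across
regions for the brain-region analysis. Regional covariates are one-sample
t-statistics of subject-level expression centered by each subject's
cross-region mean per gene (duplicate gene–region measurements averaged
within subject first); zero-variance pairs are capped at ±1e6.

## Post-processing

- Detection: Bonferroni at α = 0.05, inclusive cutoff (p ≤ α/n).
- Distinct signals: percentage variance per PC of the predicted-expression
  matrix against a permutation null; the default scheme shuffles each
  gene's column independently (preserving per-gene marginals, the standard
  PCA permutation null), a full-matrix entry shuffle is available.
  p = (1 + #{perm ≥ obs})/(1 + n_perm), so p is never 0; PCs with p < 0.05
  count as distinct signals.
- Replication AUC: positives are the smallest ceil(0.01·q) reference
  p-values (ties broken by gene id); the AUC is the Mann–Whitney statistic
  of −p_test with midranks, identical to sweeping a p-value threshold.
  The permutation null permutes test p-values over gene labels; its exact
  SD is sqrt((q+1)/(12·k·(q−k))) — about 0.02 only at a full tested-gene
  universe (k = 200 positives of q = 20,000), and 0.065 at q = 2,000 —
  while the mean is 0.5 at any size. Both are asserted in the tests.
- Genomic correlation: Pearson on the intersection of tested genes
  (≥ 10 required).

## Numerical conventions and degenerate inputs

Constant predictions define R² = 0 (triggering the retention filter);
genes with σ_g = 0 or no GWAS-overlapping SNPs are excluded and logged;
zero-variance responses yield all-zero weights rather than errors;
closest-CpG ties break toward the smaller coordinate; the MHC interval is
configurable (GRCh37 chr6:25–35 Mb shipped as `MHC_GRCH37`, never
hard-coded into the statistics). All randomness flows through seeded
generators keyed by (seed, context), so every artifact is reproducible
from its config, whose hash and seed are stamped into output headers.

## Problem sizes

The shipped test suite and the acceptance script train the full synthetic
study (1,000 samples, 1,500 SNPs, 150 CpGs, 30 genes) and use 10,000
calibration draws and 10,000 AUC permutations; smaller systems are used
for unit-level oracles. These sizes were chosen so the complete analysis
reruns in minutes on a single core while keeping Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

- The measured-covariance inflation is a property of genes whose weighted
  CpGs have correlated genetic components; for genes with mutually
  uncorrelated CpG predictions the statistic is calibrated under either
  covariance source, so direction tests condition on a cross-term ratio
  ≥ 0.1.
- Elastic-net support recovery under strong LD is inherently partial:
  weights spread across correlated SNPs, so fitted composite weights are
  compared to the truth by correlation, not exact support match.
- The replication machinery assumes two studies share a gene id universe;
  no liftover or id mapping is provided.
- No genotype QC/imputation, no trans effects, no multi-tissue models.
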