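# Methods

## Data model

A `NucleusDataset` aligns three objects on nucleus barcodes: a sparse
nuclei × genes integer count matrix, a dense nuclei × antibodies count
matrix whose panel contains exactly one reference antibody (histone H3
by default), and a metadata table with donor, disease group (young /
aged / AD / ALS / FTD), 10x-well batch, hashtag counts and optional
cell-type/cluster labels. Nuclei are rows in every in-memory matrix;
on-disk bundles follow the 10x convention (features as MatrixMarket
rows). Barcode joins are exact string matches; assembly restricts to the
barcode intersection of the three sources.

## Reference normalization and nCLR

Nuclear antibody capture counts mix protein abundance with a per-nucleus
capture-efficiency scalar (nuclear access, permeabilization, tag
recovery). Because histone H3 abundance is nearly constant per nucleus,
the ratio `n_p = (A + pc) / (A_H3 + pc)` cancels that scalar exactly
when the pseudocount `pc` is zero, and to first order otherwise. The
default pseudocount is 1: zeros are common in antibody capture and the
subsequent log is otherwise undefined. Nuclei with zero raw reference
counts are flagged and must be excluded from protein analyses when
`pc = 0`.

The centered log-ratio step maps each value to
`ln(n_p / gmean(n_p))`, with the geometric mean taken **per antibody
across the nuclei of a centering cohort** (default: all QC-passed
nuclei), so each antibody's cohort log-mean is zero. Two design points:

- Although the ratio formula alone could be read without a logarithm,
  "centered natural log ratio" values must live on an additive scale for
  the downstream linear models, so the natural log is applied.
- The alternative centering axis — per nucleus across antibodies, the
  classical compositional CLR — would cancel the H3 reference
  algebraically (ln(A_p/A_H3) minus its per-nucleus mean no longer
  depends on A_H3 at all), defeating the point of reference
  normalization. It is available behind `axis="nucleus"` for
  comparison; per-antibody centering is the default.

Percentile stratification computes thresholds on a stated nucleus
subset only (default: the analyzed cluster), with ties assigned to the
lower bin; default bands are bottom 25%, mid, top 10–25% and top 10%,
with quintiles as an alternative. Density maps of protein-high nuclei
are Gaussian KDEs (Scott bandwidth) of the subset evaluated at every
nucleus's 2-D embedding position, min–max scaled to [0, 1].

## Two-step association model

Step 1 fits, per gene, ordinary least squares of ln(1 + depth-normalized
expression) on an intercept, `log_ncounts` (ln of the nucleus's total
gene counts), `log_hashtag_counts` and one-hot batch indicators,
dropping collinear columns with a warning. Genes expressed in fewer than
25 nuclei are skipped. Step 2 regresses the step-1 residuals on the
nCLR values of the panel proteins — jointly by default, one at a time in
`single` mode — with two-sided *t*-tests per coefficient (residual
degrees of freedom account for the step-1 covariates) and
Benjamini–Hochberg adjustment across all gene × protein tests as one
family at FDR 0.05.

The name notwithstanding, the operational formula contains only fixed
effects, so the model is per-gene OLS with batch as a categorical fixed
effect. By default the protein columns are residualized on the step-1
covariates first; the two-step coefficients then equal those of a single
joint regression of expression on covariates plus proteins
(Frisch–Waugh–Lovell), which the tests verify to 1e-8. Setting
`residualize_proteins=False` reproduces the literal two-step procedure.

Overlap of signed association sets with an external gene set uses the
2×2 table (associated vs rest) × (in set vs not) over the tested-gene
universe, with the sample odds ratio ad/bc and a two-sided Fisher exact
p-value. The percent overlap of two gene sets is `100·|A∩B|/|A∪B|`.

## QC and preprocessing

Nucleus filters: at least 50 detected genes; at most 5% mitochondrial
counts (genes with the standard human `MT-` name prefix); hashtag counts
at most 4,000; TDP-43 antibody counts at most 3,000 (applied only when
that antibody is in the panel, so RNA-only samples skip it). Gene
filter: detected in at least 5 nuclei. Nucleus and gene filters are
iterated to a fixed point so a second application removes nothing.

Depth normalization scales each nucleus to 10,000 counts before
ln(x+1); the fixed target makes values comparable across depth.
Variable genes use the Seurat-style recipe (per-gene mean and dispersion
of expm1 values, dispersion z-scored within 20 mean bins; selection
window mean ∈ (0.0015, 0.18), normalized dispersion > 0.30), delegated
to scanpy's implementation of that recipe. The window values target
genome-wide panels where most genes are sparse; on the desk-scale
synthetic cohort (500 dense genes) they select nothing, so the tests
exercise selection on purpose-built sparse matrices and the CLI falls
back to all genes with a notice. Embedding/clustering is PCA (40
components, clamped to the data rank with a warning), a k = 10
nearest-neighbor graph and Leiden at resolution 0.8, delegated to
scanpy/leidenalg; the first two PCs serve as the 2-D embedding for
density work, and optional per-batch PC-mean centering stands in for
dedicated batch integration (which, like UMAP internals and doublet or
hashtag demultiplexing, is out of scope).

## Nucleus- and donor-level statistics

Nucleus-level contrasts use the pooled two-sample *t*-test with pooled
Cohen's *d* = (m₁−m₂)/s_pooled; the identity *d* = *t*·√(1/n₁+1/n₂) is
asserted on every computed contrast. The pooled (not Welch) convention
is used because it is the one under which reported (t, n₁, n₂, d) trios
for the capillary cluster contrasts are mutually self-consistent.

Stoichiometry curves (one protein against another, per disease group)
sort nuclei by the x protein, form 20 equal-count bins, take per-bin
means of both proteins, and smooth **both** the bin centers and bin
means with the same 3-bin running mean — smoothing both preserves exact
linear relationships, which the tests assert. Binned means were chosen
over model-based smoothers as reproducible and assumption-light.

Composition statistics operate on donor-level units (the proportion of
each donor's nuclei per cluster, rows summing to 1): one-way ANOVA with
Tukey HSD post hoc pairwise tests (statsmodels), excluding groups with a
single unit, and Spearman rank correlation of per-donor proportions
against donor age (two-sided, ≥ 4 donors). Nucleus-level contrasts and
donor-level tests are deliberately separate entry points.

## Pseudobulk and donor correlation

Pseudobulk units sum raw counts per donor × cell type; units with fewer
than 10 member nuclei or fewer than 800 total counts are dropped and
reported. Unit sums conserve member-nucleus counts exactly.
Differential testing is delegated: the module exports genes × units
count tables with a covariate sheet (disease group, modal batch per
donor) ready for DESeq2-style count models.

The donor-correlation view normalizes and log-scales nuclei of one cell
type, fits PCA on nuclei (50 components by default), optionally centers
PCs per batch, averages PC coordinates per donor (donors with fewer than
10 nuclei excluded), computes pairwise Pearson correlations, and
clusters donors by average linkage on the 1 − r distance, with Newick
export of the dendrogram. Fitting PCA on nuclei and then averaging per
donor (rather than on donor-mean profiles) weights the fit by the
nuclei actually observed.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume,
at desk scale; defaults: 4 donors per group × 5 groups, donors
interleaved round-robin over 4 batches so every batch mixes disease
groups (mirroring pooled 10x reactions), negative-binomial nuclei per
donor (mean 250, shape 5), 500 genes of which 10 are `MT-` prefixed,
panel {H3, TDP43, p65, beta-catenin}, expected depth 2,000 counts per
nucleus.

Latent protein levels are natural-log scale: H3 constant up to small
noise (SD 0.05); other proteins lognormal across nuclei (log-SD 1) with
configured shifts in reactive-cluster nuclei of disease donors (default
TDP43 −1.0, beta-catenin −0.5, p65 +0.25 — a scaled-down analogue of
disease-associated depletion). Antibody counts are negative binomial
with mean `c_i · exp(L[i,p])`, where `c_i` is a lognormal
capture-efficiency scalar (log-SD 0.35) shared across the panel
including H3 — exactly the nuisance that reference normalization
removes, asserted by an invariance test. Gene counts are negative
binomial with log-mean `alpha_g + batch offset + Σ_p beta[g,p]·L[i,p]`
renormalized per nucleus and scaled by a lognormal depth factor;
mitochondrial share is Beta-distributed (mean 2%) with a 2% subpopulation
in a >5% regime, hashtag counts are lognormal (median 800) with a 2%
subpopulation above 4,000, and 1% of nuclei are shallow — so every QC
rule is exercised. Planted-effect genes receive a fixed, well-expressed
baseline (`effect_gene_alpha = 2.0` on the log relative-expression
scale) so the recovery estimand does not fluctuate with a random
per-replicate gene depth. A fixed seed makes the emitted bundle
byte-reproducible.

What the generator does **not** emulate: ambient RNA, doublets, hashtag
cross-contamination, realistic gene–gene correlation structure beyond
the planted protein programs, and genome-scale gene panels. Passing
tests therefore demonstrate correctness of the algorithms and
calibration of the statistics under the stated model, not robustness to
every artifact of real tissue data.

## Validation design and numerical choices

- False-discovery calibration: 50 global-null cohorts (~2,000 nuclei ×
  500 genes) — the fraction of BH q < 0.05 calls stays within the
  nominal level. Recovery: a planted β = +1 gene is recovered positive
  and significant in ≥ 95% of 50 cohort replicates at ~2,000 nuclei.
- Estimator convergence: under the count observation model, the fitted
  slope converges to a pseudo-true value slightly attenuated relative to
  the planted latent-scale effect (ln(x+1) concavity plus nCLR
  measurement noise; ≈0.88 at the default antibody depth), a floor that
  does not shrink with sample size. The monotone-convergence check is
  therefore run on data satisfying the model's assumptions — Gaussian
  linear expression with proteins orthogonal to the covariates — where
  the two-step estimator is unbiased and the mean absolute error halves
  per 4× nuclei (checked at n = 500, 2,000, 8,000).
- CLR exactness is asserted against an explicit product/nth-root oracle
  to 1e-12; OLS residual orthogonality to 1e-8; BH against an
  independent step-up implementation; Fisher p-values against exhaustive
  hypergeometric enumeration.
- Ties in percentile bins go to the lower bin; collinear design columns
  are dropped earliest-first; `n_pcs` and bin warnings are emitted
  rather than silent clamps; degenerate inputs (zero-count nuclei,
  zero-variance contrasts, constant proteins, identical embedding
  points) raise informative errors.
- Problem sizes in the test suite and acceptance script (cohorts of
  ~2,000–4,600 nuclei, 500 genes, 25–50 replicates) are desk-scale
  choices that keep the full suite under a minute while leaving the
  statistical checks well-powered.

## Known limitations

- The model treats batch as a fixed effect; donor random effects are not
  modeled (nucleus-level contrasts likewise treat nuclei as independent,
  matching the plain unpaired tests they mirror).
- The nCLR slope estimated from antibody counts is attenuated relative
  to the latent log-protein scale by measurement noise; sign and ranking
  of effects are preserved, absolute effect sizes are conservative.
- Harmony-style integration, DESeq2 testing, GSEA/pathway scoring,
  doublet detection and hashtag demultiplexing are intentionally
  delegated to the dedicated tools; this package prepares their inputs.
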