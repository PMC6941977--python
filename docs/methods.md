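# Methods

This note documents the statistical procedures implemented in `pewas`, the
assumptions behind them, the synthetic study design used for validation,
and the numerical and design choices that were genuinely open.

## 1. Preprocessing

**Scales.** Methylation beta-values $b \in (0,1)$ are converted to
M-values $M = \log_2(b/(1-b))$, the scale on which methylation differences
are approximately homoskedastic and the EWAS regression is linear.  The
package computes M directly from betas (the standard equivalent of the
intensity-ratio definition, without an offset), because betas are the
portable interchange scale between platforms.  Protein intensities are
natural-log scaled.  Values at exactly 0 or 1 (betas) or ≤ 0 (proteins)
are domain errors — no silent clamping.

**Winsorization.** Per feature, values strictly below the 5th / above the
95th percentile are replaced by the respective percentile.  The percentile
convention is linear interpolation (numpy/R type 7); no convention is
universal, so it is a keyword (`method`).  Under linear interpolation a
second winsorization pass can move boundary values by a sub-grid amount
(the clamped mass shifts the interpolated percentile); exact idempotence
holds under the order-statistic convention `method="lower"`, which the
property tests use.

**Standardization.** Per-feature z-scoring with the sample SD (n−1).
Zero-variance features are an error naming the feature.  Missing values
are excluded from all column statistics and propagate through transforms.

**Probe QC.** Sequential filters in a fixed order — SNP-control probes,
under-measured probes (< 100 measurements), chromosome X, chromosome Y,
non-cg probes — with a ledger counting each probe at the first rule that
removes it.  On a manifest with 450K-like category sizes this retains
470,837 of 485,577 probes.

**Cell deconvolution.** Reference-based estimation in the Houseman
tradition: each sample's marker-CpG betas are projected onto cell-type
reference profiles under non-negativity (exact active-set NNLS via
`scipy.optimize.nnls`), then the weights are renormalized to the simplex.
Renormalization (rather than an equality constraint in the solver) matches
common practice and keeps the solver simple.  A rank-deficient reference
is an error.  At beta-noise SD 0.02 with 6 cell types × 10 markers each,
recovery MAE on known mixtures is < 0.01 (the acceptance bound is 0.05).

## 2. The step-wise EWAS

Every step fits, for each CpG × protein pair, OLS of the residual M-value
on an intercept and the residual log-protein, over pairwise-complete rows;
two-sided p-values use the t distribution with n−2 df.  Pairs with fewer
than 3 complete observations are skipped and counted.  The scan is
vectorized via pairwise-complete cross-moment matmuls, so a full
2,000 × 200 scan is a single pass.

**Residualization is cumulative**: each step regresses the *original*
transformed matrices on all covariates accumulated so far.  For nested OLS
this equals sequential residualization of residuals but avoids numerical
drift.  Covariate expansion: smoking becomes two indicator contrasts
(never/former/current); estimated cell fractions enter minus one column
(they sum to 1 and would be collinear with the intercept); a replication
cohort's genetic and proteomic PCs are appended at the sex step.
Collinear designs are an error naming the offending columns.

**cis-SNP adjustment.** For each feature, every SNP within 1 Mb of its
position/interval is tested by univariate OLS; the most significant is
retained if p < 1e−5, with greedy forward selection on residuals up to
`max_snps` (default 1).  There is no canonical selection rule for this
adjustment; these defaults are an explicit, configurable convention.  Selected SNPs
are residualized per feature on top of the shared design
(Frisch–Waugh-consistent: features and dosages are both projected off the
shared covariates first).

**Attribution and the final set.** The candidate universe for steps ≥ 1
is the step-0 significant set (full re-scans are an option).  A pair
significant at step k−1 but not at k is recorded once in the dropout
ledger under the covariate added at step k; the final set is the pairs
significant at *every* step, so step-0 set = final set ⊎ ledger exactly.
All significance comparisons are strict (p < threshold).

**Diagnostics.** Per-protein genomic inflation
$\lambda = \mathrm{median}\,\chi^2_1(1-p)\, /\, 0.4549$ — the
median-ratio definition, the field standard when λ is reported without a
formula.  The residual-confounder check computes the top 10 PCs
of each residual matrix (features standardized, missing imputed by column
means) and flags any PC whose maximum univariate R² against a feature of
the other data set exceeds 1.5%.  Note the *max*-R² statistic has a null
expectation of roughly $2\log(m)/n$ for m features — about 2% at
m = 1,000, n = 500 — so at desk feature counts the absolute 1.5% flag is
conservative in the direction of flagging; the discriminating quantity is
how far a PC's max R² rises above that order-statistic floor, which the
tests check directly.

**Step-wise vs joint.** `joint_model_check` refits each final pair as one
OLS of M on the protein plus all covariates simultaneously (optionally
with all pairwise covariate interaction products) and reports the slope
shift.  With correlated covariates the shift stays below 0.05 on the
standardized scale; a pair driven by a covariate interaction is exposed
because the protein term loses significance once the product terms enter.

## 3. Replication and power

A discovery pair replicates when its p-value in the replication cohort
(same pipeline, plus PC covariates) passes $0.05/N$, N being the number of
pairs identified at that discovery step.  Pairs untestable in the
replication data count as failures; N is never reduced — conservative,
and consistent with fixed-N thresholding.  Directionality consistency is
the fraction of sign-concordant pairs among nominally significant
replication results (undefined when there are none).

Replication power is a hybrid sampling scheme: the unknown true effect is
drawn from $\mathcal N(\hat\beta, \mathrm{SE}^2)$; for each draw the
two-sided rejection probability at the replication threshold is the
noncentral-t tail with $n_{\mathrm{rep}}-2$ df and SE rescaled by
$\sqrt{n_{\mathrm{disc}}/n_{\mathrm{rep}}}$; power is the mean over draws
(flag at ≥ 95%).  No winner's-curse shrinkage is applied to the discovery
estimate.  The scheme is validated against a brute-force
simulate-and-refit oracle to ±0.02.  (The opposite-tail noncentral-t term
underflows in scipy at large noncentrality and is replaced by its limit.)

## 4. pQTM characterization

- **cis/trans**: cis iff same chromosome and distance from the CpG to the
  protein-gene interval ≤ 1 Mb (0 inside the interval; the boundary is
  inclusive — the convention is declared since sources are ambiguous).
- **Signal grouping**: connected components of the bipartite CpG–protein
  graph, optionally pre-merging CpGs within `locus_merge_bp`; components
  are labeled by their lexicographically smallest protein (overridable).
- **Cross-reactivity**: pQTMs whose CpG or aptamer appears on a flag list
  are marked, never deleted.
- **Annotation enrichment**: per category, the 2×2 table of set membership
  × annotation over the manifest background; sample OR with
  Haldane–Anscombe 0.5 correction when a cell is zero, exact two-sided
  Fisher p (delegated to `scipy.stats.fisher_exact`, verified against a
  hypergeometric-enumeration oracle to 1e−10), log-OR normal 95% CI.
- **Hi-C contact enrichment**: CpGs and protein gene starts are placed in
  1-kb bins; fold = observed contact-positive fraction over the mean of
  size-matched random CpG×protein pairings redrawn from the observed
  pools; empirical p = (1 + #{random ≥ observed})/(n_random + 1).  Because
  the background pool contains the true pairs, a planted 1.7-fold excess
  re-estimates slightly low (≈1.6 at 98 pairs over an 89 × 15 pool) — an
  inherent property of size-matched pool backgrounds, not an error.
- **eQTM overlap**: a join of pQTM CpGs against a local CpG–transcript
  lookup table, one row per matching transcript.

## 5. Downstream associations

Metabolic syndrome follows the harmonized ≥3-of-5 rule (waist ≥ 94/80 cm
by sex; TG ≥ 150 mg/dl or lipid drug; HDL < 40/50 mg/dl by sex or lipid
drug; BP ≥ 130/85 mmHg or drug; glucose ≥ 100 mg/dl or drug).  The two
lipid-drug criteria share one `lipid_drug` flag, as typical tables carry a
single indicator.  Missing components count as not-met (drug flags can
still satisfy a criterion) and the missing count is reported; the rule is
monotone — worsening a component never switches the flag off.

Phenotype scans model the omics feature as the outcome
(feature ~ phenotype + age + sex; binary phenotypes enter as 0/1
regressors) with Bonferroni thresholds 0.05/n_features (e.g. 5.6e−4 at 89
CpGs, 3.3e−3 at 15 proteins).  Metabolite scans add cell fractions and
genetic PCs as covariates, thresholded at 0.05/(n_CpGs × n_metabolites)
(2.5e−7 at 89 × 2,251) — computed from the product formula throughout.
Joint variance explained fits one OLS of a protein on all of its pQTM
CpGs and reports R² and adjusted R²; designs wider than the sample are
refused (regularized variants are out of scope).

## 6. The synthetic study design

The generator emulates a two-cohort pEWAS: a discovery cohort (default
500 samples × 2,000 CpGs × 200 proteins) and a replication cohort at
344/944 of its size, sharing planted effects and array/annotation
structures but redrawing all samples.  Defaults are the validation
conditions and are not tuned per run:

- **Covariates**: sex ~ Bernoulli(½); age ~ U(32, 81); BMI ~ N(27.5, 4.5²);
  smoking never/former/current (0.45/0.30/0.25) with a 0/0.5/1 burden
  score; diabetes via a logistic link on age and BMI (mild, realistic
  correlation that makes attribution non-trivial).
- **Cell composition**: Dirichlet around a granulocyte-dominated
  6-type profile (concentration 60); reference profiles separate each
  type's markers by ≥ 0.5 beta so deconvolution is identifiable; marker
  betas are mixtures of the reference by the true fractions plus
  beta-noise 0.02.
- **Planted effects**: `effect_size` is the induced *pair correlation* —
  each side loads on the shared driver with correlation
  $\sqrt{|e|}$, the sign on the protein side.  The default palette plants
  6 pairs per driver (direct + the seven covariates) with |e| cycling
  over {0.4, 0.5, 0.6} and alternating sign, plus explicit nulls.  No
  published effect-size distribution exists for real pQTMs; these values
  are chosen so that recovery is a sharp test (well-powered at the
  desk-scale Bonferroni threshold, yet fully removed by residualizing the
  true driver).
- **Non-marker methylation** is Gaussian on the M scale (per-CpG mean ~
  N(0, 1.8²), noise SD 0.3 × U(0.6, 1.6)) mapped to betas by the inverse
  M-transform; proteins are Gaussian on the log scale (mean ~ N(7, 0.8²)).
- **cis-SNPs**: each snp-driven pair gets one causal dosage
  (MAF ~ U(0.1, 0.4)) within 1 Mb of its CpG, plus a null SNP in the same
  window and background SNPs far away.
- **Replication structure**: three genetic and three proteomic latent
  factors (SD `ethnicity_pc_sd`, default 1) load sparsely on CpGs and
  proteins; their standardized values are observed as `geno_pc*` /
  `proteo_pc*` covariates, emulating a multi-ethnic cohort with mild cell
  lysis.
- **Hi-C**: contacts over the planted-CpG × protein-gene bin pool at base
  rate 0.15, with a 1.7-fold excess on direct (true pQTM) pairs.
- **Determinism**: one master seed; structure tables (manifest, reference,
  SNP map, Hi-C) derive from the seed alone so both cohorts share them;
  per-cohort draws derive from (seed, cohort).  Identical configs produce
  byte-identical bundles.

**What the generator does not emulate** — array noise chemistry, batch and
plate effects, LD beyond one causal SNP per pair, realistic annotation
correlation structure, non-Gaussian protein tails.  Passing tests
therefore demonstrate that the *procedure* recovers planted causal
structure under its own assumptions, not that real cohorts meet those
assumptions.

## 7. Validation experiments and problem sizes

The acceptance suite runs, on one CPU in a few minutes: driver-attribution
recovery ≥ 80% over 20 seeds at 500 × 2,000 × 200 (observed ≈ 95%;
residual misses are diabetes-driven pairs absorbed by the correlated age/
BMI steps); family-wise error on 200 all-null 200 × 200 × 25 cohorts
within 3 binomial SEs of α; Fisher p vs enumeration exhaustively for all
2×2 tables with n ≤ 40 plus 2,000 sampled tables up to n = 200 (full
enumeration to n = 200 is ~1.4M tables and is not informative beyond the
sample); λ on uniform p as the mean of ten 100k batches (a single batch
has MC SD ≈ 0.008, wider than the ±0.01 band); cell-fraction MAE at noise
0.02; Hi-C fold recovery at the study-like 98-pair geometry; and the
power estimator against its refit oracle (the oracle's fixed design is
normalized to unit second moment so the comparison isolates estimator
error rather than design-draw noise).

## 8. Known limitations

- Attribution is order-dependent by design: a pair driven by a covariate
  correlated with an *earlier* step's covariate can be attributed to the
  earlier step (seen for diabetes after BMI).  This mirrors the method
  itself, not an implementation artifact.
- Scan p-values use n−2 df even after residualization (the conventional
  choice); with many covariates and small n this is slightly
  anticonservative, which the null FWER experiment bounds empirically.
- The PC residual-confounder flag uses an absolute 1.5% cut on a max-R²
  statistic whose null level depends on (n, m); interpret flags relative
  to the noise floor at the data's own dimensions.
- `select_cis_snps` defaults (1 SNP per feature, α = 1e−5, 1 Mb) are a
  declared convention, not an estimate.
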