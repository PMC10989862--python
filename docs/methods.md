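# Methods

This note documents the models implemented in `vinegp`, the choices made
where the design was genuinely open, and what the synthetic data generator
does and does not emulate.

## Study system

The package targets breeding programs built from a handful of biparental
crosses that share parents (elite wine varieties crossed with
mildew-resistant hybrids). Two sets of offspring exist: a phenotyped and
genotyped **training set** (TS) and a genotyped-only **validation set**
(VS) of selection candidates pre-screened by marker-assisted selection on
major resistance loci. The analysis chain extracts genotypic values from
lightly replicated field trials, trains genomic prediction models on them,
predicts the VS, and ranks candidates against a breeder-defined ideotype.

## Genotype quality control (`genomat`)

Dosages are counts of the alternate allele (0/1/2, `NaN` for missing).
Default thresholds: markers with more than 10% missing calls are removed,
then individuals with more than 50% missing calls, then missing values are
imputed, then markers with minor allele frequency below 1% are removed.
Imputation is the deterministic within-cross mean (global mean fallback):
the contract it serves is "no missing values downstream", not genotype
calling accuracy, and it keeps the pipeline free of external phasing
software. Imputed dosages may be fractional.

The additive genomic relationship matrix is the VanRaden form
`K = ZZ' / (2 Σ p_j (1 − p_j))` with `Z` the dosage matrix centered by
twice the observed allele frequency. Relatedness is therefore relative to
the genotyped panel: within-family values are positive only when the panel
contains enough unrelated material to anchor the frequencies.

Outlying individuals (pedigree errors, selfings, contamination) are
flagged per cross by the squared Mahalanobis distance of each member to the
within-cross mean on the first *q* = 5 marker-PCA dimensions (configurable),
referred to a χ²_q upper tail at α = 0.01. The score space is a
documented choice; the chi-square reference makes the null flag rate equal
α, which the tests verify at n = 10,000.

Marker intersection between separately genotyped populations matches on
(chromosome, bp position) and harmonizes allele orientation by flipping
dosages (`2 − dosage`) when ref/alt are swapped. Coordinates are 1-based
throughout.

Read-depth-based genotype filters are out of scope: the pipeline starts
from called dosages and no read data exist downstream of that point.

## Per-trait mixed model (`phenomodel`)

For a trait observed over two (or more) years on a p-rep grid:

    y_ijkl = μ + Y_k + G_i + C_j + x_r + y_c (+ extras) + ε_ijkl

with year fixed and genotype (nested in cross), cross, row and column
independent random intercepts: G ~ N(0, σ²_G), C ~ N(0, σ²_C), and so on.
A homogeneous genotype variance across crosses is assumed. Program-specific
extra random intercepts (e.g. resistance-locus classes or pruning type) can
be added as additional categorical columns; they are eligible for the same
elimination step.

**Estimation.** The restricted likelihood is profiled over the residual
variance and parameterized by log variance ratios γ_k = σ²_k/σ²_ε; all
linear algebra runs through the q×q system `M = I + S Z'Z S`
(S = blockwise √γ), so an evaluation costs one Cholesky of dimension
q = total number of random levels. Optimization is derivative-free:
bounded Powell over log γ (bounds e^−15 … e^10), followed by two cyclic
Brent polishing passes per coordinate; single-component models use Brent
directly. Tolerances are set so balanced designs reproduce closed-form
ANOVA estimators to 1e−6. Convergence failure raises with the last
iterate.

**Model selection.** Backward elimination: each random term is tested by a
REML likelihood-ratio test against χ²₁ (the plain χ²₁ reference, not the
boundary 50:50 mixture — conservative, i.e. it keeps terms slightly too
often); the least significant term with p ≥ 0.05 is dropped and the
procedure repeats. The fixed year term is then tested by a Wald F-test on
the maximum-likelihood fit with residual denominator degrees of freedom
(n − rank X). If the genotype term itself is eliminated the trait is
flagged non-genetic and falls back to raw per-genotype means.

**Heritability.** Broad-sense, on the genotype scale:
`H² = (σ²_G + σ²_C) / (σ²_G + σ²_C + σ²_ε)`. Spatial and year variances are
excluded by definition; the synthetic generator uses the same definition
when scaling trait architectures, so target and estimate are commensurable.

**Genotypic values and deregression.** The genotypic value of genotype i is
the genotype BLUP plus its cross BLUP when the cross term survived
selection. Its PEV is the conditional variance of that *sum*: the two
per-level conditional variances (from the mixed-model-equation inverse,
including fixed-effect uncertainty) plus twice their conditional
covariance. The covariance term matters: with few cross levels it is
markedly negative (the two BLUPs share information), and dropping it
overstates PEV enough to bias deregression upward by ~10-15%.
Deregression divides by the reliability:

    drgBLUP = BLUP / (1 − PEV/σ²_g),    σ²_g = σ²_G + σ²_C.

Genotypes with PEV ≥ σ²_g (reliability ≤ 0) are excluded from the trait
with a recorded reason — the only value-preserving option. The meaningful
direction of the "slope 1" check is the regression of drgBLUP on the true
genotypic value: BLUPs regress at the mean reliability (< 1), deregressed
values at 1; simulations at h² = 0.4 verify a mean slope of 1 ± 0.1.
Traits phenotyped a single year skip the model entirely: the raw
observation (mean over replicates for controls) is used, with PEV and
reliability undefined.

## Genomic prediction (`genopred`)

**GBLUP.** `y = 1μ + g + e`, `g ~ N(0, σ²_u K)` with K the VanRaden GRM of
the training dosages. One spectral decomposition of K reduces REML to a
1-D bounded search over log(σ²_e/σ²_u) (tolerance 1e−10). The fitted model
is re-expressed as ridge marker effects `β = Z'(K + λI)^{-1}(y − μ̂)/c`, so
kinship-form and marker-form GEBVs agree to machine precision (tested at
1e−8) and out-of-sample prediction is
`μ̂ + (X_new − 2p_train) β`. PEVs of training GEBVs come from
`σ²_u K − σ²_u K P K σ²_u`; validation PEVs from the conditional formula
`σ²_u diag(K_vv − K_vt (K_tt + λI)^{-1} K_tv)`.

**Lasso.** Pathwise coordinate descent on standardized dosages, written
against the Gram matrix (covariance updates), minimizing
`(1/2n)‖y − Xβ‖² + λ‖β‖₁` along 100 log-spaced penalties from λ_max
(smallest all-zero penalty) down to λ_max/100; λ is chosen by 5-fold inner
cross-validation on mean squared error (minimum rule; the 1-SE rule is a
one-line change at the call site but is not exposed as a default).
Coefficients return on the dosage scale. Solutions satisfy the KKT
conditions to 1e−6, checked against an independent residual-based gradient
and cross-checked against scikit-learn's `Lasso` at the same penalty. The
binomial variant runs IRLS with penalized weighted coordinate descent
(weights clipped below at 1e−5), selecting λ on inner-CV binomial
deviance, with classification at probability 0.5.

**Cross-validation.** K = 5 folds, R = 10 repetitions by default; folds
are plain random partitions (family structure is not stratified by
default, matching unbalanced cross sizes; stratification would be a
caller-side grouping). Fold predictive ability is the Pearson correlation
between observed and predicted values (accuracy for binary traits); the
summary is the mean over the K·R fold values and its standard error
`sd/√(K·R)`. A held-out fold with zero variance yields a missing fold PA,
excluded with a warning. The better of GBLUP and lasso is chosen per
trait; exact ties resolve to GBLUP.

**Second deregression.** Validation predictions are deregressed to restore
the trait scale for the selection index. For GBLUP the reliability formula
is applied to the centered genomic value with σ²_g = σ̂²_u and the
conditional PEV above, re-adding the intercept (so PEV = 0 is exactly the
identity and the trait mean is preserved). For the lasso, shrinkage is
undone by refitting ordinary least squares on the active markers in the
training set (pseudo-inverse under collinearity); an empty active set
degenerates to the intercept with a warning.

## Selection index (`selindex`)

The multitrait genotype–ideotype distance index:

1. Optimum-direction traits become `|value − optimum|`, direction
   minimize.
2. Each trait is rescaled to 0–100 with 100 at the desired pole
   (`100(x−min)/(max−min)` for maximize, mirrored for minimize), then
   multiplied by its weight. Predictive abilities are the natural weights;
   traits with weight below the configured threshold (0 by default, 0.5 in
   a strict setting) are excluded. Because the factor analysis below works
   on the correlation matrix, positive column scalings are absorbed by
   standardization: the operational content of a weight is the
   inclusion/exclusion decision, which makes "zero weight ⇒ no influence"
   an exactly testable property.
3. Exploratory factor analysis of the trait correlation matrix:
   eigendecomposition, Kaiser retention (eigenvalue ≥ 1, at least one
   factor), varimax rotation with a deterministic sign convention
   (non-negative loading sums), regression-method scores computed in the
   retained eigen-space (`R⁺Λ = V_k D_k^{−1/2} Q`), which also covers
   rank-deficient correlation matrices from collinear traits.
4. The ideotype is the all-100 (weighted) vector — the attained column
   maxima of the rescaled matrix — pushed through the same
   standardization and score operator. MGIDI_i is the Euclidean distance
   of genotype i's factor scores to the ideotype's; ranks ascend with a
   stable tie-break on genotype id; per-factor squared-distance shares
   (summing to 1) give the strength/weakness profile of each selection.

A genotype at the desired pole of every trait has distance exactly 0 and
rank 1; ranks are invariant to positive affine transforms of any input
trait. Predicted berry color (binary) is reported alongside selections,
never as an index trait.

## Synthetic data (`simcross`)

The generator reproduces the statistical structure the analysis assumes:

- **Founders**: phased haplotype pairs at per-SNP allele frequencies drawn
  uniformly in a configurable MAF range (default 0.05–0.5); markers evenly
  spaced on each chromosome, physical positions by the fixed
  1 cM = 1 Mb convention.
- **Meiosis**: crossover counts per chromosome Poisson(L/100), positions
  uniform, no interference (Haldane) — the simplest defensible model, with
  the closed-form recombination fraction `r = (1 − e^{−2d/100})/2` verified
  against 10,000 simulated gametes.
- **Traits**: additive QTL effects (gaussian, laplace or ±1) at sampled
  loci, plus a gaussian per-cross shift scaled so the variance of cross
  means approximates the configured fraction of the genetic variance; the
  whole genetic value is rescaled so its realized variance matches the σ²_g
  implied by the target H² and residual variance exactly.
- **Field design**: one plant per genotype plus replicated controls
  (default 5 replicates, mirroring repeated check varieties), crosses
  filling the grid contiguously with controls on random cells; row, column,
  year and residual effects drawn at their configured variances (defaults
  in the acceptance study: spatial 0.1–0.2, year 0.2–0.5, residual 1.0 —
  moderate nuisance variances relative to σ²_g ≤ 1.5).
- **Binary major-gene trait**: carrier status at one segregating locus
  flips the label with probability 1 − penetrance (default 0.95).
- **Missingness**: uniform independent masking (default 5%).

Not emulated: sequencing reads and depth-dependent genotyping error,
linkage-disequilibrium structure beyond what meiosis creates in two
generations, genotype-by-environment interaction, dominance and epistasis,
selfing or backcross pedigrees. Passing tests therefore demonstrate the
correctness and calibration of the estimators under the assumed model, not
robustness to, e.g., G×E or non-additive variance in real trials.

## Problem sizes

The default test and acceptance configurations use 8 crosses over 6
shared parents, 200–400 training genotypes, 300–600 SNPs, 2 years and
moderate replicate counts — large enough for the asymptotic checks (REML
recovery within 15%, CV calibration, architecture interaction over 20
seeds) while keeping a full run on one CPU in minutes. All randomness
flows from one master seed through a stable blake2s hash per stage, so
every run is reproducible bit for bit and any stage can be re-run in
isolation.

## Known limitations

- Deregressing the genotype+cross sum with a single combined reliability
  cannot perfectly undo the different shrinkage of the two components;
  with 8 crosses a small (~5%) upward bias of the slope against truth
  remains, inside the tested 1 +/- 0.1 band.
- The χ²₁ reference for variance-component LRTs is conservative at the
  boundary; terms are retained slightly more often than a 50:50 mixture
  reference would.
- Across-population prediction evaluates on target genotypes not present
  in the training source; when the source *is* the target it falls back to
  the within-population cross-validation scheme rather than reporting an
  in-sample correlation.
- Within-cross mean imputation ignores linkage information; its accuracy
  is far below haplotype-based imputation and it is not intended as a
  substitute where genotype accuracy matters.
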