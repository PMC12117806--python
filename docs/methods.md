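# Methods

## Models

### Univariate kernel models

For a trait `y` with one record per animal,

    y = X b + u + e,   u ~ N(0, sigma2_r K),   e ~ N(0, sigma2_e I)

where `K` is either the genomic relationship matrix **G** (then
`u` are breeding values and sigma2_r/(sigma2_r+sigma2_e) is the
heritability) or the metagenome relationship matrix **M** (then `u` are
microbial values and the ratio is the microbiability). Estimation is
REML. Because there is one record per animal, rotating the model by the
eigenvectors of `K` diagonalises the covariance, and the restricted
likelihood profiles analytically over the residual variance; what
remains is a one-dimensional bounded search over
log lambda = log(sigma2_r/sigma2_e) on [-12, 12]. Each likelihood
evaluation is O(n·p), so a fit costs one eigendecomposition plus a
scalar search. The rotated likelihood is tested for equality with a
dense-matrix evaluation of the Patterson–Thompson restricted likelihood
on instances up to n = 50.

Random effects are predicted by BLUP. For validation animals,
`u_target = sigma2_r K[target,train] V^-1 (y_train - X_train b)` — the
conditional mean of a joint multivariate normal, which is also how the
test oracle computes it.

### Bivariate proxy-trait model

The adjusted chamber trait y* and its metagenome prediction m̂ (both
observed on the validation animals) follow

    [u1; u2] ~ MVN(0, G ⊗ B),   [e1; e2] ~ MVN(0, I ⊗ C)

with 2×2 genetic and residual covariance matrices B and C. Rotating
both trait vectors by the eigenvectors of G factorises the restricted
likelihood into n independent bivariate normal terms with covariance
`d_k B + C`, evaluated vectorised with closed-form 2×2 inverses. B and
C are parameterised through their Cholesky factors, which enforces
positive semidefiniteness; the genetic correlation
rho = B12/sqrt(B11·B22) therefore never leaves [-1, 1]. Optimisation is
L-BFGS-B from three starts built from the two univariate fits (genetic
correlation 0, +0.5, -0.5). The printed model has no fixed effects; a
per-trait general mean is nevertheless fitted because y* and m̂ are
centred only approximately, which costs nothing and stabilises the fit.

Standard errors come from the inverse observed information (central
finite differences of the REML log-likelihood in the variance-component
coordinates, relative step 1e-4); heritabilities and correlations get
delta-method standard errors through a numerical Jacobian of the
transform. The delta-method SE of the univariate ratio is checked
against a parametric bootstrap (within 25% on a fixed scenario).

### Relative efficacy of indirect selection

`rho_g * sqrt(h2_proxy / h2_direct)` — classical selection-index theory
for the expected correlated response when selecting on the proxy
instead of the goal trait, at equal selection intensity and accuracy of
breeding-value estimation proportional to sqrt(h2).

## The MRM recipe and its choices

Counts + 1 → proportions (sample row totals) → log10 → z-score every
tag within every cohort (flowcell × flock × birth-year × sex) →
pairwise Pearson correlation across tags; diagonal set to exactly 1.

* Row totals for the proportion step are those of the pseudo-counted
  matrix, so proportions sum to one and are always positive. The
  alternative (raw read totals) differs by a per-sample constant that
  almost entirely cancels in the later correlation; the choice is
  numerically immaterial.
* The per-cohort standard deviation uses the n−1 denominator.
* A tag with zero variance within a cohort carries no information
  there; its normalized values are set to 0 for that cohort rather
  than dropping the tag, keeping tag sets aligned across cohorts.
  Cohorts of size 1 are an error (the pipeline drops samples whose
  cohort is orphaned by read-count QC).
* A `clr` mode replaces the first two steps with the centred log-ratio;
  on dense data the two modes produce off-diagonals correlating > 0.95,
  asserted as a property test (the threshold is this package's choice).

The GRM is VanRaden method 1 with SNP filters MAF > 0.01 (strict) and
call rate ≥ 0.70. Missing genotypes are handled pairwise: both the
numerator and the 2Σp(1−p) denominator of each entry are restricted to
the SNPs non-missing in both animals, which keeps entries correctly
scaled under missingness at random. Such a matrix need not be positive
semidefinite; mixed-model routines clip negative eigenvalues to zero
(nearest-PSD projection in the eigenbasis) and reject matrices whose
most negative eigenvalue exceeds 5% of the largest.

## Phenotype preparation

Gas traits are scaled per measurement lot: each value is divided by its
lot mean and multiplied by the overall population mean (defaults 7.5
g/day CH4, 623 g/day CO2, 0.032 ratio). This removes the lot-level
scale effect caused by variable time off feed and makes every lot mean
equal the overall mean exactly — an identity the tests assert to
floating precision. Records flagged unreliable are NaN and excluded
from lot means. Fixed effects (birth/rearing rank class, age-of-dam
class, birth-date deviation covariate, and a flock × birth-year × sex
contemporary group) are removed by a rank-revealing least-squares fit;
the residual is the adjusted phenotype y*. The ratio trait is analysed
×100 (as a percentage) in the bivariate model; a property test confirms
this rescaling leaves heritabilities and correlations unchanged.

## Validation schemes

Forward prediction trains on all earlier birth years and validates on
the latest; the presence filter for tags is computed on training
samples only. Cohort-blocked cross-validation packs whole cohorts into
folds (default 11) longest-first onto the currently smallest fold, with
a preference for folds already holding the same flock when the size
balance (≤ 1.1× target) permits; cohorts are never split, so no fold
shares cohort-level environment with its training data. The presence
filter for CV uses all samples. Accuracy is the Pearson correlation of
the prediction with y* per cohort (FP) or per fold (CV); the slope of
y* on the prediction measures bias (1 = unbiased). Summaries are
group-size-weighted means; their SE is the weighted standard deviation
over the square root of the effective number of groups — the figure
summary the field uses, made explicit here.

## The synthetic-data generator

What it emulates: binomial SNP genotypes with allele frequencies in
[0.05, 0.5] (all pass the MAF filter by default; widen the range to
stress filtering) and missingness 0.04 (matching a mean call rate of
0.96); breeding values built from marker effects so cov(g) = sigma2_g G
for the realized GRM; microbial values sharing a latent driver with g
(cor = rho_gm, default 0.75, which is what induces the bivariate
genetic covariance); a log-linear latent-abundance tag model (baseline
skew → sparsity; per-cohort batch shifts → exactly the nuisance the
cohort normalization removes; per-animal loadings on the standardized
microbial value → signal) with multinomial sampling at log-normal
depths (median 300k reads, so a small realistic fraction of samples
fails the 100k QC); multiplicative log-normal lot effects (sd 0.10) on
lots of 12, because time off feed scales emissions — whether the real
lot effect is additive or multiplicative is not knowable from the
published analysis, and multiplicative is the reading consistent with
scaling by lot means; and modest real fixed effects for the adjustment
step to remove. Default variance components sigma2_g = 0.16,
sigma2_e = 0.84, sigma2_m = 1.0 give a heritability of 0.16 and
microbiability of 0.54, typical of chamber CH4 in grazing lambs.

What it does not emulate: restriction-site biology, sequencing error in
tag sequences, PCR duplicates, real taxonomic composition, pedigree
(family) structure, repeated measures, or maternal effects. Passing
recovery tests therefore show that the estimators are correct for the
assumed covariance structures, not that real rumen data satisfies those
structures.

Note on `true_h2`: the generator reports
sigma2_g/(sigma2_g + sigma2_e), the direct genetic fraction. When
rho_gm ≠ 0 part of the microbial variance is also genetic, so the
realized heritability of the full phenotype exceeds `true_h2`; recovery
tests that target `true_h2` set sigma2_m = 0.

## Recovery-study design

The recovery protocols (in `rmcblup.recovery`) simulate under the
model each estimator assumes and check the mean estimate over 30
seeded replicates: heritability 0.16 at 2000 animals × 5000 SNPs;
microbiability 0.64 and 0.18 at 1000 animals × 3000 tags (the tag
dimension is scaled down from the >200k of a full campaign — the MRM is
a correlation matrix either way, and 3000 tags already reproduce its
spectral character); genetic correlation 0.75 at 1000 animals. For the
bivariate study the marker count is 800: a panel of *unrelated*
simulated animals at high marker density yields a GRM much less
informative than a family-structured field population, and 800 markers
at n = 1000 matches the information content of such data as gauged by
the delta-method SE of the genetic correlation (~0.09–0.12). REML
ratio estimates are truncated at 0, so the low-signal microbiability
study has a small known upward bias (~0.02) — visible, documented, and
inside the study's tolerance.

## Numerical conventions

* Log-likelihood convention: −½[log|V| + log|X'V⁻¹X| + y'Py +
  (n−p)·log 2π]; with this constant the bivariate log-likelihood at
  zero covariances equals the sum of the two univariate ones.
* Convergence: bounded scalar search to xatol 1e-10 (univariate);
  L-BFGS-B with ftol 1e-12/gtol 1e-8, max 200 iterations, best of three
  starts (bivariate). Boundary estimates are reported at the boundary;
  the observed information can then be singular, in which case standard
  errors are flagged unreliable rather than fabricated.
* Kernel draws for simulation use a Cholesky factor of K + 1e-6 I.
* PCA of a relationship matrix: eigendecomposition, scores scaled by
  sqrt(eigenvalue), signs fixed by the largest-magnitude loading,
  variance explained relative to the positive spectrum.

## Known limitations

* The fixed-effect structure for liveweight-type traits (mob
  interactions) is not modelled; the design builder accepts arbitrary
  factor combinations instead.
* Single-kernel models only: G and M are fitted separately, never
  jointly in one equation.
* Standard errors mirror the delta-method construction of mainstream
  REML software but exact numerical equivalence with any particular
  program is not claimed.
* The CV fold packer is a deterministic stand-in for hand-curated
  cohort groupings; it reproduces their qualitative size balance, not
  any specific composition.
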