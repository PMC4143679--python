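# Methods

## The association model

pleioscan tests association between a biallelic SNP and a k-dimensional
phenotype vector by *reverse regression*: the minor-allele count
`N ∈ {0, 1, 2}` is modelled as `Binomial(2, p(X))` with the canonical
logistic link `logit p(X) = β₀ + Σⱼ βⱼ Xⱼ`. Under Hardy–Weinberg-style
exchangeability of the two allele copies, this is exactly logistic
regression on the 2n allele observations, so standard GLM theory applies.
The association test is the likelihood-ratio statistic
`Λ = 2(ℓ̂_full − ℓ̂_null)` against `χ²_k`. Conditioning on the phenotypes
means their joint distribution never has to be specified: correlated,
skewed, or binary components are all legitimate regressors, which is what
makes the approach attractive for multivariate and longitudinal traits.

Assumptions worth stating: individuals are unrelated (no kinship
correction), the genotype effect is additive on the log-odds of carrying a
minor allele, and the χ²_k reference relies on the usual asymptotics (at
n ≈ 100+ with k ≤ 4 the calibration experiments below show it holds well).

### Fitting

The null model has a closed-form MLE, `β̂₀ = logit(Σᵢ Nᵢ / 2n)`; a SNP that
is monomorphic in the analysed sample raises `MonomorphicError` (QC
normally removes these first). The full model is maximised by
Newton–Raphson with step-halving, started at the null intercept, declaring
convergence when the relative log-likelihood change drops below 1e-8
(default; `max_iter=100`). Both log-likelihoods include the `log C(2, Nᵢ)`
constant, so reported values are true log-probabilities; the constant
cancels in Λ. Numerical guards:

- rank-deficient designs (e.g. a phenotype column collinear with the
  intercept) raise `DegenerateDesignError`;
- inside `lrt_test`/`scan`, zero-variance phenotype columns are instead
  dropped with a warning and the degrees of freedom reduced; if every
  column is constant the statistic is exactly 0 with p = 1;
- (quasi-)complete separation is flagged rather than raised: a fit whose
  coefficients run past 25 in magnitude, or whose fitted allele
  probabilities are numerically 0 or 1 (within 1e-7), is returned with
  `converged=False`, and the scan layer records the SNP with a missing
  p-value. These SNPs are excluded from the FDR denominator because no
  valid p-value exists for them;
- a numerically slightly negative Λ (> −1e-8) is clipped to 0.

The log-likelihood uses `log(1+eˣ) = logaddexp(0, x)` and is stable for
linear predictors up to ±700.

## Preprocessing of longitudinal phenotypes

Blood-pressure-like traits are treated as log-normal: each trait is
natural-log transformed (any non-positive observed value is a hard error
naming the offending record). A one-sample Kolmogorov–Smirnov diagnostic
against a moment-matched normal is provided as an advisory check; it uses
estimated parameters without a Lilliefors correction and never gates the
pipeline.

**Imputation.** For each trait separately, the T time points are modelled
as one multivariate normal and fitted by EM over the arbitrarily-missing
data. The E-step computes per-row conditional means *and* conditional
covariances of the missing block given the observed block; the M-step
updates μ from the completed rows and Σ from the completed second moments
including the conditional-covariance correction (omitting it is the classic
single-fill mistake that biases variances downward — a `single_pass` flag
exposes exactly that conditional-mean-only fill for comparison). The
observed-data log-likelihood is tracked and is non-decreasing by
construction; iteration stops at relative change < 1e-8 (max 500
iterations). Missing entries are then replaced by their conditional mean
`μ_Y + Σ_YZ Σ_ZZ⁻¹ (Z − μ_Z)`; fully missing rows receive μ with a
warning, a singular observed block falls back to a pseudo-inverse. Traits
are imputed independently of each other because the phenotype vector is
defined per trait; cross-trait information is deliberately not pooled.
(Note the conditional-mean formula is the "+" form — the multivariate
normal conditional expectation; a "−" in front of the regression term is a
typo occasionally seen in print.)

**Covariate adjustment.** After imputation, each trait at each time point
is residualised by OLS on an intercept, age, smoking status and medication
indicator. Individuals missing any covariate at any time point are dropped
from the analysis entirely, producing a single analysis sample for all
phenotype designs (mirroring how cohort analyses shrink, e.g. 157 → 139).
A covariate constant within the kept sample is dropped from that regression
with a warning.

**PCA.** Principal components are taken from the covariance (not
correlation) matrix of the column-centred residuals — all columns share
units after adjustment. Loadings are signed so the largest-magnitude entry
of each is positive, making scores reproducible across runs and platforms.

**Phenotype-vector designs.** T1/T2: all T adjusted time points of
trait 1/trait 2 (k = T). T3/T4: the first `n_components` PC scores of one
trait (default 2). T5: the concatenated leading PCs of both traits
(k = 2·n_components, i.e. 4 by default).

## QC and the genome scan

SNPs are recoded so the counted allele is the minor one (a 0.5 frequency
tie keeps the input coding), then filtered: MAF must be at least 0.01
(boundary inclusive; MAF uses non-missing genotypes only), and the exact
conditional Hardy–Weinberg test must not fall below `0.05 / M` where M is
the number of SNPs entering QC. The exact test enumerates all heterozygote
counts compatible with the observed allele counts on the log scale; an
asymptotic chi-square variant is available behind `hwe_method="chisq"`.

The scan applies per-SNP casewise deletion of missing genotypes, runs the
LRT for every QC-passing SNP, and corrects the valid p-values by
Benjamini–Hochberg (via `statsmodels.stats.multitest`, checked in the test
suite against a literal step-up implementation) at an overall FDR of 0.05.
Reports rank by ascending p-value with ties broken by chromosome then
position, and numeric columns are serialised with fixed scientific
formatting so repeated runs are byte-identical.

## The simulation study

`simulate_genotypes` draws HWE genotypes (`Binomial(2, MAF)`, default MAF
0.3 — a common variant, matching the method's common-variant focus).
`simulate_phenotypes` implements three pleiotropic bivariate models with
residual correlation ρ:

- **bivariate_normal** — `traitⱼ = effectⱼ·N + eⱼ`, `(e₁,e₂)` standard
  bivariate normal with correlation ρ; effects are per-allele shifts in
  residual-SD units and their signs set the direction of pleiotropy.
- **bivariate_chisq** — each trait is the sum of squares of 3 latent
  normals; latent pairs across traits are correlated at √ρ so the traits'
  correlation is ≈ ρ (squares of ρ*-correlated normals correlate at ρ*²);
  supported for ρ ≥ 0 only. The genotype shifts one latent mean by
  `effectⱼ·N`, i.e. acts on the noncentrality — the trait-scale effect is
  therefore direction-free, so opposite-direction scenarios use the normal
  model.
- **normal_binary** — trait 1 as in the normal model; trait 2 is the
  indicator that a correlated latent normal shifted by `effect₂·N` exceeds
  the threshold giving 30% prevalence under the null (prevalence is a
  config knob).

`estimate_type1_power` runs `reps` replicates (default 1000) of `n`
individuals (default 500) and, on the *same* data per replicate (common
random numbers, so comparisons are paired), evaluates four analyses: the
bivariate LRT (k=2), each univariate LRT (k=1), and a k=1 LRT on PC1 of the
two traits, with PC1 re-estimated within each replicate from the trait
covariance. Per-replicate seeds are spawned deterministically from the
scenario seed, so a `SimConfig` fully determines its `PowerReport`. Fit
failures count as non-rejections and are tallied separately.

Scenario values used by the acceptance checks: effect sizes ±0.4 per allele
(power scenarios), ρ = 0.1/0.35/0.7 for the low/medium/high correlation
regimes, α = 0.05. At these paper-scale effect sizes all non-PC1 analyses
sit near power 1 at n = 500; the informative contrasts are the type-I
calibration and the collapse of PC1 under opposite-direction effects.

## The synthetic end-to-end study

`simulate_study_dataset` emulates a longitudinal blood-pressure cohort:
log-normal SBP/DBP over 4 examinations built from a per-subject random
intercept (intra-class correlation 0.4, so PC1 carries ≈ 55% of the
within-trait variance and the first two PCs ≈ 70–85% after adjustment),
total log-scale SD 0.12, age/smoking/medication effects on the traits,
MCAR phenotype missingness per examination at (8%, 35%, 35%, 75%), ~7% of
individuals with an incomplete covariate record (dropped at adjustment),
2% missing genotypes, and 500 HWE SNPs of which one shifts the
subject-level component of *both* traits by 0.8 within-trait SD per minor
allele — a deliberately strong pleiotropic signal so the benchmark has an
unambiguous ground truth. Defaults: n = 150 individuals.

What this generator does *not* emulate: linkage disequilibrium between
SNPs, genotyping error, informative (non-MCAR) missingness, family
structure, time-varying genetic effects, and non-lognormal phenotype
tails. Passing tests therefore demonstrate correctness of the statistical
machinery under the stated models, not robustness to those real-data
complications.

## Problem sizes and numerical conventions

The Monte-Carlo experiments use n = 500 with 1000 replicates per scenario;
the EM-recovery experiment uses n = 2000 with 20% missingness; the
end-to-end study uses 150 individuals × 500 SNPs. Tolerances: Newton and EM
convergence 1e-8 (relative); LRT negative-clip 1e-8; PSD repair ridge
1e-8; separation bound 25 on coefficients and 1e-7 on fitted
probabilities. Ties in ranked reports break by chromosome then position;
the MAF-0.5 coding tie keeps the input allele.

## Known limitations

- Non-converged (separated) SNPs yield no p-value; with rare genotypes at
  small n this can remove real signals rather than report unstable ones.
- The χ²_k reference is asymptotic; at n below ~50 with k = 4 the test can
  be conservative or liberal — the calibration tests cover n ≥ 100.
- EM assumes multivariate normality on the log scale and MCAR/MAR
  missingness; MNAR dropout (e.g. sicker patients missing visits) will
  bias the imputed values.
- The FDR q-values assume independent-ish tests; under strong LD the BH
  procedure remains valid but conservative interpretations apply.
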