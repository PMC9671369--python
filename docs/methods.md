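# Methods

## Statistical model

The screen targets variants whose phenotypic effect depends on an
environmental exposure. Under the working structural model

    y_i = Σ_j β1_j c_j(g_ij) + Σ_j β3_j c_j(g_ij) E_i + β2 E_i
          + Σ_(a,b) β_ab g_ia g_ib + γ C_i + ε_i,

with dosage g ∈ {0,1,2}, coding map c (additive/dominant/recessive),
binary exposure E ~ Bernoulli(q) and covariates C, the conditional
variance of y given genotype g at an interacting locus is

    Var(y | g) = (β2 + β3 g)² q(1−q) + σ²,

so a non-zero interaction β3 induces variance heterogeneity across
genotype groups even when the exposure is unobserved. That identity is
the scientific basis of Step 2 and is verified directly by simulation in
the test suite (Monte Carlo vs. closed form, relative error < 2% at
n = 200,000).

Step 1 is covariate-adjusted per-variant OLS, computed by Frisch–Waugh
residualization: phenotype and all dosage columns are residualized on the
covariate block once, after which the per-variant slope, SE and p-value
from simple regression on residuals (with the full-model degrees of
freedom) equal the full-model quantities exactly; the suite asserts this
against per-variant full fits. Step 1 uses OLS rather than a mixed model:
simulated samples are unrelated by construction, and relatedness
correction is deliberately out of scope.

Step 2 applies the Brown–Forsythe variant of Levene's test (absolute
deviations from group *medians*), which keeps its nominal size under
heavy-tailed phenotypes where the mean-based variant does not. Because
the test cannot carry covariates, it is applied to covariate-only
regression residuals; when a SNP's dosage correlates with a covariate
(|r| > 0.1) the screen logs a warning, since residualization can then
bias the test.

## Phenotype models

**avMSE (diopters).** A three-component Gaussian mixture: an
emmetropic/hyperopic peak and moderate- and high-myopia components,

| component | weight | mean (D) | SD (D) |
|---|---|---|---|
| emmetropic | 0.658941 | +1.203997 | 1.10 |
| moderate myopia | 0.306384 | −2.50 | 1.80 |
| high-myopia tail | 0.034675 | −8.00 | 3.00 |

The component-2/3 locations and all SDs were fixed a priori as the three
clinical regimes; the remaining three parameters (emmetropic mean and two
weights) were then solved analytically so the population mean is
−0.25 D, the SD 2.67 D, and P(avMSE ≤ −0.50) = 0.340 exactly — the
Stage-I demographic calibration. The solved values are frozen as
defaults.

**AOSW (years).** Age of onset of spectacle wear is generated from a
latent refractive liability R (the same mixture) through a two-regime
monotone link reflecting the bimodal phenomenology of spectacle onset:
myopic liabilities (R ≤ τ) map to a school-age onset mode, the rest to a
presbyopic mode,

    μ(R) = 17.222 + 1.5 (R − τ)   if R ≤ τ,   τ = −1.231
    μ(R) = 38.259 + 2.0 (R − τ)   otherwise,

with regime noise SD 5 y (early) / 12 y (late), rounding to whole years
and clipping to [5, 70]. Non-wearers (no AOSW) are removed with
probability expit(1.2 (R − 1.82156)), i.e. preferentially from the
least-myopic tail, giving 25% missingness overall. Link parameters were
calibrated once by Monte Carlo so the observed (wearer) distribution has
mean 31.6 y, SD 17.0 y and myopic fraction P(5 < AOSW ≤ 25) = 0.38. A
single linear latent→AOSW link cannot reach that combination of moments
and tail mass; the two-regime link is the package's design choice.

**Exposure.** UniEdu is Bernoulli with logit(prevalence) plus the rGE
contribution Σ_j rge_logodds_j (g_j − 2 f_j); dosages are centered so the
marginal prevalence stays at its target (0.37 Stage I, 0.32 Stage II)
while the per-allele odds ratio is exp(rge_logodds) exactly. EduYears is
drawn on 13–26 whole years, centered near 21 for degree holders and 17
otherwise.

**Genotypes.** Hardy–Weinberg sampling on the minor allele; when the
declared effect allele is the major allele (e.g. frequency 0.904) the
reported dosage is flipped so it still counts the effect allele. LD
blocks use common-uniform allele copying against the block lead with
copy probability c (default 0.95): marginal allele frequencies are
preserved exactly, the lead–member allele correlation is c for equal
frequencies, and c = 1 yields r² = 1. Only pairwise r² matters for
clumping, so no recombination-map or coalescent realism is attempted.

### What the generator does **not** emulate

No relatedness or population structure (the PCs are pure noise), no
imputation uncertainty or genotyping error, no LD beyond within-block
pairwise correlation, no mean–variance coupling beyond what the mixture
itself induces, and no exposure measurement error. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not robustness to those real-data features; in
particular the screen's behavior for variants correlated with ancestry
is exercised only through the covariate-correlation warning.

## Numerical choices

* **Robust SEs**: HC1, `(X'X)⁻¹ X' diag(e²) X (X'X)⁻¹ · n/(n−k)` — the
  common small-sample-corrected sandwich.
* **Wald CIs** use the normal quantile 1.96 throughout (intended n are
  large); p-values use the normal reference for both families.
* **Logistic IRLS**: internally standardized columns, Newton steps with
  deviance step-halving, convergence at max |score| < 1e-8 (standardized
  scale) or a deviance plateau at double precision; 50-iteration cap.
  Separation raises an explicit error (diverging standardized
  coefficients or fully saturated fitted probabilities).
* **Levene groups**: dosages hard-called by rounding to {0,1,2}; groups
  under 10 samples dropped (both config-exposed — upstream tools leave
  this unstated). Zero denominator (all deviations equal) returns p = 1
  with a warning rather than NaN.
* **binomial_tail** sums the exact log-PMF via logsumexp, accurate to
  ~1e-20 tails; clamped at 1.
* **Clumping ties** break by (p, chrom, pos, id), making selection
  invariant to variant input order. Defaults p_entry 1e-4, r² 0.1,
  window 500 kb are package choices; the upstream settings are not
  published.
* **Spearman concordance**: midranks for ties; exact permutation p for
  n ≤ 9, t-approximation with n−2 df otherwise (at the intended n = 25
  the approximation is standard practice).
* **Complete cases** per model, with dropped counts logged.
* Dominance comparison resolves exact −2logLik ties to additive.
* All randomness flows from one root seed through named
  `numpy.random.SeedSequence` spawns (genotypes / exposure / covariates /
  phenotype, and per-replicate streams in the harness), so every output
  is bit-reproducible and the harness supports common random numbers
  across effect grids.

## Problem sizes

The package targets desk scale: ≤ ~5,000 variants × ~50,000 samples.
The shipped demo uses 2,000 samples × 500 variants with three planted
interaction variants (marginal −0.3 D, interaction −2.0 D per allele per
UniEdu unit ≈ 0.75 phenotype SD, exposure main effect −1.2 D). These
effects were sized by an a-priori power analysis so Levene's test has
near-complete power at n = 2,000 under the Bonferroni threshold — at
this cohort size, effects an order of magnitude smaller (as reported in
large biobanks) are undetectable by design of the statistics, not a
defect of the implementation. Calibration checks run at 10,000
replicates (type-I error), 5,000 replicates (CI coverage at n = 5,000),
and 100 seeded end-to-end screens.

## Known limitations

* Exposure × covariate product terms are not modeled (the interaction
  equations carry none); omitted-confounder-interaction bias is a known
  caveat of this family of GxE tests.
* Levene-on-residuals is biased for variants correlated with covariates;
  the screen warns but does not correct.
* The AOSW link is a stylized two-mode model; real onset-age reporting
  shows digit preference and recall error that are not simulated.
* The logistic Myopic analyses use the derived classification, so their
  power depends on the chosen thresholds (−0.50 D; 5 < AOSW ≤ 25 y).
* No mixed-model or dispersion-model (heteroskedastic LMM) machinery:
  mean–variance relationships intrinsic to non-normal traits can create
  vQTL signals at strong marginal-effect loci that are not GxE; the
  package screens for candidates, it does not adjudicate mechanism.
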