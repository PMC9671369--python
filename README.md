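# vqtlscreen

Two-step variance-heterogeneity (vQTL) screening and gene-by-environment
(GxE) interaction analysis for quantitative ocular phenotypes, with a
calibrated synthetic cohort simulator.

## The problem

Myopia develops predominantly during school age, and education is one of
its strongest environmental risk factors. Genetic variants whose effect on
refractive error *depends* on educational exposure (GxE interactions) are
hard to find by brute force: testing millions of SNP x exposure terms
costs enormous multiple-testing burden. A two-step screen avoids this.
A SNP involved in a GxE interaction is expected to show (1) a *marginal*
association with the phenotype, and (2) *variance heterogeneity* — the
phenotype variance differs between genotype groups — because mixing
exposed and unexposed individuals with different genetic effects inflates
the spread in the effect-carrying genotypes. Neither step needs exposure
data, so the screen can run on genotype + phenotype alone; only the small
prioritized set is then tested for explicit interactions.

This package implements that workflow for refractive error (`avMSE`,
diopters; myopic iff avMSE <= -0.50 D) and its surrogate, age of onset of
spectacle wear (`AOSW`, years; myopic iff 5 < AOSW <= 25), with
University education (`UniEdu`, binary) or age completing full-time
education (`EduYears`) as the exposure. Because the motivating cohort
data (UK Biobank) are access-restricted, the package also ships a
simulator that reproduces the statistical structure those analyses
assume, so every stage is testable end to end.

## The method

**Step 1 — marginal scan.** Per-variant OLS of the phenotype on
effect-allele dosage with covariates (sex, age, age², genotyping array,
10 ancestry PCs), followed by greedy LD clumping (smallest p first,
members join a lead within 500 kb at r² ≥ 0.1). Variants at *P* < 1e-4
proceed.

**Step 2 — variance heterogeneity.** Levene's median (Brown–Forsythe)
test on covariate-adjusted residuals r across hard-called genotype
groups: with z_ij = |r_ij − median_i|,

    W = [(N−k)/(k−1)] · Σ_i n_i (z̄_i − z̄)² / Σ_ij (z_ij − z̄_i)²,

referred to F(k−1, N−k). Leads are selected at the Bonferroni level
α/#leads (e.g. 0.05/956 = 5.23e-5).

**Interaction stage.** For selected variants:

* GxE: `y = β₀ + β₁·SNP + β₂·E + β₃·SNP×E + γC + ε` — OLS for binary
  UniEdu, HC1 robust SEs for continuous EduYears, IRLS logistic for the
  binary Myopic outcome;
* dominance comparison: the GxE model refitted with the SNP coded
  additive (0,1,2), dominant (0,1,1) or recessive (0,0,1); equal
  parameter counts, so the lowest −2 log-likelihood wins;
* GxG: `y = β₀ + β₁·SNP₁ + β₂·SNP₂ + β₃·SNP₁×SNP₂ + γC + ε` over all
  C(m,2) pairs with Bonferroni correction (0.05/300 for 25 variants);
* rGE: logistic `logit P(E=1) = ω₀ + ω₁·SNP + γC`, reported as the
  per-allele odds ratio exp(ω₁).

**Evaluation.** Replication counting with an exact binomial upper-tail
enrichment test, Spearman concordance of interaction effects across
stages, and a Monte Carlo harness measuring type-I error and power of the
Levene and GxE tests under the package's non-normal phenotype models.

All regression engines (OLS, HC1 sandwich, IRLS logistic), the Levene
median test and the log-space binomial tail are implemented here and
cross-checked against independent implementations in the test suite.
Estimators follow scikit-learn conventions (`LinearModel`,
`LogisticModel`, `TwoStepScreen` with `fit`/`transform` and `_`-suffixed
fitted attributes).

## Worked example

Simulate a Stage-I style cohort (2,000 samples, 500 variants of which 3
carry a planted SNP×UniEdu interaction of −2.0 D per allele) and screen:

```python
import vqtlscreen as v
from vqtlscreen.pipeline import covariate_frame, demo_variants

sim = v.CohortSimulator(demo_variants(), n=2000, stage="stage1",
                        exposure_effect=-1.2)
gm, coh = sim.simulate(42)
sc = v.two_step_screen(gm, coh["avMSE"], covariates=covariate_frame(coh),
                       exposure=coh["UniEdu"])
print(sc.results_.query("selected")[["id", "beta", "p_marginal", "levene_p"]])
```

```
   id      beta   p_marginal     levene_p
v0001 -0.950690 1.669872e-11 1.843733e-11
v0002 -0.927170 5.598502e-13 3.367483e-09
v0003 -0.994832 1.350806e-12 4.868115e-10
```

Six leads passed Step 1; at the Bonferroni Step-2 threshold (0.05/6 =
8.3e-3) exactly the three planted variants are selected: each shows a
myopia-directed marginal effect (negative beta, diopters per effect
allele) and strong variance heterogeneity. An explicit interaction test
on the first recovers the planted effect:

```python
r = v.gxe_test(gm.column("v0001"), coh["UniEdu"], coh["avMSE"],
               covariate_frame(coh))
# beta3 = -2.177 D, 95% CI (-2.617, -1.736), p = 3.6e-22
```

The bundled published summary table for the 25 refractive-error vQTLs
reproduces the replication analysis directly:

```python
tab = v.load_vqtl_summary()
ev = v.replication_enrichment(tab["id"], tab["id"],
                              tab["levene_p_stage2"], alpha=0.05)
# 19 of 25 replicate; enrichment p = 2.52e-20
```

A full simulate → screen → confirm → interact → evaluate run:

```bash
vqtlscreen pipeline --demo --seed 1 --outdir runs/demo
```

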