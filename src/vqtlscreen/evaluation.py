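"""Replication, concordance and calibration (type-I error / power) analyses.

Three independent checks on a two-stage vQTL analysis:

* :func:`replication_enrichment` — how many Stage-I-selected variants
  replicate at a nominal level in an independent Stage-II cohort, with an
  exact binomial upper-tail enrichment p-value;
* :func:`effect_concordance` — Spearman rank correlation of interaction
  effect sizes across the two stages (midranks for ties; exact
  permutation p for n <= 9, t-approximation otherwise);
* :func:`typeI_power_harness` — Monte Carlo characterization of the
  variance-heterogeneity and GxE tests under configurable phenotype
  models: empirical rejection rate +/- Monte Carlo SE per nominal alpha
  under the null, and empirical power over an interaction effect grid
  (common random numbers across the grid, so power is comparable between
  effect sizes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PhenotypeModel
from .models import binomial_tail, fit_linear, hard_call, levene_median_test

__all__ = [
    "EvalSummary",
    "replication_enrichment",
    "effect_concordance",
    "typeI_power_harness",
]


@dataclass
class EvalSummary:
    """Container for evaluation outputs; any subset may be populated."""

    n_tested: int | None = None
    n_replicated: int | None = None
    replication_alpha: float | None = None
    enrichment_p: float | None = None
    spearman_rho: float | None = None
    spearman_p: float | None = None
    typeI_table: pd.DataFrame | None = None
    power_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "n_tested": self.n_tested,
            "n_replicated": self.n_replicated,
            "replication_alpha": self.replication_alpha,
            "enrichment_p": self.enrichment_p,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
        }
        if self.typeI_table is not None:
            out["typeI_table"] = self.typeI_table.to_dict(orient="records")
        if self.power_table is not None:
            out["power_table"] = self.power_table.to_dict(orient="records")
        return {k: v for k, v in out.items() if v is not None}


def replication_enrichment(stage1_ids, stage2_ids, stage2_pvalues,
                           alpha: float = 0.05) -> EvalSummary:
    """Count Stage-II replications and test enrichment over chance.

    ``stage2_ids``/``stage2_pvalues`` must align with ``stage1_ids``
    one-to-one (same variants, same order). A variant replicates when its
    Stage-II p-value is below ``alpha``; under the null the replication
    count is Binomial(n, alpha), and the enrichment p-value is the exact
    upper tail P(X >= observed count).
    """
    s1 = list(stage1_ids)
    s2 = list(stage2_ids)
    p2 = np.asarray(stage2_pvalues, dtype=float)
    if s1 != s2 or len(s1) != p2.shape[0]:
        raise ValueError("stage-1 and stage-2 variant lists are misaligned")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n = len(s1)
    k = int(np.sum(p2 < alpha))
    return EvalSummary(
        n_tested=n, n_replicated=k, replication_alpha=alpha,
        enrichment_p=binomial_tail(k, n, alpha),
    )


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def effect_concordance(betas_stage1, betas_stage2,
                       exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation between two stages' effect sizes.

    Uses midranks for ties. The p-value is an exact two-sided permutation
    enumeration for n <= ``exact_max_n`` and the usual t-approximation
    with n - 2 degrees of freedom otherwise. Requires >= 3 pairs; a
    constant vector leaves the correlation undefined and is an error.
    """
    a = np.asarray(betas_stage1, dtype=float)
    b = np.asarray(betas_stage2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("effect vectors must be 1-D and of equal length")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant effect vector: correlation undefined")
    ra, rb = _midranks(a), _midranks(b)

    def _pearson(u, v):
        u = u - u.mean()
        v = v - v.mean()
        return float(u @ v / math.sqrt((u @ u) * (v @ v)))

    rho = _pearson(ra, rb)
    if n <= exact_max_n:
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = _pearson(ra, rb[list(perm)])
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
    return rho, float(2.0 * stats.t.sf(abs(t), n - 2))


def _gxe_pvalue(y, g, e):
    fit = fit_linear(np.column_stack([g, e, g * e]), y,
                     terms=["snp", "E", "snp_x_e"])
    return fit.pvalues_[2]


def typeI_power_harness(phenotype_models: dict[str, PhenotypeModel],
                        tests=("levene", "gxe_linear"),
                        alphas=(0.05, 0.01),
                        effect_grid=(0.0,),
                        reps: int = 1000, n: int = 2000, maf: float = 0.3,
                        prevalence: float = 0.35,
                        exposure_effect: float = 0.0,
                        nuisance_gxe: float = 0.0,
                        min_group_size: int = 10,
                        seed: int = 0) -> EvalSummary:
    """Monte Carlo type-I error and power for the screen's two tests.

    For each phenotype model and each interaction effect size ``b`` in
    ``effect_grid`` (phenotype units per allele per exposure unit; 0 is
    the null), ``reps`` cohorts of ``n`` samples are simulated with one
    HWE variant at the given ``maf`` and a Bernoulli exposure, the named
    tests are run, and rejection rates at each nominal alpha recorded
    with their Monte Carlo SE sqrt(r(1-r)/reps) and a calibration verdict
    (|rate - alpha| within 3 SE) for the null cells. ``nuisance_gxe``
    plants an interaction with an independent, unobserved second exposure
    in every cell, for checking calibration of the education-interaction
    test in the presence of GxE effects not involving education.
    Common random numbers are reused across the effect grid, making the
    power curves monotone-comparable; results are reproducible bit-for-bit
    given (seed, reps, grid).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    root = np.random.SeedSequence(seed)
    model_seeds = root.spawn(len(phenotype_models))
    for (mname, model), mseed in zip(phenotype_models.items(), model_seeds):
        pvals = {(t, b): np.empty(reps) for t in tests for b in effect_grid}
        rep_seeds = mseed.spawn(reps)
        for r in range(reps):
            rng = np.random.default_rng(rep_seeds[r])
            u = rng.random((n, 2))
            g = (u[:, 0] < maf).astype(float) + (u[:, 1] < maf).astype(float)
            e = (rng.random(n) < prevalence).astype(float)
            latent = model.sample_latent(n, rng)
            eps = rng.standard_normal(n)  # AOSW regime noise, shared over grid
            e2 = (rng.random(n) < 0.5).astype(float)  # unobserved exposure
            groups = hard_call(g)
            for b in effect_grid:
                shift = b * g * e + exposure_effect * e + nuisance_gxe * g * e2
                if model.family == "mixture_gaussian":
                    y = latent + shift
                else:
                    me, ml, tau, be, bl, sde, sdl = model.aosw_link
                    early = latent <= tau
                    mu = np.where(early, me + be * (latent - tau),
                                  ml + bl * (latent - tau))
                    sd = np.where(early, sde, sdl)
                    lo, hi = model.aosw_bounds
                    y = np.clip(np.rint(mu + sd * eps + shift), lo, hi)
                if "levene" in tests:
                    lev = levene_median_test(y, groups,
                                             min_group_size=min_group_size)
                    pvals[("levene", b)][r] = lev.p
                if "gxe_linear" in tests:
                    pvals[("gxe_linear", b)][r] = _gxe_pvalue(y, g, e)
        for t in tests:
            for b in effect_grid:
                p = pvals[(t, b)]
                for a in alphas:
                    rate = float(np.mean(p < a))
                    mcse = math.sqrt(max(rate * (1 - rate), 1e-12) / reps)
                    rows.append({
                        "phenotype_model": mname, "test": t, "effect": b,
                        "alpha": a, "rate": rate, "mc_se": mcse,
                        "reps": reps, "n": n,
                        "calibrated": (abs(rate - a) <= 3 * mcse
                                       if b == 0.0 else None),
                    })
    table = pd.DataFrame(rows)
    null_t = table[table["effect"] == 0.0].reset_index(drop=True)
    power_t = table[table["effect"] != 0.0].reset_index(drop=True)
    return EvalSummary(typeI_table=null_t,
                       power_table=power_t if len(power_t) else None)
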