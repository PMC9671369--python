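"""Synthetic genotype-exposure-phenotype cohorts for vQTL and GxE analysis.

This module generates cohorts with the statistical structure that a two-step
variance-heterogeneity screen and downstream gene-by-environment (GxE)
interaction tests assume: Hardy-Weinberg biallelic genotypes with optional
LD blocks, a binary education exposure (``UniEdu``) with configurable
prevalence and gene-environment correlation (rGE), and two refractive-error
phenotypes --

``avMSE``
    average mean spherical equivalent in diopters (negative = myopic),
    drawn from a three-component Gaussian mixture (emmetropic peak,
    moderate myopia, high-myopia tail) calibrated so that at the defaults
    the mean is -0.25 D, the SD 2.67 D and the myopic fraction
    (avMSE <= -0.50 D) 0.34;

``AOSW``
    self-reported age of onset of spectacle wear in whole years on [5, 70],
    produced by passing a latent refractive liability through a monotone
    decreasing two-regime link (school-age onset for myopic liabilities,
    presbyopic onset otherwise), with non-wearers (no AOSW) removed
    preferentially from the least-myopic tail.

Variant effects can be marginal, interactive (GxE with the exposure, GxG
between pairs), dominance-coded, or exposure-correlated (rGE).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "VariantSpec",
    "PhenotypeModel",
    "GenotypeMatrix",
    "CohortSimulator",
    "avmse_model",
    "aosw_model",
    "simulate_genotypes",
    "simulate_exposure",
    "simulate_phenotype",
    "simulate_covariates",
    "classify_myopic",
    "CODINGS",
]

# dosage -> predictor maps for the three genetic models
CODINGS = {
    "additive": np.array([0.0, 1.0, 2.0]),
    "dominant": np.array([0.0, 1.0, 1.0]),
    "recessive": np.array([0.0, 0.0, 1.0]),
}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class VariantSpec:
    """Specification of one biallelic variant to simulate.

    Parameters
    ----------
    id, chrom, pos
        Identifier, chromosome label and 1-based position.
    ea, nea
        Effect and non-effect allele strings. Dosage counts copies of the
        effect allele, which need not be the minor allele.
    maf
        Minor allele frequency in (0, 0.5]. Give either ``maf`` (the effect
        allele is then the minor allele) or ``ea_freq``.
    ea_freq
        Effect-allele frequency in (0, 1); if above 0.5 the effect allele
        is the major allele and HWE sampling is done on the minor allele.
    beta_marginal
        Phenotype shift per (coded) effect-allele unit.
    beta_gxe
        Interaction effect: phenotype shift per coded unit per exposure unit.
    coding
        ``additive`` (0,1,2), ``dominant`` (0,1,1) or ``recessive`` (0,0,1);
        applied to both marginal and GxE effect terms.
    rge_logodds
        Log-odds of the binary exposure per effect-allele copy
        (gene-environment correlation).
    ld_block
        Variants sharing a block label are generated with correlated
        haplotypes (see :func:`simulate_genotypes`); ``None`` = independent.
    """

    id: str
    chrom: str = "1"
    pos: int = 1
    ea: str = "A"
    nea: str = "G"
    maf: float | None = None
    ea_freq: float | None = None
    beta_marginal: float = 0.0
    beta_gxe: float = 0.0
    coding: str = "additive"
    rge_logodds: float = 0.0
    ld_block: int | None = None

    def __post_init__(self):
        if self.coding not in CODINGS:
            raise ValueError(f"unknown coding {self.coding!r} for {self.id}")
        if self.ea_freq is None and self.maf is None:
            raise ValueError(f"variant {self.id}: give maf or ea_freq")
        if self.ea_freq is None:
            object.__setattr__(self, "ea_freq", float(self.maf))
        f = float(self.ea_freq)
        if not 0.0 < f < 1.0:
            raise ValueError(f"variant {self.id}: ea_freq {f} outside (0, 1)")
        maf = min(f, 1.0 - f)
        if self.maf is not None and not 0.0 < self.maf <= 0.5:
            raise ValueError(f"variant {self.id}: maf {self.maf} outside (0, 0.5]")
        object.__setattr__(self, "maf", maf)
        if int(self.pos) < 1:
            raise ValueError(f"variant {self.id}: pos must be 1-based (>= 1)")

    @property
    def ea_is_minor(self) -> bool:
        return self.ea_freq <= 0.5

    def coding_map(self) -> np.ndarray:
        return CODINGS[self.coding]


@dataclass(frozen=True)
class PhenotypeModel:
    """Distributional model for the phenotype's baseline (null) component.

    ``mixture_gaussian`` draws the phenotype noise directly from the
    Gaussian mixture with the given ``components`` (weight, mean, sd).
    ``latent_to_aosw`` first draws a latent refractive liability from the
    mixture, then maps it to an age of onset of spectacle wear through a
    two-regime monotone link and discretizes to whole years on
    ``aosw_bounds``; a fraction of samples (non-wearers, drawn from the
    least-myopic latent tail) is set missing.
    """

    family: str = "mixture_gaussian"
    components: tuple[tuple[float, float, float], ...] = (
        (0.658941, 1.203997, 1.10),
        (0.306384, -2.5, 1.8),
        (0.034675, -8.0, 3.0),
    )
    noise_sd: float = 0.0          # extra N(0, sd) noise on top of the mixture
    aosw_bounds: tuple[int, int] = (5, 70)
    # two-regime link: early (school-age) onset for latent <= tau, else late
    aosw_link: tuple[float, float, float, float, float, float, float] = (
        17.222,   # early-regime mean at latent == tau
        38.259,   # late-regime mean at latent == tau
        -1.231,   # tau: latent liability split point (diopters)
        1.5,      # early-regime slope (years per diopter of latent)
        2.0,      # late-regime slope
        5.0,      # early-regime onset SD (years)
        12.0,     # late-regime onset SD (years)
    )
    # non-wearer missingness: P(missing) = expit(steepness * (latent - r0))
    missing_rate: float = 0.25
    missing_steepness: float = 1.2
    missing_r0: float = 1.82156
    missing_rule: str = "logistic in latent liability; least-myopic tail excluded"

    def __post_init__(self):
        if self.family not in ("mixture_gaussian", "latent_to_aosw"):
            raise ValueError(f"unknown phenotype family {self.family!r}")
        w = np.array([c[0] for c in self.components], dtype=float)
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"mixture weights sum to {w.sum()!r}, not 1")
        if any(c[2] <= 0 for c in self.components):
            raise ValueError("mixture component sds must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.aosw_bounds
        if not lo < hi:
            raise ValueError("aosw_bounds min must be < max")

    # -- sampling ---------------------------------------------------------

    def sample_latent(self, n: int, rng) -> np.ndarray:
        """Draw n values from the Gaussian mixture (the latent liability)."""
        rng = _as_rng(rng)
        w = np.array([c[0] for c in self.components])
        mu = np.array([c[1] for c in self.components])
        sd = np.array([c[2] for c in self.components])
        comp = rng.choice(len(w), size=n, p=w / w.sum())
        x = rng.normal(mu[comp], sd[comp])
        if self.noise_sd > 0:
            x = x + rng.normal(0.0, self.noise_sd, size=n)
        return x

    def sample(self, n: int, rng) -> np.ndarray:
        """Draw n baseline phenotype values (avMSE path; no AOSW mapping)."""
        return self.sample_latent(n, _as_rng(rng))

    def aosw_from_latent(self, latent: np.ndarray, rng,
                         shift: np.ndarray | float = 0.0) -> np.ndarray:
        """Map latent liability to AOSW years; ``shift`` adds effect terms."""
        rng = _as_rng(rng)
        me, ml, tau, be, bl, se, sl = self.aosw_link
        early = latent <= tau
        mu = np.where(early, me + be * (latent - tau), ml + bl * (latent - tau))
        sd = np.where(early, se, sl)
        raw = mu + sd * rng.standard_normal(latent.size) + shift
        lo, hi = self.aosw_bounds
        return np.clip(np.rint(raw), lo, hi)

    def nonwearer_mask(self, latent: np.ndarray, rng) -> np.ndarray:
        rng = _as_rng(rng)
        p = expit(self.missing_steepness * (latent - self.missing_r0))
        return rng.random(latent.size) < p


def avmse_model() -> PhenotypeModel:
    """Default refractive-error model (mean -0.25 D, SD 2.67, 34% myopic)."""
    return PhenotypeModel(family="mixture_gaussian")


def aosw_model() -> PhenotypeModel:
    """Default age-of-onset model (wearers: mean ~31.6 y, SD ~17, 38% myopic)."""
    return PhenotypeModel(family="latent_to_aosw")


@dataclass
class GenotypeMatrix:
    """N x M effect-allele dosage matrix with per-variant metadata.

    ``dosage`` holds values in {0, 1, 2} (float array; missing as NaN when
    read from files). ``variants`` is a DataFrame with at least columns
    (id, chrom, pos, ea, nea); rows align with dosage columns.
    """

    dosage: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def ea_frequencies(self) -> np.ndarray:
        return np.nanmean(self.dosage, axis=0) / 2.0

    def column(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) != 1:
            raise KeyError(f"variant {variant_id!r} not found (or duplicated)")
        return self.dosage[:, self.variants.index.get_loc(idx[0])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.samples,
                            columns=list(self.variants["id"]))


def simulate_genotypes(specs: Sequence[VariantSpec], n: int, seed,
                       ld_copy_prob: float = 0.95) -> GenotypeMatrix:
    """Draw HWE genotypes, with optional LD blocks via allele copying.

    Each variant's minor allele is sampled per Hardy-Weinberg proportions
    ((1-p)^2, 2p(1-p), p^2). Variants that share an ``ld_block`` are coupled
    through common uniform draws: each of the two allele slots of a
    non-lead block member reuses the block lead's uniform with probability
    ``ld_copy_prob`` (else a fresh uniform), which preserves every
    variant's marginal allele frequency exactly and gives, for equal
    frequencies, allele correlation ``ld_copy_prob`` with the lead (hence
    pairwise dosage r^2 of ``ld_copy_prob**2`` between the lead and a
    member, and r^2 = 1 at copy probability 1). Blocks are independent of
    one another. Reported dosage counts the *effect* allele, flipping
    orientation when the effect allele is the major allele.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    specs = list(specs)
    if not specs:
        raise ValueError("specs must be non-empty")
    rng = _as_rng(seed)
    n = int(n)
    m = len(specs)
    dosage = np.empty((n, m), dtype=float)
    if not 0.0 <= ld_copy_prob <= 1.0:
        raise ValueError("ld_copy_prob must be in [0, 1]")

    # lead uniforms per block, per allele slot
    block_lead_u: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for j, spec in enumerate(specs):
        p = spec.maf
        u1 = rng.random(n)
        u2 = rng.random(n)
        if spec.ld_block is not None:
            if spec.ld_block not in block_lead_u:
                block_lead_u[spec.ld_block] = (u1, u2)
            else:
                lu1, lu2 = block_lead_u[spec.ld_block]
                take1 = rng.random(n) < ld_copy_prob
                take2 = rng.random(n) < ld_copy_prob
                u1 = np.where(take1, lu1, u1)
                u2 = np.where(take2, lu2, u2)
        g_minor = (u1 < p).astype(float) + (u2 < p).astype(float)
        dosage[:, j] = g_minor if spec.ea_is_minor else 2.0 - g_minor

    variants = pd.DataFrame(
        {
            "id": [s.id for s in specs],
            "chrom": [str(s.chrom) for s in specs],
            "pos": [int(s.pos) for s in specs],
            "ea": [s.ea for s in specs],
            "nea": [s.nea for s in specs],
            "ea_freq": [s.ea_freq for s in specs],
            "ld_block": [s.ld_block for s in specs],
        }
    )
    samples = [f"S{i + 1:06d}" for i in range(n)]
    return GenotypeMatrix(dosage, variants, samples)


def simulate_exposure(genotypes: GenotypeMatrix, specs: Sequence[VariantSpec],
                      prevalence: float, seed) -> pd.DataFrame:
    """Simulate the binary UniEdu exposure and the EduYears variable.

    UniEdu is Bernoulli with logit equal to ``logit(prevalence)`` plus the
    rGE contribution ``sum_j rge_logodds_j * (g_j - 2 f_j)`` (dosages are
    centered so the marginal prevalence stays at the target; the per-allele
    odds ratio exp(rge_logodds) is unaffected). EduYears (age completing
    full-time education) is drawn on 13..26 whole years, shifted upward for
    UniEdu = 1 (degree holders finish around 21, others around 17).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    rng = _as_rng(seed)
    n = genotypes.n_samples
    eta = np.full(n, logit(prevalence))
    for j, spec in enumerate(specs):
        if spec.rge_logodds != 0.0:
            g = genotypes.dosage[:, j]
            eta = eta + spec.rge_logodds * (g - 2.0 * spec.ea_freq)
    uniedu = (rng.random(n) < expit(eta)).astype(int)
    edu = np.where(
        uniedu == 1,
        np.clip(np.rint(rng.normal(21.0, 1.8, n)), 17, 26),
        np.clip(np.rint(rng.normal(16.7, 1.5, n)), 13, 19),
    )
    return pd.DataFrame({"UniEdu": uniedu, "EduYears": edu.astype(int)},
                        index=genotypes.samples)


def simulate_covariates(n: int, seed, n_pcs: int = 10) -> pd.DataFrame:
    """Age / sex / genotyping-array / ancestry-PC covariates (null effects)."""
    rng = _as_rng(seed)
    age = np.clip(np.rint(rng.normal(58.0, 7.5, n)), 40, 73).astype(int)
    cov = {
        "age": age,
        "sex": (rng.random(n) < 0.54).astype(int),
        "array": (rng.random(n) < 0.10).astype(int),
    }
    for k in range(1, n_pcs + 1):
        cov[f"pc{k}"] = rng.standard_normal(n)
    return pd.DataFrame(cov)


def simulate_phenotype(genotypes: GenotypeMatrix, exposures, covariates,
                       specs: Sequence[VariantSpec], model: PhenotypeModel,
                       seed, gxg_pairs: Sequence[tuple[str, str, float]] = (),
                       exposure_effect: float = 0.0,
                       covariate_effects: dict[str, float] | None = None,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the phenotype under the interaction structural model.

    The systematic part is
    ``sum_j beta_marginal_j c_j(g_j) + sum_j beta_gxe_j c_j(g_j) E
    + exposure_effect * E + sum_pairs beta_ab g_a g_b + C gamma``
    with c_j the variant's dominance-coding map and E the UniEdu column of
    ``exposures`` (or ``exposures`` itself if array-like). Baseline noise
    comes from the model's mixture (avMSE) or the latent-to-AOSW link, in
    which case the systematic part is added in years, the output is rounded
    to whole years, clipped to the model bounds, and non-wearers are
    returned as NaN.

    Returns
    -------
    phenotype : ndarray
        avMSE in diopters, or AOSW in years with NaN for non-wearers.
    latent : ndarray
        The latent refractive liability actually drawn (equals the
        phenotype noise for the mixture family).
    """
    rng = _as_rng(seed)
    n = genotypes.n_samples
    if isinstance(exposures, pd.DataFrame):
        e = np.asarray(exposures["UniEdu"], dtype=float)
    elif exposures is None:
        e = np.zeros(n)
    else:
        e = np.asarray(exposures, dtype=float)
    if e.shape[0] != n:
        raise ValueError("exposure length does not match genotypes")

    systematic = np.zeros(n)
    for j, spec in enumerate(specs):
        if spec.beta_marginal == 0.0 and spec.beta_gxe == 0.0:
            continue
        g = genotypes.dosage[:, j]
        coded = spec.coding_map()[g.astype(int)]
        systematic += spec.beta_marginal * coded + spec.beta_gxe * coded * e
    if exposure_effect:
        systematic = systematic + exposure_effect * e
    by_id = {s.id: j for j, s in enumerate(specs)}
    for a, b, beta in gxg_pairs:
        if a == b:
            raise ValueError(f"GxG pair must use distinct variants, got {a!r}")
        systematic += beta * genotypes.dosage[:, by_id[a]] * genotypes.dosage[:, by_id[b]]
    if covariate_effects:
        if covariates is None:
            raise ValueError("covariate_effects given without covariates")
        for name, gamma in covariate_effects.items():
            systematic = systematic + gamma * np.asarray(covariates[name], float)

    latent = model.sample_latent(n, rng)
    if model.family == "mixture_gaussian":
        return systematic + latent, latent
    # latent_to_aosw: effects act on the year scale on top of the link
    aosw = model.aosw_from_latent(latent, rng, shift=systematic)
    miss = model.nonwearer_mask(latent, rng)
    aosw = aosw.astype(float)
    aosw[miss] = np.nan
    return aosw, latent


def classify_myopic(avmse: np.ndarray | None = None,
                    aosw: np.ndarray | None = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Classify samples as myopic from avMSE or AOSW.

    The avMSE rule is myopic iff avMSE <= -0.50 D (boundary included); the
    AOSW rule is myopic iff 5 < AOSW <= 25 years. Each sample must have
    exactly one phenotype available (NaN = missing); a sample with neither
    is flagged excluded rather than silently dropped, as are non-wearers
    (missing AOSW) on the AOSW path.

    Returns
    -------
    myopic : float ndarray with values {0.0, 1.0, NaN (excluded)}
    excluded : bool ndarray
    """
    if avmse is None and aosw is None:
        raise ValueError("supply avmse and/or aosw")
    av = None if avmse is None else np.asarray(avmse, dtype=float)
    ao = None if aosw is None else np.asarray(aosw, dtype=float)
    n = av.shape[0] if av is not None else ao.shape[0]
    if av is not None and ao is not None and av.shape[0] != ao.shape[0]:
        raise ValueError("avmse and aosw lengths differ")
    if av is not None and ao is not None:
        both = ~np.isnan(av) & ~np.isnan(ao)
        if both.any():
            raise ValueError("exactly one phenotype must be supplied per sample")
    myopic = np.full(n, np.nan)
    if av is not None:
        has = ~np.isnan(av)
        myopic[has] = (av[has] <= -0.50).astype(float)
    if ao is not None:
        has = ~np.isnan(ao)
        myopic[has] = ((ao[has] > 5) & (ao[has] <= 25)).astype(float)
    excluded = np.isnan(myopic)
    return myopic, excluded


@dataclass
class CohortSimulator:
    """One-call simulator for a full Stage-I- or Stage-II-style cohort.

    Stage I carries the measured refractive error (avMSE, diopters);
    Stage II carries the age of onset of spectacle wear (AOSW, years) with
    non-wearers excluded. Both carry UniEdu/EduYears, age, sex, array and
    10 ancestry PCs. All randomness derives from a single root seed via
    named child streams (genotypes, exposure, covariates, phenotype) so
    runs are reproducible stream-by-stream.
    """

    specs: Sequence[VariantSpec]
    n: int = 2000
    stage: str = "stage1"
    prevalence: float = 0.37          # Stage-I UniEdu prevalence; Stage II 0.32
    phenotype_model: PhenotypeModel | None = None
    gxg_pairs: Sequence[tuple[str, str, float]] = ()
    exposure_effect: float = 0.0
    covariate_effects: dict[str, float] | None = None
    ld_copy_prob: float = 0.95

    def __post_init__(self):
        if self.stage not in ("stage1", "stage2"):
            raise ValueError("stage must be 'stage1' or 'stage2'")
        if self.phenotype_model is None:
            self.phenotype_model = (avmse_model() if self.stage == "stage1"
                                    else aosw_model())

    def simulate(self, seed) -> tuple[GenotypeMatrix, pd.DataFrame]:
        """Return (genotypes, cohort table) for a fresh cohort."""
        ss = np.random.SeedSequence(seed)
        r_geno, r_expo, r_cov, r_phen = (np.random.default_rng(s)
                                         for s in ss.spawn(4))
        gm = simulate_genotypes(self.specs, self.n, r_geno,
                                ld_copy_prob=self.ld_copy_prob)
        expo = simulate_exposure(gm, self.specs, self.prevalence, r_expo)
        cov = simulate_covariates(self.n, r_cov)
        cov.index = gm.samples
        y, _latent = simulate_phenotype(
            gm, expo, cov, self.specs, self.phenotype_model, r_phen,
            gxg_pairs=self.gxg_pairs, exposure_effect=self.exposure_effect,
            covariate_effects=self.covariate_effects,
        )
        tab = pd.concat([expo, cov], axis=1)
        tab.insert(0, "sample_id", gm.samples)
        if self.stage == "stage1":
            tab.insert(1, "avMSE", y)
            myopic, _ = classify_myopic(avmse=y)
        else:
            tab.insert(1, "AOSW", y)
            myopic, _ = classify_myopic(aosw=y)
        tab.insert(2, "Myopic", myopic)
        tab = tab.reset_index(drop=True)
        return gm, tab
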