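"""Interaction hypothesis tests on screened variants.

Covers the Stage-II style analyses downstream of the vQTL screen:
gene-by-environment (GxE) tests with a binary or continuous exposure and a
linear, robust-SE linear, or logistic outcome model; the dominance-coded
model comparison (additive / dominant / recessive, ranked by -2 log
likelihood); gene-by-gene (GxG) product-term tests over all variant pairs;
and the gene-environment correlation (rGE) test regressing the binary
exposure on dosage.

All tests include the main effects alongside their interaction term
(hierarchical principle) and mirror the screening covariate set. Exposure
x covariate terms are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .cohort import CODINGS
from .models import (LinearModel, LogisticModel, bonferroni_alpha,
                     fit_linear, fit_logistic, hard_call)

__all__ = [
    "InteractionResult",
    "gxe_test",
    "dominance_model_comparison",
    "gxg_test",
    "gxg_all_pairs",
    "rge_test",
    "ea_freq_by_stratum",
]

_FAMILIES = ("linear", "linear_robust", "logistic")


@dataclass
class InteractionResult:
    """Result of a single interaction (or rGE association) test."""

    variant: str
    exposure: str
    outcome: str
    coding: str
    family: str
    term: str
    beta: float
    se: float
    ci95: tuple[float, float]
    p: float
    minus2loglik: float
    n_used: int
    model: object = None

    @property
    def odds_ratio(self) -> float:
        if self.family != "logistic":
            raise AttributeError("odds ratio defined for logistic fits only")
        return float(np.exp(self.beta))

    @property
    def or_ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.ci95[0])), float(np.exp(self.ci95[1])))

    def to_row(self) -> dict:
        return {
            "variant": self.variant, "exposure": self.exposure,
            "outcome": self.outcome, "coding": self.coding,
            "family": self.family, "beta": self.beta, "se": self.se,
            "ci_lo": self.ci95[0], "ci_hi": self.ci95[1], "p": self.p,
            "minus2loglik": self.minus2loglik, "n_used": self.n_used,
        }


def _coded(genotype, coding, variant_id):
    g = hard_call(np.asarray(genotype, dtype=float))
    coded = np.where(np.isfinite(g), CODINGS[coding][
        np.nan_to_num(g).astype(int)], np.nan)
    fin = coded[np.isfinite(coded)]
    if fin.size == 0 or np.all(fin == fin[0]):
        raise ValueError(
            f"degenerate {coding} coding for {variant_id}: predictor is "
            "constant (e.g. no minor-allele homozygotes)"
        )
    return coded


def _cov_block(covariates, n):
    if covariates is None:
        return np.empty((n, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), list(covariates.columns)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return C, [f"c{j}" for j in range(C.shape[1])]


def _fit(design, names, y, family):
    if family == "logistic":
        return fit_logistic(design, y, terms=names)
    return fit_linear(design, y, robust=(family == "linear_robust"),
                      terms=names)


def gxe_test(genotype, exposure, outcome, covariates=None,
             coding: str = "additive", family: str = "linear",
             variant_id: str = "snp", exposure_name: str = "E",
             outcome_name: str = "y") -> InteractionResult:
    """Genotype-by-exposure interaction test.

    Fits ``outcome ~ coded(g) + E + coded(g):E + covariates`` and reports
    the product term. ``coding`` maps hard-called dosage through additive
    (0,1,2), dominant (0,1,1) or recessive (0,0,1); under the additive
    model the exposure-associated shift is beta3 per effect-allele copy
    (2*beta3 for homozygotes). ``family`` selects OLS, OLS with HC1 robust
    SEs (continuous exposures such as years of education), or IRLS
    logistic regression (binary outcomes such as myopia status).
    """
    if family not in _FAMILIES:
        raise ValueError(f"family must be one of {_FAMILIES}")
    coded = _coded(genotype, coding, variant_id)
    e = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    C, cnames = _cov_block(covariates, y.shape[0])
    names = ["snp", exposure_name, "snp_x_e"] + cnames
    design = np.column_stack([coded, e, coded * e, C])
    fitted = _fit(design, names, y, family)
    i = fitted.terms_.index("snp_x_e")
    return InteractionResult(
        variant=variant_id, exposure=exposure_name, outcome=outcome_name,
        coding=coding, family=fitted.family_, term="snp_x_e",
        beta=float(fitted.coef_[i]), se=float(fitted.se_[i]),
        ci95=(float(fitted.ci95_[i, 0]), float(fitted.ci95_[i, 1])),
        p=float(fitted.pvalues_[i]), minus2loglik=float(fitted.minus2loglik_),
        n_used=fitted.n_used_, model=fitted,
    )


def dominance_model_comparison(genotype, exposure, outcome, covariates=None,
                               family: str = "linear",
                               variant_id: str = "snp",
                               exposure_name: str = "E",
                               outcome_name: str = "y",
                               ) -> tuple[dict[str, InteractionResult], str]:
    """Fit the GxE model under all three codings; pick the best fit.

    The three codings have equal parameter counts, so the most
    parsimonious model is simply the one with the lowest -2 log
    likelihood; exact ties resolve to additive.
    """
    results = {
        c: gxe_test(genotype, exposure, outcome, covariates, coding=c,
                    family=family, variant_id=variant_id,
                    exposure_name=exposure_name, outcome_name=outcome_name)
        for c in ("additive", "dominant", "recessive")
    }
    best = min(results, key=lambda c: (results[c].minus2loglik,
                                       c != "additive"))
    return results, best


def gxg_test(genotype_a, genotype_b, outcome, covariates=None,
             family: str = "linear", id_a: str = "snp_a",
             id_b: str = "snp_b", outcome_name: str = "y",
             ) -> InteractionResult:
    """Genotype-by-genotype (epistasis) product-term test."""
    if id_a == id_b:
        raise ValueError("GxG test requires two distinct variants")
    ga = np.asarray(genotype_a, dtype=float)
    gb = np.asarray(genotype_b, dtype=float)
    y = np.asarray(outcome, dtype=float)
    C, cnames = _cov_block(covariates, y.shape[0])
    names = [id_a, id_b, "snp_x_snp"] + cnames
    design = np.column_stack([ga, gb, ga * gb, C])
    fitted = _fit(design, names, y, family)
    i = fitted.terms_.index("snp_x_snp")
    return InteractionResult(
        variant=f"{id_a}x{id_b}", exposure=id_b, outcome=outcome_name,
        coding="additive", family=fitted.family_, term="snp_x_snp",
        beta=float(fitted.coef_[i]), se=float(fitted.se_[i]),
        ci95=(float(fitted.ci95_[i, 0]), float(fitted.ci95_[i, 1])),
        p=float(fitted.pvalues_[i]), minus2loglik=float(fitted.minus2loglik_),
        n_used=fitted.n_used_, model=fitted,
    )


def gxg_all_pairs(dosage_frame: pd.DataFrame, outcome, covariates=None,
                  family: str = "linear", alpha: float = 0.05,
                  outcome_name: str = "y") -> pd.DataFrame:
    """Test every pair of variant columns for a GxG interaction.

    Enumerates all C(m, 2) pairs (300 pairs for 25 variants) and applies a
    Bonferroni correction with the actual pair count; the returned frame
    carries the per-pair product-term estimate, p, and a ``significant``
    flag at the corrected level.
    """
    ids = list(dosage_frame.columns)
    rows = []
    for a, b in combinations(ids, 2):
        r = gxg_test(dosage_frame[a], dosage_frame[b], outcome,
                     covariates=covariates, family=family, id_a=a, id_b=b,
                     outcome_name=outcome_name)
        rows.append({"snp_a": a, "snp_b": b, "beta": r.beta, "se": r.se,
                     "ci_lo": r.ci95[0], "ci_hi": r.ci95[1], "p": r.p,
                     "n_used": r.n_used})
    out = pd.DataFrame(rows)
    thr = bonferroni_alpha(alpha, len(out)) if len(out) else np.nan
    out["alpha_corrected"] = thr
    out["significant"] = out["p"] < thr
    return out


def rge_test(genotype, exposure_binary, covariates=None,
             variant_id: str = "snp", exposure_name: str = "UniEdu",
             ) -> InteractionResult:
    """Gene-environment correlation: logistic fit of exposure on dosage.

    Reports the per-effect-allele log-odds of the exposure; the odds
    ratio and its CI are available via ``odds_ratio`` / ``or_ci95``.
    """
    g = np.asarray(genotype, dtype=float)
    e = np.asarray(exposure_binary, dtype=float)
    uniq = np.unique(e[np.isfinite(e)])
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError("rGE exposure must be binary 0/1")
    C, cnames = _cov_block(covariates, e.shape[0])
    names = ["snp"] + cnames
    fitted = fit_logistic(np.column_stack([g, C]), e, terms=names)
    i = fitted.terms_.index("snp")
    return InteractionResult(
        variant=variant_id, exposure=exposure_name, outcome=exposure_name,
        coding="additive", family="logistic", term="snp",
        beta=float(fitted.coef_[i]), se=float(fitted.se_[i]),
        ci95=(float(fitted.ci95_[i, 0]), float(fitted.ci95_[i, 1])),
        p=float(fitted.pvalues_[i]), minus2loglik=float(fitted.minus2loglik_),
        n_used=fitted.n_used_, model=fitted,
    )


def ea_freq_by_stratum(genotype, exposure_binary) -> dict[str, float]:
    """Effect-allele frequency within each exposure stratum (rGE summary)."""
    g = np.asarray(genotype, dtype=float)
    e = np.asarray(exposure_binary, dtype=float)
    ok = np.isfinite(g) & np.isfinite(e)
    return {
        "freq_ea_exposed": float(np.mean(g[ok & (e == 1)]) / 2.0),
        "freq_ea_unexposed": float(np.mean(g[ok & (e == 0)]) / 2.0),
    }
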