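"""Two-step variance-heterogeneity (vQTL) screen.

Step 1 is a marginal (standard GWAS-style) scan of each variant against the
phenotype with covariate adjustment, followed by greedy LD clumping of the
variants passing a lenient p-value threshold. Step 2 applies Levene's
median test to the covariate-adjusted phenotype residuals within the
hard-called genotype groups of each clump lead, selecting leads at the
Bonferroni-corrected family-wise level over the number of leads tested.

The screen is exposed as the scikit-learn style estimator
:class:`TwoStepScreen` (``fit`` + ``transform`` selecting the screened
variant columns); :func:`marginal_scan`, :func:`clump` and
:func:`two_step_screen` are functional wrappers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .cohort import GenotypeMatrix
from .models import (Z95, bonferroni_alpha, hard_call, levene_median_test)

__all__ = ["TwoStepScreen", "marginal_scan", "clump", "two_step_screen"]


def _scan_core(variants: pd.DataFrame, G: np.ndarray, y: np.ndarray,
               C: np.ndarray, maf_min: float):
    """Covariate-adjusted per-variant OLS via Frisch-Waugh residualization.

    Residualizes the phenotype and every dosage column on the covariate
    matrix once; the per-variant slope, SE and p from simple regression on
    the residuals (with the full-model degrees of freedom) equal the
    full-model OLS quantities exactly.
    """
    kcov = C.shape[1]
    n_used = y.shape[0]
    Ct_C = C.T @ C
    y_res = y - C @ np.linalg.solve(Ct_C, C.T @ y)
    G_res = G - C @ np.linalg.solve(Ct_C, C.T @ G)
    gg = np.einsum("ij,ij->j", G_res, G_res)
    gy = G_res.T @ y_res
    yy = float(y_res @ y_res)

    res = variants.copy().reset_index(drop=True)
    freq = np.nanmean(G, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    mono = gg <= 1e-12
    maf_fail = maf < maf_min
    testable = ~(mono | maf_fail)
    skipped = [f"skipped monomorphic variant {vid}"
               for vid in res.loc[mono, "id"]]
    if maf_fail.any():
        skipped.append(
            f"excluded {int(maf_fail.sum())} variant(s) with MAF < {maf_min}"
        )

    beta = np.full(len(res), np.nan)
    se = np.full(len(res), np.nan)
    dof = n_used - kcov - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        b = gy / gg
        rss = yy - b**2 * gg
        s = np.sqrt(np.maximum(rss, 0.0) / dof / gg)
    beta[testable] = b[testable]
    se[testable] = s[testable]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pmarg = 2.0 * stats.norm.sf(np.abs(z))

    res["freq_ea"] = freq
    res["n_used"] = n_used
    res["beta"] = beta
    res["se"] = se
    res["p_marginal"] = pmarg
    res["flipped"] = False
    return res, y_res, skipped


def _covariate_matrix(n, covariates, exposure=None):
    cols = [np.ones(n)]
    if covariates is not None:
        C = (covariates.to_numpy(dtype=float)
             if isinstance(covariates, pd.DataFrame)
             else np.asarray(covariates, dtype=float))
        if C.ndim == 1:
            C = C[:, None]
        cols.append(C)
    if exposure is not None:
        cols.append(np.asarray(exposure, dtype=float)[:, None])
    return np.column_stack(cols)


class TwoStepScreen(BaseEstimator):
    """Marginal scan + LD clumping + Levene's median test selection.

    Parameters
    ----------
    p_entry : float
        Step-1 inclusion threshold on the marginal p-value (default 1e-4).
    r2_threshold, window_bp : float, int
        Clumping: variants within ``window_bp`` of a lead on the same
        chromosome with dosage r^2 >= ``r2_threshold`` join its clump.
    alpha : float
        Family-wise level for Step 2; the per-lead threshold is
        ``alpha / n_leads`` (Bonferroni).
    maf_min : float
        Variants with minor allele frequency below this are excluded.
    min_group_size : int
        Genotype groups smaller than this are dropped in Levene's test.
    adjust_for_exposure : bool
        Include the exposure as a covariate in Step 1 and in the
        residualization used for Step 2 (sensitivity-analysis toggle).
    orient_risk_allele : bool
        Report the effect allele as the risk (phenotype-lowering, i.e.
        myopia-predisposing) allele, flipping orientation when needed.

    Fitted attributes: ``results_`` (per-variant DataFrame), ``support_``
    (boolean mask over input variants), ``n_leads_``,
    ``step2_threshold_``, ``log_``.
    """

    def __init__(self, p_entry: float = 1e-4, r2_threshold: float = 0.1,
                 window_bp: int = 500_000, alpha: float = 0.05,
                 maf_min: float = 0.05, min_group_size: int = 10,
                 adjust_for_exposure: bool = False,
                 orient_risk_allele: bool = True):
        self.p_entry = p_entry
        self.r2_threshold = r2_threshold
        self.window_bp = window_bp
        self.alpha = alpha
        self.maf_min = maf_min
        self.min_group_size = min_group_size
        self.adjust_for_exposure = adjust_for_exposure
        self.orient_risk_allele = orient_risk_allele

    # ------------------------------------------------------------------

    def fit(self, genotypes: GenotypeMatrix, phenotype, covariates=None,
            exposure=None):
        if not isinstance(genotypes, GenotypeMatrix):
            raise TypeError("genotypes must be a GenotypeMatrix")
        for par in ("p_entry", "alpha", "r2_threshold"):
            v = getattr(self, par)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{par} must be in (0, 1]")
        y = np.asarray(phenotype, dtype=float).ravel()
        n = genotypes.n_samples
        if y.shape[0] != n:
            raise ValueError("phenotype length does not match genotypes")
        self.log_ = []

        expo = (None if not self.adjust_for_exposure
                else np.asarray(exposure, dtype=float))
        if self.adjust_for_exposure and exposure is None:
            raise ValueError("adjust_for_exposure=True requires an exposure")
        C = _covariate_matrix(n, covariates, expo)

        ok = np.isfinite(y) & np.all(np.isfinite(C), axis=1)
        ok &= np.all(np.isfinite(genotypes.dosage), axis=1)
        if (~ok).sum():
            self.log_.append(f"dropped {int((~ok).sum())} incomplete samples")
        y, C = y[ok], C[ok]
        G = genotypes.dosage[ok]

        res, y_res, skipped = _scan_core(genotypes.variants, G, y, C,
                                         self.maf_min)
        n_used = y.shape[0]
        self.log_.extend(skipped)

        if self.orient_risk_allele:
            beta = res["beta"].to_numpy()
            flip = np.isfinite(beta) & (beta > 0)
            if flip.any():
                res.loc[flip, ["ea", "nea"]] = res.loc[
                    flip, ["nea", "ea"]].to_numpy()
                res.loc[flip, "freq_ea"] = 1.0 - res.loc[flip, "freq_ea"]
                res.loc[flip, "beta"] = -res.loc[flip, "beta"]
                res.loc[flip, "flipped"] = True
                for vid in res.loc[flip, "id"]:
                    self.log_.append(
                        f"re-oriented {vid} to the risk (phenotype-lowering) "
                        "allele"
                    )

        # ---- clumping -------------------------------------------------
        lead_of = clump(res, G, self.p_entry, self.r2_threshold,
                        self.window_bp)
        res["clump_lead"] = [lead_of.get(v) == v for v in res["id"]]
        res["clump_of"] = [lead_of.get(v, "") for v in res["id"]]
        leads = res.index[res["clump_lead"]].tolist()
        self.n_leads_ = len(leads)

        # ---- Step 2: Levene's median test on covariate-only residuals --
        res["levene_w"] = np.nan
        res["levene_p"] = np.nan
        self.step2_threshold_ = (
            bonferroni_alpha(self.alpha, self.n_leads_) if leads else np.nan
        )
        for j in leads:
            g = G[:, j]
            # residualization ignores the SNP's own mean effect by design;
            # warn when the SNP tracks a covariate (known source of bias)
            if C.shape[1] > 1:
                cc = np.corrcoef(np.column_stack([g, C[:, 1:]]), rowvar=False)
                if np.nanmax(np.abs(cc[0, 1:])) > 0.1:
                    self.log_.append(
                        f"warning: {res.at[j, 'id']} correlates with a "
                        "covariate (|r| > 0.1); Levene residuals may be biased"
                    )
            lev = levene_median_test(y_res, hard_call(g),
                                     min_group_size=self.min_group_size)
            res.at[j, "levene_w"] = lev.w
            res.at[j, "levene_p"] = lev.p
        res["selected"] = res["clump_lead"] & (
            res["levene_p"] < self.step2_threshold_
        )
        if not leads:
            self.log_.append("no variants passed Step 1; empty selection")

        res["step1_threshold"] = self.p_entry
        res["step2_threshold"] = self.step2_threshold_
        self.results_ = res
        self.support_ = res["selected"].to_numpy(dtype=bool)
        return self

    def get_support(self):
        return self.support_

    def transform(self, genotypes):
        """Select the screened variant columns from dosages."""
        G = (genotypes.dosage if isinstance(genotypes, GenotypeMatrix)
             else np.asarray(genotypes, dtype=float))
        return G[:, self.support_]


def marginal_scan(genotypes: GenotypeMatrix, phenotype, covariates=None,
                  adjust_for_exposure: bool = False, exposure=None,
                  maf_min: float = 0.05,
                  orient_risk_allele: bool = True) -> pd.DataFrame:
    """Per-variant covariate-adjusted OLS scan (Step 1 without clumping)."""
    y = np.asarray(phenotype, dtype=float).ravel()
    n = genotypes.n_samples
    expo = np.asarray(exposure, dtype=float) if adjust_for_exposure else None
    if adjust_for_exposure and exposure is None:
        raise ValueError("adjust_for_exposure=True requires an exposure")
    C = _covariate_matrix(n, covariates, expo)
    ok = np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    ok &= np.all(np.isfinite(genotypes.dosage), axis=1)
    res, _, _ = _scan_core(genotypes.variants, genotypes.dosage[ok], y[ok],
                           C[ok], maf_min)
    if orient_risk_allele:
        flip = np.asarray(res["beta"] > 0) & np.isfinite(res["beta"])
        if flip.any():
            res.loc[flip, ["ea", "nea"]] = res.loc[
                flip, ["nea", "ea"]].to_numpy()
            res.loc[flip, "freq_ea"] = 1.0 - res.loc[flip, "freq_ea"]
            res.loc[flip, "beta"] = -res.loc[flip, "beta"]
            res.loc[flip, "flipped"] = True
    cols = ["id", "chrom", "pos", "ea", "nea", "freq_ea", "n_used",
            "beta", "se", "p_marginal", "flipped"]
    return res[cols]


def clump(scan: pd.DataFrame, dosage: np.ndarray, p_entry: float,
          r2_threshold: float, window_bp: int) -> dict[str, str]:
    """Greedy LD clumping; returns {variant_id: lead_id} for passers.

    Repeatedly takes the smallest-p unassigned variant with
    p < ``p_entry`` as a lead (ties broken by (chrom, pos, id) so the
    result does not depend on input order), then assigns every unassigned
    passer on the same chromosome within ``window_bp`` whose dosage
    r^2 with the lead is >= ``r2_threshold`` to its clump.
    """
    cand = scan.loc[np.asarray(scan["p_marginal"] < p_entry)
                    & np.isfinite(scan["p_marginal"])].copy()
    cand = cand.sort_values(["p_marginal", "chrom", "pos", "id"])
    assigned: dict[str, str] = {}
    order = cand.index.tolist()
    for i in order:
        vid = cand.at[i, "id"]
        if vid in assigned:
            continue
        assigned[vid] = vid
        gi = dosage[:, scan.index.get_loc(i)]
        for j in order:
            wid = cand.at[j, "id"]
            if wid in assigned:
                continue
            if cand.at[j, "chrom"] != cand.at[i, "chrom"]:
                continue
            if abs(int(cand.at[j, "pos"]) - int(cand.at[i, "pos"])) > window_bp:
                continue
            gj = dosage[:, scan.index.get_loc(j)]
            ok = np.isfinite(gi) & np.isfinite(gj)
            if gi[ok].std() == 0 or gj[ok].std() == 0:
                continue
            r = np.corrcoef(gi[ok], gj[ok])[0, 1]
            if r * r >= r2_threshold:
                assigned[wid] = vid
    return assigned


def two_step_screen(genotypes: GenotypeMatrix, phenotype, covariates=None,
                    exposure=None, **params) -> TwoStepScreen:
    """Run the full two-step screen; returns the fitted estimator."""
    sc = TwoStepScreen(**params)
    return sc.fit(genotypes, phenotype, covariates=covariates,
                  exposure=exposure)
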