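"""Bundled reference tables.

Published summary statistics for the 25 refractive-error variance QTLs
identified by the two-stage UK Biobank analysis (Stage I: measured
refractive error, avMSE, N = 88,334; Stage II: age of onset of spectacle
wear, AOSW, N = 252,838): per-variant Levene's median test p-values in
both stages, SNP x UniEdu interaction estimates for both outcomes, and
the gene-environment correlation (rGE) tests for the six lead
interaction variants. These tables serve as inputs to the replication,
enrichment and concordance analyses, and as worked-example data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_vqtl_summary", "load_rge_summary"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("vqtlscreen.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_vqtl_summary() -> pd.DataFrame:
    """25 vQTLs: two-stage Levene p-values and SNP x UniEdu interactions.

    Columns include the effect/non-effect alleles (effect allele =
    myopia-predisposing), effect-allele frequency, Levene's median test
    p-values in Stage I (avMSE) and Stage II (AOSW), and the SNP x UniEdu
    interaction coefficient with 95% CI and p-value for each stage's
    outcome (years of AOSW, diopters of avMSE). Rows are ordered by
    Stage-I Levene p-value.
    """
    return _read("ukb_vqtl_summary.tsv")


def load_rge_summary() -> pd.DataFrame:
    """rGE logistic tests (UniEdu on dosage) for the 6 lead GxE variants."""
    return _read("ukb_rge_summary.tsv")
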