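"""Readers and writers: VCF v4.2, dosage TSV, cohort TSV.

Genotypes travel either as VCF (GT hard calls; REF = non-effect allele,
ALT = effect allele, so ALT dosage counts the effect allele) via pysam,
or as a plain tab-separated dosage matrix (samples x variants, header row
of variant ids, optional sidecar variant-metadata TSV). Cohort tables are
tab-separated with '.' for missing values. Coordinates are 1-based
throughout (VCF convention).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam

from .cohort import GenotypeMatrix

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "read_genotypes",
    "write_cohort_tsv",
    "read_cohort_tsv",
]

MISSING = "."


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write hard-call GT records (REF = nea, ALT = ea), VCF v4.2."""
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(gm.variants["chrom"].astype(str)):
        header.contigs.add(chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in gm.samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for j, row in gm.variants.iterrows():
            rec = vcf.new_record(
                contig=str(row["chrom"]), start=int(row["pos"]) - 1,
                alleles=(str(row["nea"]), str(row["ea"])), id=str(row["id"]),
            )
            dos = gm.dosage[:, gm.variants.index.get_loc(j)]
            for s, d in zip(gm.samples, dos):
                if np.isnan(d):
                    rec.samples[s]["GT"] = (None, None)
                else:
                    k = int(round(d))
                    rec.samples[s]["GT"] = (1, 1) if k == 2 else (
                        (0, 1) if k == 1 else (0, 0))
            vcf.write(rec)


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a biallelic VCF into an effect-allele (ALT) dosage matrix."""
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if len(set(samples)) != len(samples):
            raise ValueError(f"{path}: duplicated sample ids")
        rows, meta = [], []
        for i, rec in enumerate(vcf):
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"{path}: record {i + 1} ({rec.id or rec.pos}) is not "
                    "biallelic"
                )
            dos = np.empty(len(samples))
            for k, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    dos[k] = np.nan
                else:
                    dos[k] = float(sum(gt))
            rows.append(dos)
            meta.append({
                "id": rec.id or f"var{i + 1}", "chrom": rec.chrom,
                "pos": rec.pos,  # pysam exposes the 1-based POS here
                "ea": rec.alts[0], "nea": rec.ref,
            })
    if not rows:
        raise ValueError(f"{path}: no variant records")
    variants = pd.DataFrame(meta)
    if variants["id"].duplicated().any():
        raise ValueError(f"{path}: duplicated variant ids")
    return GenotypeMatrix(np.column_stack(rows) if len(rows) else
                          np.empty((len(samples), 0)), variants, samples)


def write_dosage_tsv(gm: GenotypeMatrix, path: str,
                     variants_path: str | None = None) -> None:
    """Samples x variants dosage TSV ('.' for missing) + metadata sidecar."""
    frame = gm.to_frame()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t", na_rep=MISSING, float_format="%g")
    if variants_path is not None:
        gm.variants.to_csv(variants_path, sep="\t", index=False,
                           na_rep=MISSING)


def read_dosage_tsv(path: str, variants_path: str | None = None,
                    ) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING])
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicated sample ids")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicated variant ids")
    dosage = df.to_numpy(dtype=float)
    fin = dosage[np.isfinite(dosage)]
    if fin.size and (fin.min() < 0 or fin.max() > 2):
        raise ValueError(f"{path}: dosages outside [0, 2]")
    if variants_path is not None:
        variants = pd.read_csv(variants_path, sep="\t", na_values=[MISSING])
        if list(variants["id"]) != list(df.columns):
            raise ValueError("variant metadata does not match dosage columns")
    else:
        variants = pd.DataFrame({
            "id": list(df.columns),
            "chrom": ["."] * df.shape[1],
            "pos": np.arange(1, df.shape[1] + 1),
            "ea": ["."] * df.shape[1],
            "nea": ["."] * df.shape[1],
        })
    return GenotypeMatrix(dosage, variants, [str(s) for s in df.index])


def read_genotypes(path: str, variants_path: str | None = None,
                   ) -> GenotypeMatrix:
    """Dispatch on extension: .vcf[.gz] via pysam, anything else as TSV."""
    base = path[:-3] if path.endswith(".gz") else path
    if os.path.splitext(base)[1].lower() == ".vcf":
        return read_vcf(path)
    return read_dosage_tsv(path, variants_path=variants_path)


def write_cohort_tsv(cohort: pd.DataFrame, path: str) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_cohort_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: cohort table must have a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample ids")
    has_any = False
    for col in ("avMSE", "AOSW"):
        if col in df.columns:
            has_any = has_any or bool(df[col].notna().any())
    if not has_any:
        raise ValueError(f"{path}: need at least one of avMSE/AOSW")
    return df
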