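"""End-to-end orchestration of the synthetic two-stage workflow.

``run_pipeline`` executes: simulate Stage-I (avMSE) and Stage-II (AOSW)
cohorts -> write/read the standard input files -> two-step vQTL screen in
Stage I -> Levene confirmation of the selected variants in Stage II ->
GxE interaction tests (both stages, UniEdu and EduYears exposures, linear
+ robust + logistic families), dominance model comparison, GxG all-pairs
and rGE tests -> replication/concordance evaluation. Every stage writes a
TSV (header comment carrying the config hash and seed) plus a plain-text
log; evaluation also emits JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import platform
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (CohortSimulator, GenotypeMatrix, VariantSpec,
                     classify_myopic)
from .evaluation import effect_concordance, replication_enrichment
from .interaction import (dominance_model_comparison, gxe_test,
                          gxg_all_pairs, rge_test)
from .io import (read_cohort_tsv, read_genotypes, write_cohort_tsv,
                 write_dosage_tsv, write_vcf)
from .models import hard_call, levene_median_test
from .screening import TwoStepScreen

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "default_demo_config",
    "demo_variants",
    "covariate_frame",
]

COVARIATE_COLS = ["sex", "age", "age2", "array"] + [f"pc{k}" for k in
                                                    range(1, 11)]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


def _from_dict(cls, d: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")
    return cls(**d)


@dataclass
class SimulateConfig:
    variants: list = field(default_factory=list)   # dicts or VariantSpec
    n_stage1: int = 2000
    n_stage2: int = 2000
    prevalence_stage1: float = 0.37
    prevalence_stage2: float = 0.32
    exposure_effect_stage1: float = 0.0   # diopters of avMSE per UniEdu unit
    exposure_effect_stage2: float = 0.0   # years of AOSW per UniEdu unit
    stage2_effect_scale: float = 1.0      # diopters -> years effect rescaling
    ld_copy_prob: float = 0.95
    gxg_pairs: list = field(default_factory=list)

    def specs(self) -> list[VariantSpec]:
        return [v if isinstance(v, VariantSpec) else VariantSpec(**v)
                for v in self.variants]


@dataclass
class Stage1Config:
    p_entry: float = 1e-4
    r2_threshold: float = 0.1
    window_bp: int = 500_000
    alpha: float = 0.05
    maf_min: float = 0.05
    min_group_size: int = 10
    adjust_for_exposure: bool = False


@dataclass
class Stage2Config:
    alpha: float = 0.05
    min_group_size: int = 10


@dataclass
class InteractionConfig:
    exposures: list = field(default_factory=lambda: ["UniEdu", "EduYears"])
    include_logistic: bool = True
    dominance: bool = True
    gxg: bool = True
    rge: bool = True


@dataclass
class EvaluationConfig:
    replication_alpha: float = 0.05


@dataclass
class PipelineConfig:
    seed: int = 1
    genotype_format: str = "tsv"          # "tsv" or "vcf"
    sensitivity_adjust_exposure: bool = False
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    stage1: Stage1Config = field(default_factory=Stage1Config)
    stage2: Stage2Config = field(default_factory=Stage2Config)
    interaction: InteractionConfig = field(default_factory=InteractionConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def __post_init__(self):
        for name, v in (("stage1.p_entry", self.stage1.p_entry),
                        ("stage1.alpha", self.stage1.alpha),
                        ("stage2.alpha", self.stage2.alpha),
                        ("evaluation.replication_alpha",
                         self.evaluation.replication_alpha)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.genotype_format not in ("tsv", "vcf"):
            raise ValueError("genotype_format must be 'tsv' or 'vcf'")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sub = {
            "simulate": SimulateConfig, "stage1": Stage1Config,
            "stage2": Stage2Config, "interaction": InteractionConfig,
            "evaluation": EvaluationConfig,
        }
        kwargs = {}
        for key, kls in sub.items():
            if key in d:
                kwargs[key] = _from_dict(kls, d.pop(key), key)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d, **kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"]["variants"] = [
            dataclasses.asdict(v) if isinstance(v, VariantSpec) else dict(v)
            for v in self.simulate.variants
        ]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def covariate_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Standard adjustment set: sex, age, age^2, array, PC1-10."""
    cov = cohort[["sex", "age", "array"]
                 + [f"pc{k}" for k in range(1, 11)]].copy()
    cov.insert(2, "age2", cov["age"].astype(float) ** 2)
    return cov[COVARIATE_COLS]


def demo_variants(seed: int = 7, n_variants: int = 500, n_gxe: int = 3,
                  n_marginal: int = 22) -> list[VariantSpec]:
    """Deterministic demo variant panel: planted GxE + marginal + null.

    The GxE variants carry a marginal effect of -0.3 D and an interaction
    effect of -2.0 D per allele per UniEdu unit (~0.75 phenotype SD),
    sized so the variance-heterogeneity step has near-complete power at
    the demo scale of 2,000 samples; marginal-only variants carry mean
    effects without variance heterogeneity; three LD triplets exercise
    clumping; everything else is null.
    """
    rng = np.random.default_rng(seed)
    specs = []
    alleles = ("A", "C", "G", "T")
    for j in range(n_variants):
        maf = float(rng.uniform(0.08, 0.5))
        chrom = str(1 + j % 22)
        pos = 1_000_000 + (j // 22) * 1_000_000 + int(rng.integers(0, 1000))
        ea, nea = rng.choice(alleles, size=2, replace=False)
        kw = dict(id=f"v{j + 1:04d}", chrom=chrom, pos=pos, ea=str(ea),
                  nea=str(nea), maf=maf)
        if j < n_gxe:
            kw.update(maf=float(rng.uniform(0.25, 0.45)),
                      beta_marginal=-0.3, beta_gxe=-2.0)
        elif j < n_gxe + n_marginal:
            kw.update(beta_marginal=float(-rng.uniform(0.25, 0.5)))
        elif j < n_gxe + n_marginal + 9:
            # three LD triplets among null variants, same chrom/maf per block
            block = (j - n_gxe - n_marginal) // 3
            kw.update(ld_block=block, chrom="22",
                      pos=5_000_000 + block * 50_000 + (j % 3) * 1_000,
                      maf=0.3)
        specs.append(VariantSpec(**kw))
    return specs


def default_demo_config(seed: int = 1) -> PipelineConfig:
    """2,000-sample, 500-variant demo with 3 planted GxE variants."""
    return PipelineConfig(
        seed=seed,
        simulate=SimulateConfig(
            variants=demo_variants(),
            n_stage1=2000, n_stage2=4000,
            exposure_effect_stage1=-1.2,
            exposure_effect_stage2=-3.0,
            stage2_effect_scale=2.5,
        ),
    )


def _scaled_specs(specs, scale):
    if scale == 1.0:
        return specs
    return [replace(s, beta_marginal=s.beta_marginal * scale,
                    beta_gxe=s.beta_gxe * scale) for s in specs]


def _write_tsv(df: pd.DataFrame, path: str, header_line: str) -> None:
    with open(path, "w") as fh:
        fh.write(header_line + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=".")


def run_pipeline(config: PipelineConfig, outdir: str) -> str:
    """Run the full synthetic Stage-I/Stage-II workflow into ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    tag = f"# vqtlscreen={__version__} config_hash={config.config_hash()} seed={config.seed}"
    log: list[str] = [tag.lstrip("# "),
                      f"python={platform.python_version()}"]

    def _stage(name):
        def deco(fn):
            def wrapped(*a, **kw):
                try:
                    return fn(*a, **kw)
                except PipelineError:
                    raise
                except Exception as exc:
                    raise PipelineError(name, type(exc).__name__, str(exc))
            return wrapped
        return deco

    ss = np.random.SeedSequence(config.seed)
    seed1, seed2 = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    sim = config.simulate
    specs1 = sim.specs()
    specs2 = _scaled_specs(specs1, sim.stage2_effect_scale)

    @_stage("simulate")
    def _simulate():
        gm1, coh1 = CohortSimulator(
            specs1, n=sim.n_stage1, stage="stage1",
            prevalence=sim.prevalence_stage1,
            exposure_effect=sim.exposure_effect_stage1,
            gxg_pairs=sim.gxg_pairs, ld_copy_prob=sim.ld_copy_prob,
        ).simulate(seed1)
        gm2, coh2 = CohortSimulator(
            specs2, n=sim.n_stage2, stage="stage2",
            prevalence=sim.prevalence_stage2,
            exposure_effect=sim.exposure_effect_stage2,
            gxg_pairs=[(a, b, w * sim.stage2_effect_scale)
                       for a, b, w in sim.gxg_pairs],
            ld_copy_prob=sim.ld_copy_prob,
        ).simulate(seed2)
        # Stage II includes spectacle wearers only (AOSW reporters)
        wear = coh2["AOSW"].notna()
        log.append(f"stage2: excluded {int((~wear).sum())} non-wearers "
                   f"of {len(coh2)}")
        coh2 = coh2.loc[wear].reset_index(drop=True)
        gm2 = GenotypeMatrix(gm2.dosage[wear.to_numpy()], gm2.variants,
                             [s for s, w in zip(gm2.samples, wear) if w])
        for stage, gm, coh in (("stage1", gm1, coh1), ("stage2", gm2, coh2)):
            if config.genotype_format == "vcf":
                write_vcf(gm, os.path.join(outdir, f"{stage}_genotypes.vcf"))
            else:
                write_dosage_tsv(
                    gm, os.path.join(outdir, f"{stage}_dosage.tsv"),
                    os.path.join(outdir, f"{stage}_variants.tsv"))
            write_cohort_tsv(coh, os.path.join(outdir, f"{stage}_cohort.tsv"))

    _simulate()

    @_stage("read")
    def _read(stage):
        if config.genotype_format == "vcf":
            gm = read_genotypes(os.path.join(outdir,
                                             f"{stage}_genotypes.vcf"))
        else:
            gm = read_genotypes(
                os.path.join(outdir, f"{stage}_dosage.tsv"),
                variants_path=os.path.join(outdir, f"{stage}_variants.tsv"))
        coh = read_cohort_tsv(os.path.join(outdir, f"{stage}_cohort.tsv"))
        return gm, coh

    gm1, coh1 = _read("stage1")
    gm2, coh2 = _read("stage2")

    @_stage("screen")
    def _screen(adjust):
        sc = TwoStepScreen(
            p_entry=config.stage1.p_entry,
            r2_threshold=config.stage1.r2_threshold,
            window_bp=config.stage1.window_bp, alpha=config.stage1.alpha,
            maf_min=config.stage1.maf_min,
            min_group_size=config.stage1.min_group_size,
            adjust_for_exposure=adjust,
        )
        sc.fit(gm1, coh1["avMSE"], covariates=covariate_frame(coh1),
               exposure=coh1["UniEdu"])
        return sc

    screen = _screen(config.stage1.adjust_for_exposure)
    log.extend(screen.log_)
    _write_tsv(screen.results_, os.path.join(outdir, "screen_results.tsv"),
               tag)
    selected = screen.results_.loc[screen.results_["selected"], "id"].tolist()
    log.append(f"screen: {screen.n_leads_} leads, {len(selected)} selected")

    @_stage("confirm_vqtl")
    def _confirm():
        cov2 = covariate_frame(coh2)
        y = coh2["AOSW"].to_numpy(dtype=float)
        C = np.column_stack([np.ones(len(coh2)), cov2.to_numpy(float)])
        okv = np.isfinite(y)
        yr = y[okv] - C[okv] @ np.linalg.lstsq(C[okv], y[okv], rcond=None)[0]
        rows = []
        for vid in selected:
            g = gm2.column(vid)[okv]
            lev = levene_median_test(
                yr, hard_call(g),
                min_group_size=config.stage2.min_group_size)
            rows.append({"id": vid, "levene_w": lev.w, "df1": lev.df1,
                         "df2": lev.df2, "levene_p": lev.p})
        return pd.DataFrame(rows, columns=["id", "levene_w", "df1", "df2",
                                           "levene_p"])

    confirm = _confirm()
    _write_tsv(confirm, os.path.join(outdir, "stage2_levene.tsv"), tag)

    @_stage("interaction")
    def _interactions():
        rows = []
        dom_rows = []
        for stage, gm, coh, outcome_col in (
                ("stage1", gm1, coh1, "avMSE"), ("stage2", gm2, coh2,
                                                 "AOSW")):
            cov = covariate_frame(coh)
            y = coh[outcome_col].to_numpy(dtype=float)
            myo = coh["Myopic"].to_numpy(dtype=float)
            for vid in selected:
                g = gm.column(vid)
                for expo_name in config.interaction.exposures:
                    e = coh[expo_name].to_numpy(dtype=float)
                    fam = ("linear" if expo_name == "UniEdu"
                           else "linear_robust")
                    r = gxe_test(g, e, y, cov, family=fam, variant_id=vid,
                                 exposure_name=expo_name,
                                 outcome_name=outcome_col)
                    rows.append({**r.to_row(), "stage": stage})
                    if config.interaction.include_logistic:
                        rl = gxe_test(g, e, myo, cov, family="logistic",
                                      variant_id=vid,
                                      exposure_name=expo_name,
                                      outcome_name="Myopic")
                        rows.append({**rl.to_row(), "stage": stage})
                if config.interaction.dominance and stage == "stage2":
                    try:
                        fits, best = dominance_model_comparison(
                            g, coh["UniEdu"].to_numpy(float), y, cov,
                            variant_id=vid, exposure_name="UniEdu",
                            outcome_name=outcome_col)
                        for coding, r in fits.items():
                            dom_rows.append({
                                "id": vid, "coding": coding, "beta": r.beta,
                                "p": r.p, "minus2loglik": r.minus2loglik,
                                "most_parsimonious": coding == best})
                    except ValueError as exc:
                        log.append(f"dominance: {vid}: {exc}")
        return pd.DataFrame(rows), pd.DataFrame(dom_rows)

    inter, dom = _interactions()
    _write_tsv(inter, os.path.join(outdir, "interaction_results.tsv"), tag)
    if len(dom):
        _write_tsv(dom, os.path.join(outdir, "dominance_results.tsv"), tag)

    @_stage("gxg")
    def _gxg():
        if not config.interaction.gxg or len(selected) < 2:
            return None
        frames = []
        for stage, gm, coh, outcome_col in (
                ("stage1", gm1, coh1, "avMSE"),
                ("stage2", gm2, coh2, "AOSW")):
            dosf = pd.DataFrame({v: gm.column(v) for v in selected},
                                index=gm.samples)
            out = gxg_all_pairs(dosf, coh[outcome_col].to_numpy(float),
                                covariate_frame(coh),
                                outcome_name=outcome_col)
            out.insert(0, "stage", stage)
            frames.append(out)
        return pd.concat(frames, ignore_index=True)

    gxg = _gxg()
    if gxg is not None:
        _write_tsv(gxg, os.path.join(outdir, "gxg_results.tsv"), tag)

    @_stage("rge")
    def _rge():
        if not config.interaction.rge:
            return None
        rows = []
        for vid in selected:
            r = rge_test(gm2.column(vid), coh2["UniEdu"].to_numpy(float),
                         covariate_frame(coh2), variant_id=vid)
            rows.append({"id": vid, "logodds": r.beta,
                         "odds_ratio": r.odds_ratio,
                         "or_lo": r.or_ci95[0], "or_hi": r.or_ci95[1],
                         "p": r.p, "n_used": r.n_used})
        return pd.DataFrame(rows, columns=["id", "logodds", "odds_ratio",
                                           "or_lo", "or_hi", "p", "n_used"])

    rge = _rge()
    if rge is not None:
        _write_tsv(rge, os.path.join(outdir, "rge_results.tsv"), tag)

    @_stage("evaluate")
    def _evaluate():
        summary: dict = {"seed": config.seed,
                         "config_hash": config.config_hash(),
                         "n_selected": len(selected)}
        if len(confirm):
            ev = replication_enrichment(
                confirm["id"], confirm["id"], confirm["levene_p"],
                alpha=config.evaluation.replication_alpha)
            summary.update(n_tested=ev.n_tested,
                           n_replicated=ev.n_replicated,
                           enrichment_p=ev.enrichment_p)
        if len(inter):
            b1 = inter.query("stage == 'stage1' and exposure == 'UniEdu' "
                             "and family == 'linear'")
            b2 = inter.query("stage == 'stage2' and exposure == 'UniEdu' "
                             "and family == 'linear'")
        else:
            b1 = b2 = inter
        if len(b1) >= 3 and len(b1) == len(b2):
            rho, p = effect_concordance(b1["beta"].to_numpy(),
                                        b2["beta"].to_numpy())
            summary.update(spearman_rho=rho, spearman_p=p)
        if config.sensitivity_adjust_exposure:
            alt = _screen(not config.stage1.adjust_for_exposure)
            alt_sel = set(alt.results_.loc[alt.results_["selected"], "id"])
            base = set(selected)
            union = base | alt_sel
            summary["sensitivity_adjust_exposure"] = {
                "selected_base": sorted(base),
                "selected_toggled": sorted(alt_sel),
                "overlap": len(base & alt_sel),
                "jaccard": (len(base & alt_sel) / len(union)
                            if union else 1.0),
            }
        with open(os.path.join(outdir, "evaluation.json"), "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        return summary

    _evaluate()
    with open(os.path.join(outdir, "pipeline.log"), "w") as fh:
        fh.write("\n".join(log) + "\n")
    return outdir
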