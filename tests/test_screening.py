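"""Two-step screen: scan oracle, clumping, selection behavior."""

import numpy as np
import pandas as pd
import pytest

from vqtlscreen import (GenotypeMatrix, TwoStepScreen, VariantSpec,
                        avmse_model, marginal_scan, simulate_genotypes,
                        simulate_phenotype, two_step_screen)
from vqtlscreen.pipeline import covariate_frame
from vqtlscreen.screening import clump


def _specs(mafs, **common):
    return [VariantSpec(id=f"v{i}", chrom=str(1 + i % 2), pos=1000 * (i + 1),
                        maf=m, **common) for i, m in enumerate(mafs)]


class TestMarginalScan:
    def test_matches_per_variant_ols_oracle(self):
        # scan equals brute-force covariate-adjusted OLS per variant
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        specs = _specs([0.2, 0.3, 0.4, 0.5])
        gm = simulate_genotypes(specs, 400, seed=1)
        C = rng.standard_normal((400, 3))
        y = gm.dosage @ [0.2, 0.0, -0.1, 0.0] + C @ [1.0, -1.0, 0.5] \
            + rng.standard_normal(400)
        res = marginal_scan(gm, y, covariates=C, orient_risk_allele=False)
        for j in range(4):
            X = sm.add_constant(np.column_stack([C, gm.dosage[:, j]]))
            ref = sm.OLS(y, X).fit()
            assert res["beta"][j] == pytest.approx(ref.params[-1], abs=1e-10)
            assert res["se"][j] == pytest.approx(ref.bse[-1], abs=1e-10)

    def test_null_p_uniform(self):
        from scipy import stats

        specs = _specs([0.3])
        pvals = []
        for s in range(300):
            gm = simulate_genotypes(specs, 250, seed=1000 + s)
            rng = np.random.default_rng(5000 + s)
            y = rng.standard_normal(250)
            pvals.append(marginal_scan(gm, y)["p_marginal"][0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.001

    def test_known_beta_ci_coverage(self):
        rng0 = np.random.default_rng(77)
        hits = 0
        reps = 300
        specs = _specs([0.3])
        for s in range(reps):
            gm = simulate_genotypes(specs, 500, seed=rng0.integers(2**31))
            rng = np.random.default_rng(rng0.integers(2**31))
            y = -0.4 * gm.dosage[:, 0] + rng.standard_normal(500)
            row = marginal_scan(gm, y).iloc[0]
            lo, hi = row.beta - 1.96 * row.se, row.beta + 1.96 * row.se
            hits += lo <= -0.4 <= hi
        assert hits / reps > 0.90

    def test_risk_allele_orientation(self):
        # a protective (positive-beta) allele is flipped; p unchanged
        specs = _specs([0.3])
        gm = simulate_genotypes(specs, 2000, seed=3)
        rng = np.random.default_rng(4)
        y = +0.8 * gm.dosage[:, 0] + rng.standard_normal(2000)
        raw = marginal_scan(gm, y, orient_risk_allele=False).iloc[0]
        flip = marginal_scan(gm, y, orient_risk_allele=True).iloc[0]
        assert flip.flipped and not raw.flipped
        assert flip.beta == pytest.approx(-raw.beta)
        assert flip.freq_ea == pytest.approx(1 - raw.freq_ea)
        assert flip.p_marginal == pytest.approx(raw.p_marginal)
        assert (flip.ea, flip.nea) == (raw.nea, raw.ea)

    def test_monomorphic_skipped(self):
        gm = simulate_genotypes(_specs([0.3, 0.3]), 100, seed=5)
        gm.dosage[:, 1] = 0.0
        res = marginal_scan(gm, np.random.default_rng(6).standard_normal(100),
                            maf_min=0.0)
        assert np.isnan(res["beta"][1]) and np.isfinite(res["beta"][0])


class TestClump:
    def _scan_frame(self, ids, chroms, poss, ps):
        return pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss,
                             "p_marginal": ps})

    def test_perfect_ld_one_lead(self):
        specs = [VariantSpec(id="a", chrom="1", pos=1000, maf=0.3, ld_block=1),
                 VariantSpec(id="b", chrom="1", pos=2000, maf=0.3, ld_block=1)]
        gm = simulate_genotypes(specs, 500, seed=7, ld_copy_prob=1.0)
        scan = self._scan_frame(["a", "b"], ["1", "1"], [1000, 2000],
                                [1e-8, 1e-6])
        lead_of = clump(scan, gm.dosage, 1e-4, 0.1, 500_000)
        assert lead_of == {"a": "a", "b": "a"}

    def test_different_chromosomes_all_leads(self):
        specs = [VariantSpec(id="a", chrom="1", pos=1000, maf=0.3),
                 VariantSpec(id="b", chrom="2", pos=1000, maf=0.3)]
        gm = simulate_genotypes(specs, 500, seed=8)
        scan = self._scan_frame(["a", "b"], ["1", "2"], [1000, 1000],
                                [1e-8, 1e-6])
        lead_of = clump(scan, gm.dosage, 1e-4, 0.1, 500_000)
        assert lead_of == {"a": "a", "b": "b"}

    def test_window_limits_assignment(self):
        specs = [VariantSpec(id="a", chrom="1", pos=1000, maf=0.3,
                             ld_block=1),
                 VariantSpec(id="b", chrom="1", pos=900_000, maf=0.3,
                             ld_block=1)]
        gm = simulate_genotypes(specs, 500, seed=9, ld_copy_prob=1.0)
        scan = self._scan_frame(["a", "b"], ["1", "1"], [1000, 900_000],
                                [1e-8, 1e-6])
        lead_of = clump(scan, gm.dosage, 1e-4, 0.1, 500_000)
        assert lead_of == {"a": "a", "b": "b"}  # outside the window

    def test_matches_brute_force_on_block_structure(self):
        # exhaustive reference implementation of the same greedy rule
        rng = np.random.default_rng(10)
        specs = []
        for j in range(12):
            specs.append(VariantSpec(id=f"v{j}", chrom="1",
                                     pos=10_000 + 2_000 * j, maf=0.3,
                                     ld_block=j // 3))
        gm = simulate_genotypes(specs, 800, seed=11, ld_copy_prob=0.97)
        ps = rng.uniform(1e-9, 5e-5, 12)
        scan = self._scan_frame([s.id for s in specs],
                                ["1"] * 12, [s.pos for s in specs], ps)
        got = clump(scan, gm.dosage, 1e-4, 0.1, 500_000)

        # reference: explicit loop over sorted candidates with set algebra
        order = np.argsort(ps, kind="stable")
        expect = {}
        for i in order:
            vid = specs[i].id
            if vid in expect:
                continue
            expect[vid] = vid
            for j in order:
                wid = specs[j].id
                if wid in expect:
                    continue
                if abs(specs[j].pos - specs[i].pos) > 500_000:
                    continue
                r = np.corrcoef(gm.dosage[:, i], gm.dosage[:, j])[0, 1]
                if r * r >= 0.1:
                    expect[wid] = vid
        assert got == expect

    def test_no_passers_empty(self):
        scan = self._scan_frame(["a"], ["1"], [1], [0.5])
        assert clump(scan, np.zeros((10, 1)), 1e-4, 0.1, 500_000) == {}


class TestTwoStepScreen:
    def test_recovers_planted_gxe(self, small_cohort):
        specs, gm, coh = small_cohort
        sc = two_step_screen(gm, coh["avMSE"],
                             covariates=covariate_frame(coh),
                             exposure=coh["UniEdu"])
        res = sc.results_
        assert res.loc[res["id"] == "gxe1", "selected"].item()
        # marginal-only variant reaches Step 2 but shows no heterogeneity
        marg = res.loc[res["id"] == "marg1"].iloc[0]
        if marg.clump_lead:
            assert marg.levene_p > sc.step2_threshold_

    def test_selection_invariant_to_variant_order(self, small_cohort):
        specs, gm, coh = small_cohort
        cov = covariate_frame(coh)
        sel1 = set(two_step_screen(gm, coh["avMSE"], covariates=cov)
                   .results_.query("selected")["id"])
        perm = [3, 0, 4, 2, 1]
        gmp = GenotypeMatrix(gm.dosage[:, perm],
                             gm.variants.iloc[perm].reset_index(drop=True),
                             gm.samples)
        sel2 = set(two_step_screen(gmp, coh["avMSE"], covariates=cov)
                   .results_.query("selected")["id"])
        assert sel1 == sel2

    def test_pure_marginal_effect_not_selected(self):
        # additive mean effect + homoskedastic noise: no heterogeneity,
        # Step 2 false-positive rate stays near the family-wise level
        specs = [VariantSpec(id="m", chrom="1", pos=1, maf=0.3,
                             beta_marginal=-0.8)]
        n_sel = 0
        for s in range(40):
            gm = simulate_genotypes(specs, 1200, seed=200 + s)
            rng = np.random.default_rng(900 + s)
            y = -0.8 * gm.dosage[:, 0] + rng.standard_normal(1200)
            sc = two_step_screen(gm, y)
            n_sel += int(sc.results_["selected"].sum())
        assert n_sel <= 2

    def test_levene_power_monotone_in_effect(self):
        # larger |interaction| -> smaller Levene p, common random numbers
        specs = [VariantSpec(id="g", chrom="1", pos=1, maf=0.3)]
        gm = simulate_genotypes(specs, 3000, seed=42)
        rng = np.random.default_rng(43)
        e = (rng.random(3000) < 0.35).astype(float)
        noise = rng.standard_normal(3000)
        ps = []
        for b in (0.5, 1.0, 2.0):
            y = -1.0 * e + (-b) * gm.dosage[:, 0] * e + noise
            sc = two_step_screen(gm, y, p_entry=1.0 - 1e-12)
            ps.append(sc.results_["levene_p"][0])
        assert ps[0] > ps[1] > ps[2]

    def test_zero_leads_is_empty_not_error(self):
        specs = _specs([0.3, 0.4])
        gm = simulate_genotypes(specs, 300, seed=12)
        y = np.random.default_rng(13).standard_normal(300)
        sc = two_step_screen(gm, y)
        assert sc.n_leads_ == 0
        assert not sc.results_["selected"].any()
        assert any("no variants passed" in m for m in sc.log_)

    def test_maf_filter(self):
        specs = _specs([0.03, 0.3])
        gm = simulate_genotypes(specs, 2000, seed=14)
        y = np.random.default_rng(15).standard_normal(2000)
        sc = two_step_screen(gm, y, maf_min=0.05)
        assert np.isnan(sc.results_["beta"][0])
        assert np.isfinite(sc.results_["beta"][1])

    def test_bonferroni_threshold_for_956_leads(self):
        sc = TwoStepScreen()
        from vqtlscreen.models import bonferroni_alpha
        assert bonferroni_alpha(sc.alpha, 956) == pytest.approx(5.23e-5,
                                                                rel=1e-3)

    def test_transform_selects_columns(self, small_cohort):
        specs, gm, coh = small_cohort
        sc = two_step_screen(gm, coh["avMSE"],
                             covariates=covariate_frame(coh))
        sel = sc.transform(gm)
        assert sel.shape == (gm.n_samples, int(sc.results_["selected"].sum()))

    def test_sklearn_params_roundtrip(self):
        sc = TwoStepScreen(p_entry=1e-3)
        assert TwoStepScreen(**sc.get_params()).p_entry == 1e-3
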