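"""Simulator: HWE sampling, LD coupling, exposure, phenotype models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vqtlscreen import (CohortSimulator, PhenotypeModel, VariantSpec,
                        aosw_model, avmse_model, classify_myopic,
                        simulate_exposure, simulate_genotypes,
                        simulate_phenotype)
from vqtlscreen.interaction import rge_test


def _spec(**kw):
    base = dict(id="v1", chrom="1", pos=100, ea="A", nea="G", maf=0.3)
    base.update(kw)
    return VariantSpec(**base)


class TestVariantSpec:
    def test_maf_bounds_validated(self):
        with pytest.raises(ValueError):
            _spec(maf=0.0)
        with pytest.raises(ValueError):
            _spec(maf=0.7)
        with pytest.raises(ValueError):
            _spec(maf=None, ea_freq=1.0)

    def test_major_effect_allele_orientation(self):
        s = _spec(maf=None, ea_freq=0.904)
        assert s.maf == pytest.approx(0.096)
        assert not s.ea_is_minor

    def test_unknown_coding_rejected(self):
        with pytest.raises(ValueError):
            _spec(coding="codominant")


class TestGenotypes:
    def test_hwe_proportions_gof(self):
        # chi-square goodness of fit to ((1-p)^2, 2p(1-p), p^2) at n=50,000
        for maf in (0.1, 0.3, 0.5):
            gm = simulate_genotypes([_spec(maf=maf)], 50_000, seed=7)
            counts = np.bincount(gm.dosage[:, 0].astype(int), minlength=3)
            exp = 50_000 * np.array(
                [(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2])
            chi2 = ((counts - exp) ** 2 / exp).sum()
            assert stats.chi2.sf(chi2, 2) > 0.001

    def test_symmetric_maf_half(self):
        gm = simulate_genotypes([_spec(maf=0.5)], 200_000, seed=3)
        freqs = np.bincount(gm.dosage[:, 0].astype(int), minlength=3) / 200_000
        assert np.allclose(freqs, [0.25, 0.5, 0.25], atol=0.01)

    def test_major_effect_allele_dosage_frequency(self):
        # FreqEA 0.904: simulate on minor allele, report effect-allele dosage
        gm = simulate_genotypes([_spec(maf=None, ea_freq=0.904)], 100_000,
                                seed=5)
        assert gm.ea_frequencies()[0] == pytest.approx(0.904, abs=0.005)

    def test_perfect_copy_gives_r2_one(self):
        specs = [_spec(id="a", ld_block=1), _spec(id="b", pos=200, ld_block=1)]
        gm = simulate_genotypes(specs, 5000, seed=1, ld_copy_prob=1.0)
        r = np.corrcoef(gm.dosage[:, 0], gm.dosage[:, 1])[0, 1]
        assert r ** 2 == pytest.approx(1.0)

    def test_copy_probability_tunes_r2(self):
        specs = [_spec(id="a", ld_block=1), _spec(id="b", pos=200, ld_block=1)]
        gm = simulate_genotypes(specs, 200_000, seed=2, ld_copy_prob=0.8)
        r = np.corrcoef(gm.dosage[:, 0], gm.dosage[:, 1])[0, 1]
        assert r == pytest.approx(0.8, abs=0.02)   # allele corr = copy prob

    def test_blocks_independent(self):
        specs = [_spec(id="a", ld_block=1), _spec(id="b", pos=200, ld_block=2)]
        gm = simulate_genotypes(specs, 100_000, seed=4, ld_copy_prob=1.0)
        r = np.corrcoef(gm.dosage[:, 0], gm.dosage[:, 1])[0, 1]
        assert abs(r) < 0.02

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_genotypes([], 10, seed=0)
        with pytest.raises(ValueError):
            simulate_genotypes([_spec()], 0, seed=0)


class TestExposure:
    def test_prevalence_recovered(self):
        gm = simulate_genotypes([_spec()], 50_000, seed=8)
        expo = simulate_exposure(gm, [_spec()], prevalence=0.32, seed=9)
        assert expo["UniEdu"].mean() == pytest.approx(0.32, abs=0.01)
        assert expo["EduYears"].between(13, 26).all()

    def test_null_rge_equal_frequencies(self):
        spec = _spec(rge_logodds=0.0)
        gm = simulate_genotypes([spec], 50_000, seed=10)
        expo = simulate_exposure(gm, [spec], prevalence=0.35, seed=11)
        g = gm.dosage[:, 0]
        e = expo["UniEdu"].to_numpy()
        f1 = g[e == 1].mean() / 2
        f0 = g[e == 0].mean() / 2
        assert f1 == pytest.approx(f0, abs=0.01)

    def test_rge_odds_ratio_recovered(self):
        # planted OR 1.017 per effect allele, recovered by logistic refit
        spec = _spec(rge_logodds=np.log(1.017))
        gm = simulate_genotypes([spec], 400_000, seed=12)
        expo = simulate_exposure(gm, [spec], prevalence=0.32, seed=13)
        res = rge_test(gm.dosage[:, 0], expo["UniEdu"].to_numpy())
        assert res.or_ci95[0] < 1.017 < res.or_ci95[1]
        assert res.odds_ratio == pytest.approx(1.017, abs=0.01)

    def test_prevalence_validated(self):
        gm = simulate_genotypes([_spec()], 10, seed=0)
        with pytest.raises(ValueError):
            simulate_exposure(gm, [_spec()], prevalence=1.5, seed=0)


class TestPhenotypeModel:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PhenotypeModel(components=((0.5, 0, 1), (0.4, 0, 1)))

    def test_sd_positive(self):
        with pytest.raises(ValueError):
            PhenotypeModel(components=((1.0, 0.0, 0.0),))

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            PhenotypeModel(family="lognormal")

    def test_null_model_is_standard_normal(self):
        model = PhenotypeModel(components=((1.0, 0.0, 1.0),))
        gm = simulate_genotypes([_spec()], 20_000, seed=20)
        y, _ = simulate_phenotype(gm, None, None, [_spec()], model, seed=21)
        assert stats.kstest(y, "norm").pvalue > 0.001

    def test_phenotype_invariant_to_genotype_under_null(self):
        # all effect sizes zero: two-sample KS across genotype groups
        spec = _spec(maf=0.4)
        gm = simulate_genotypes([spec], 30_000, seed=22)
        y, _ = simulate_phenotype(gm, None, None, [spec], avmse_model(),
                                  seed=23)
        g = gm.dosage[:, 0]
        for a, b in [(0, 1), (1, 2)]:
            assert stats.ks_2samp(y[g == a], y[g == b]).pvalue > 0.001

    def test_conditional_variance_closed_form(self):
        # Var(Y | G=g) = (beta2 + b*g)^2 q(1-q) + sigma^2 for E~Bern(q)
        b, beta2, q, sigma = -1.5, -0.8, 0.35, 1.0
        spec = _spec(beta_gxe=b)
        model = PhenotypeModel(components=((1.0, 0.0, sigma),))
        gm = simulate_genotypes([spec], 200_000, seed=24)
        rng = np.random.default_rng(25)
        e = (rng.random(200_000) < q).astype(float)
        y, _ = simulate_phenotype(gm, e, None, [spec], model, seed=26,
                                  exposure_effect=beta2)
        g = gm.dosage[:, 0]
        for gv in (0, 1, 2):
            expected = (beta2 + b * gv) ** 2 * q * (1 - q) + sigma ** 2
            observed = y[g == gv].var()
            assert observed == pytest.approx(expected, rel=0.02)

    def test_avmse_calibration_moments(self):
        x = avmse_model().sample(100_000, 42)
        assert x.mean() == pytest.approx(-0.25, abs=0.05)
        assert x.std() == pytest.approx(2.67, abs=0.05)
        assert (x <= -0.5).mean() == pytest.approx(0.34, abs=0.01)

    def test_aosw_wearer_distribution(self):
        model = aosw_model()
        rng = np.random.default_rng(43)
        lat = model.sample_latent(100_000, rng)
        ao = model.aosw_from_latent(lat, rng)
        miss = model.nonwearer_mask(lat, rng)
        aw = ao[~miss]
        assert np.all(aw == np.rint(aw))
        assert aw.min() >= 5 and aw.max() <= 70
        assert miss.mean() == pytest.approx(0.25, abs=0.01)
        assert aw.mean() == pytest.approx(31.6, abs=0.5)
        assert aw.std() == pytest.approx(17.0, abs=0.5)
        assert ((aw > 5) & (aw <= 25)).mean() == pytest.approx(0.38, abs=0.01)

    def test_nonwearers_come_from_least_myopic_tail(self):
        model = aosw_model()
        rng = np.random.default_rng(44)
        lat = model.sample_latent(50_000, rng)
        miss = model.nonwearer_mask(lat, rng)
        assert lat[miss].mean() > lat[~miss].mean() + 1.0

    def test_dominance_coding_affects_phenotype(self):
        spec = _spec(beta_marginal=1.0, coding="recessive")
        model = PhenotypeModel(components=((1.0, 0.0, 1e-6),))
        gm = simulate_genotypes([spec], 2000, seed=27)
        y, _ = simulate_phenotype(gm, None, None, [spec], model, seed=28)
        g = gm.dosage[:, 0]
        assert np.allclose(y[g == 0].mean(), y[g == 1].mean(), atol=1e-3)
        assert y[g == 2].mean() == pytest.approx(1.0, abs=1e-3)

    def test_gxg_term_and_distinctness(self):
        specs = [_spec(id="a"), _spec(id="b", pos=200)]
        gm = simulate_genotypes(specs, 500, seed=29)
        model = PhenotypeModel(components=((1.0, 0.0, 1e-6),))
        y, _ = simulate_phenotype(gm, None, None, specs, model, seed=30,
                                  gxg_pairs=[("a", "b", 0.5)])
        prod = gm.dosage[:, 0] * gm.dosage[:, 1]
        assert np.allclose(y, 0.5 * prod, atol=1e-3)
        with pytest.raises(ValueError):
            simulate_phenotype(gm, None, None, specs, model, seed=30,
                               gxg_pairs=[("a", "a", 0.5)])


class TestClassifyMyopic:
    def test_avmse_boundary_included(self):
        myo, exc = classify_myopic(avmse=np.array([-0.50, -0.49, 0.0, -3.0]))
        assert myo.tolist() == [1.0, 0.0, 0.0, 1.0]
        assert not exc.any()

    def test_aosw_open_closed_interval(self):
        myo, exc = classify_myopic(aosw=np.array([5.0, 6.0, 25.0, 26.0]))
        assert myo.tolist() == [0.0, 1.0, 1.0, 0.0]

    def test_missing_flagged_not_dropped(self):
        myo, exc = classify_myopic(aosw=np.array([np.nan, 10.0]))
        assert exc.tolist() == [True, False]
        assert np.isnan(myo[0]) and myo[1] == 1.0

    def test_exactly_one_phenotype_per_sample(self):
        with pytest.raises(ValueError):
            classify_myopic(avmse=np.array([-1.0]), aosw=np.array([10.0]))
        with pytest.raises(ValueError):
            classify_myopic()


class TestCohortSimulator:
    def test_cohort_columns_and_determinism(self):
        specs = [_spec()]
        sim = CohortSimulator(specs, n=300, stage="stage1")
        gm1, coh1 = sim.simulate(99)
        gm2, coh2 = sim.simulate(99)
        assert np.array_equal(gm1.dosage, gm2.dosage)
        pd.testing.assert_frame_equal(coh1, coh2)
        for col in ("sample_id", "avMSE", "Myopic", "UniEdu", "EduYears",
                    "age", "sex", "array", "pc1", "pc10"):
            assert col in coh1.columns

    def test_stage2_has_nonwearer_missingness(self):
        sim = CohortSimulator([_spec()], n=4000, stage="stage2",
                              prevalence=0.32)
        _, coh = sim.simulate(100)
        frac_missing = coh["AOSW"].isna().mean()
        assert 0.18 < frac_missing < 0.32
        # myopia classification consistent with the AOSW rule
        has = coh["AOSW"].notna()
        expect = ((coh.loc[has, "AOSW"] > 5) & (coh.loc[has, "AOSW"] <= 25))
        assert (coh.loc[has, "Myopic"] == expect.astype(float)).all()
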