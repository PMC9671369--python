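import numpy as np
import pytest

from vqtlscreen import CohortSimulator, VariantSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_cohort():
    """Stage-I style cohort: one GxE variant, one marginal, three null."""
    specs = [
        VariantSpec(id="gxe1", chrom="1", pos=1000, maf=0.3,
                    beta_marginal=-0.3, beta_gxe=-2.0),
        VariantSpec(id="marg1", chrom="2", pos=2000, maf=0.4,
                    beta_marginal=-0.5),
        VariantSpec(id="null1", chrom="3", pos=3000, maf=0.2),
        VariantSpec(id="null2", chrom="3", pos=9000, maf=0.35),
        VariantSpec(id="null3", chrom="4", pos=4000, maf=0.45),
    ]
    sim = CohortSimulator(specs, n=1500, stage="stage1",
                          exposure_effect=-1.2)
    gm, coh = sim.simulate(515)
    return specs, gm, coh
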