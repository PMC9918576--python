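import numpy as np
import pytest

from admixpulse.genmap import uniform_map
from admixpulse.sim import build_source_panels, one_pulse, simulate_cohort


@pytest.fixture(scope="session")
def small_panels():
    """Two FST=0.2 panels on a 4x50 cM genome, 2000 SNPs, 60 haps each."""
    gmap = uniform_map({f"chr{i + 1}": 50.0 for i in range(4)})
    pA, pB, gmap, sites = build_source_panels(
        n_snps=2000, fst=0.2, n_haps_per_source=60, seed=11, gmap=gmap)
    return pA, pB, gmap, sites


@pytest.fixture(scope="session")
def small_cohort(small_panels):
    """3:1 pulse-admixed cohort, g=25, N=100, 20 sampled individuals."""
    pA, pB, gmap, sites = small_panels
    return simulate_cohort((pA, pB), gmap, sites, one_pulse(25), N=100,
                           sample_n=20, seed=12)


@pytest.fixture(scope="session")
def lai_small(small_panels, small_cohort):
    from admixpulse.lai import infer_local_ancestry
    pA, pB, gmap, sites = small_panels
    coh = small_cohort
    return infer_local_ancestry(coh.haplotypes, pA, pB, gmap, sites,
                                hap_ids=coh.haplotype_ids)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(99)
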