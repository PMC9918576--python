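import json

import numpy as np
import pytest
from scipy import stats

from admixpulse.genmap import uniform_map
from admixpulse.sim import (PulseSchedule, Pulse, Scenario, scenario_presets,
                            build_source_panels, simulate_cohort, one_pulse,
                            two_pulse, realized_fractions, _recombine)
from admixpulse.dating import collect_tract_lengths


def hudson_fst(pA, pB, nA, nB):
    """Hudson estimator averaged over sites (ratio of averages)."""
    num = (pA - pB) ** 2 - pA * (1 - pA) / (nA - 1) - pB * (1 - pB) / (nB - 1)
    den = pA * (1 - pB) + pB * (1 - pA)
    return num.sum() / den.sum()


class TestSourcePanels:
    def test_balding_nichols_recovers_target_fst(self):
        """Mean Hudson FST across seeds matches the Balding-Nichols F.

        Expected value checked by brute-force averaging over seeds (the
        estimator is itself the oracle here: Hudson FST is consistent for
        the simulated differentiation)."""
        vals = []
        for seed in range(12):
            pA, pB, _, _ = build_source_panels(4000, 0.2, 60, seed=seed,
                                               total_cM=100.0, n_chrom=1)
            vals.append(hudson_fst(pA.allele_freqs, pB.allele_freqs, 60, 60))
        assert np.mean(vals) == pytest.approx(0.2, abs=0.02)

    def test_low_fst_limit_small_divergence(self):
        """As F -> 0 the expected |freq difference| shrinks toward the
        finite-panel sampling floor (~sqrt(2 p q / n))."""
        def mean_diff(f):
            pA, pB, _, _ = build_source_panels(3000, f, 100, seed=1,
                                               total_cM=100.0, n_chrom=1)
            return np.abs(pA.allele_freqs - pB.allele_freqs).mean()
        d001, d01, d03 = mean_diff(0.001), mean_diff(0.1), mean_diff(0.3)
        assert d001 < d01 < d03
        # sampling floor for n=100 haplotypes is ~0.05; F=0.001 adds little
        assert d001 < 0.08

    def test_determinism_same_seed(self):
        a = build_source_panels(500, 0.2, 20, seed=7, total_cM=100.0, n_chrom=2)
        b = build_source_panels(500, 0.2, 20, seed=7, total_cM=100.0, n_chrom=2)
        np.testing.assert_array_equal(a[0].haplotypes, b[0].haplotypes)
        np.testing.assert_array_equal(a[1].haplotypes, b[1].haplotypes)

    def test_invalid_fst_rejected(self):
        with pytest.raises(ValueError, match="fst"):
            build_source_panels(100, 1.5, 10, seed=0)


class TestPulseSchedule:
    def test_founding_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PulseSchedule([Pulse(10, "A", 0.6, True), Pulse(10, "B", 0.3, True)])

    def test_generations_decrease(self):
        with pytest.raises(ValueError, match="decrease"):
            PulseSchedule([Pulse(10, "A", 1.0, True), Pulse(20, "B", 0.2)])

    def test_round_trip(self):
        sched = two_pulse(100, 25)
        assert PulseSchedule.from_dict(sched.to_dict()) == sched


class TestScenarios:
    def test_five_presets_with_study_sizes(self):
        presets = scenario_presets()
        assert len(presets) == 5
        one_wave = [p for p in presets if p.name.startswith("one-wave")]
        assert {p.pulses.g_founding for p in one_wave} == {25, 50, 100}
        assert all(p.sample_n == 40 and p.N == 100 for p in presets)
        assert all(p.n_haps_per_source == 126 for p in one_wave)
        assert all(p.n_haps_per_source == 80 for p in presets
                   if p.name.startswith("two-wave"))

    def test_serialization_round_trip(self):
        for sc in scenario_presets():
            text = json.dumps(sc.to_dict())
            assert Scenario.from_dict(json.loads(text)) == sc


class TestSimulateCohort:
    def test_single_source_founding_gives_whole_chromosome_tracts(self):
        pA, pB, gmap, sites = build_source_panels(50, 0.2, 20, seed=3,
                                                  total_cM=150.0, n_chrom=3)
        sched = PulseSchedule([Pulse(10, "A", 1.0, founding=True)])
        coh = simulate_cohort((pA, pB), gmap, sites, sched, N=30, sample_n=10,
                              seed=3, with_genotypes=False)
        assert set(coh.tracts["ancestry"]) == {"A"}
        per_chrom = coh.tracts.groupby(["haplotype", "chrom"]).size()
        assert (per_chrom == 1).all()

    def test_tracts_tile_chromosomes_exactly(self, small_cohort, small_panels):
        _, _, gmap, _ = small_panels
        t = small_cohort.tracts
        spans = (t["end_cM"] - t["start_cM"]).groupby(
            [t["haplotype"], t["chrom"]]).sum()
        for (_, chrom), total in spans.items():
            assert total == pytest.approx(gmap.length_cM(chrom), abs=1e-9)

    def test_founding_fraction_recovered_across_seeds(self):
        """Mean minor fraction over seeds ~ founding m (3:1 pulse)."""
        pA, pB, gmap, sites = build_source_panels(10, 0.2, 60, seed=0,
                                                  total_cM=350.0, n_chrom=4)
        fracs = []
        for seed in range(50):
            coh = simulate_cohort((pA, pB), gmap, sites, one_pulse(10), N=50,
                                  sample_n=20, seed=500 + seed,
                                  with_genotypes=False)
            fracs.append(realized_fractions(coh.tracts, "B").mean())
        fracs = np.array(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.25) < 3 * se + 1e-12

    def test_mean_minor_tract_length_matches_pulse_theory(self):
        """Uncensored minor tract length ~ 100/(g(1-m)) cM; direct
        breakpoint bookkeeping over 25 simulated meioses is the simulator
        itself, so the closed form is checked against the realized m."""
        pA, pB, gmap, sites = build_source_panels(10, 0.2, 126, seed=0,
                                                  total_cM=3500.0, n_chrom=22)
        coh = simulate_cohort((pA, pB), gmap, sites, one_pulse(25), N=100,
                              sample_n=40, seed=42, with_genotypes=False)
        m = realized_fractions(coh.tracts, "B").mean()
        sample = collect_tract_lengths(coh.tracts, "B", gmap)
        expected = 100.0 / (25 * (1 - m))
        assert sample.uncensored.mean() == pytest.approx(expected, rel=0.12)

    def test_determinism(self):
        pA, pB, gmap, sites = build_source_panels(200, 0.2, 30, seed=5,
                                                  total_cM=100.0, n_chrom=2)
        a = simulate_cohort((pA, pB), gmap, sites, one_pulse(10), 20, 5, seed=9)
        b = simulate_cohort((pA, pB), gmap, sites, one_pulse(10), 20, 5, seed=9)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
        assert a.tracts.equals(b.tracts)

    def test_unknown_pulse_source_rejected(self):
        pA, pB, gmap, sites = build_source_panels(50, 0.2, 10, seed=1,
                                                  total_cM=100.0, n_chrom=1)
        sched = PulseSchedule([Pulse(5, "X", 1.0, founding=True)])
        with pytest.raises(ValueError, match="source"):
            simulate_cohort((pA, pB), gmap, sites, sched, 10, 5, seed=1)

    def test_alleles_copied_from_panels(self, small_cohort, small_panels):
        assert np.isin(small_cohort.haplotypes, [0, 1]).all()


def test_crossover_count_is_poisson():
    """Segment count minus one of a two-founder gamete equals the crossover
    count, which must follow Poisson(L Morgans); chi-square on 10,000 draws."""
    rng = np.random.default_rng(123)
    L = 100.0
    h1 = (np.array([L]), np.array([1], dtype=np.int64))
    h2 = (np.array([L]), np.array([2], dtype=np.int64))
    counts = np.array([len(_recombine(h1, h2, L, rng)[0]) - 1
                       for _ in range(10_000)])
    kmax = 6
    obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
    probs = stats.poisson.pmf(np.arange(kmax), 1.0)
    probs = np.append(probs, 1 - probs.sum())
    chi2, p = stats.chisquare(obs, probs * len(counts))
    assert p > 1e-3


def test_two_wave_minor_tracts_dominate_one_wave_deep():
    """Adding a recent pulse to a deep history fattens the long-tract tail:
    the two-wave (100->25) length distribution stochastically dominates the
    one-wave g=100 distribution (one-sided KS)."""
    pA, pB, gmap, sites = build_source_panels(10, 0.2, 80, seed=0,
                                              total_cM=700.0, n_chrom=8)
    one, two = [], []
    for seed in (1, 2):
        c1 = simulate_cohort((pA, pB), gmap, sites, one_pulse(100), 100, 40,
                             seed=seed, with_genotypes=False)
        c2 = simulate_cohort((pA, pB), gmap, sites, two_pulse(100, 25), 100,
                             40, seed=seed + 10, with_genotypes=False)
        one.append(collect_tract_lengths(c1.tracts, "B", gmap).lengths)
        two.append(collect_tract_lengths(c2.tracts, "B", gmap).lengths)
    one, two = np.concatenate(one), np.concatenate(two)
    # H1: the two-wave ECDF lies below the one-wave ECDF (longer tracts)
    res = stats.ks_2samp(two, one, alternative="less")
    assert res.pvalue < 1e-6
    assert two.mean() > one.mean()
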