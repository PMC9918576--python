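import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from admixpulse.genmap import uniform_map
from admixpulse.dating import (TractLengthSample, collect_tract_lengths,
                               date_from_tracts, date_from_tract_tail,
                               coancestry_curve, bootstrap_dates,
                               generations_to_year)


def tract_frame(rows):
    return pd.DataFrame(rows, columns=["haplotype", "chrom", "start_bp",
                                       "end_bp", "start_cM", "end_cM",
                                       "ancestry"])


class TestCollectTractLengths:
    def test_full_chromosome_censored(self):
        gmap = uniform_map({"chr1": 100.0})
        t = tract_frame([("i_h0", "chr1", 0, 0, 0.0, 100.0, "B")])
        s = collect_tract_lengths(t, "B", gmap)
        assert list(s.lengths) == [100.0]
        assert list(s.censored) == [True]

    def test_alternating_interior_lengths(self):
        gmap = uniform_map({"chr1": 50.0})
        rows, anc = [], ["A", "B"]
        for k in range(5):
            rows.append(("i_h0", "chr1", 0, 0, 10.0 * k, 10.0 * (k + 1),
                         anc[k % 2]))
        s = collect_tract_lengths(tract_frame(rows), "B", gmap)
        assert np.allclose(s.lengths, [10.0, 10.0])
        assert not s.censored.any()

    def test_counts_match_run_length_oracle(self, small_cohort, small_panels):
        """Tract count equals a brute-force run-length encoding of the
        per-haplotype ancestry sequence."""
        _, _, gmap, _ = small_panels
        t = small_cohort.tracts
        s = collect_tract_lengths(t, "B", gmap)
        n_runs = 0
        for (_, _), grp in t.groupby(["haplotype", "chrom"]):
            anc = grp.sort_values("start_cM")["ancestry"].to_list()
            n_runs += sum(1 for k, a in enumerate(anc)
                          if a == "B" and (k == 0 or anc[k - 1] != "B"))
        assert len(s.lengths) == n_runs


class TestDateFromTracts:
    def test_closed_form_at_exact_mean(self):
        s = TractLengthSample(np.full(100, 100.0 / (25 * 0.75)),
                              np.zeros(100, bool), "B",
                              np.repeat("i", 100))
        assert date_from_tracts(s, 0.25).g_hat == pytest.approx(25.0)

    def test_equal_lengths_closed_form(self):
        s = TractLengthSample(np.full(20, 4.0), np.zeros(20, bool), "B",
                              np.repeat("i", 20))
        assert date_from_tracts(s, 0.5).g_hat == pytest.approx(100 / (4 * 0.5))

    def test_scale_consistency(self, rng):
        lens = rng.exponential(5.0, 200)
        s1 = TractLengthSample(lens, np.zeros(200, bool), "B",
                               np.repeat("i", 200))
        s2 = TractLengthSample(2 * lens, np.zeros(200, bool), "B",
                               np.repeat("i", 200))
        g1 = date_from_tracts(s1, 0.3).g_hat
        g2 = date_from_tracts(s2, 0.3).g_hat
        assert g1 == pytest.approx(2 * g2)

    def test_censored_mle_matches_numerical_mle(self, rng):
        lam = 0.2
        lens = rng.exponential(1 / lam, 300)
        right = rng.random(300) < 0.25
        lens[right] = lens[right] * rng.random(right.sum())  # censor short
        s = TractLengthSample(lens, right, "B", np.repeat("i", 300), right)
        got = date_from_tracts(s, 0.25, censoring=True).g_hat

        def nll(l):  # censored-exponential negative log-likelihood
            return -(np.log(l) * (~right).sum() - l * lens.sum())
        lam_hat = minimize_scalar(nll, bounds=(1e-4, 10), method="bounded").x
        assert got == pytest.approx(100 * lam_hat / 0.75, rel=1e-4)

    def test_parameter_validation(self):
        s = TractLengthSample(np.ones(20), np.zeros(20, bool), "B",
                              np.repeat("i", 20))
        with pytest.raises(ValueError, match="m must"):
            date_from_tracts(s, 1.5)
        few = TractLengthSample(np.ones(5), np.zeros(5, bool), "B",
                                np.repeat("i", 5))
        with pytest.raises(ValueError, match="uncensored"):
            date_from_tracts(few, 0.25)


class TestTailDating:
    def test_recovers_recent_pulse_from_mixture(self, rng):
        """Old-pulse (g=100) + recent-pulse (g=25) exponential mixture: the
        >15 cM tail isolates the recent rate."""
        m = 0.4375
        old = rng.exponential(100 / (100 * (1 - m)), 12000)
        recent = rng.exponential(100 / (25 * (1 - m)), 8000)
        lens = np.concatenate([old, recent])
        s = TractLengthSample(lens, np.zeros(len(lens), bool), "B",
                              np.repeat("i", len(lens)))
        est = date_from_tract_tail(s, m, threshold_cM=15.0)
        assert est.g_hat == pytest.approx(25.0, rel=0.15)

    def test_too_few_tail_tracts(self):
        s = TractLengthSample(np.ones(30), np.zeros(30, bool), "B",
                              np.repeat("i", 30))
        with pytest.raises(ValueError, match="exceed"):
            date_from_tract_tail(s, 0.25, threshold_cM=15.0)


def synthetic_pulse_tracts(rng, g, m, n_haps, chrom_cM=200.0):
    """Tracts drawn from the closed-form single-pulse Markov process:
    alternating exponential runs with rates g(1-m)/100 (minor) and
    g m/100 (major)."""
    rows = []
    for h in range(n_haps):
        hap = f"i{h // 2:03d}_h{h % 2}"
        pos = 0.0
        state = rng.random() < m
        while pos < chrom_cM:
            rate = g * (1 - m) / 100 if state else g * m / 100
            seg = rng.exponential(1 / rate)
            end = min(pos + seg, chrom_cM)
            rows.append((hap, "chr1", 0, 0, pos, end, "B" if state else "A"))
            pos = end
            state = not state
    return tract_frame(rows)


class TestCoancestryCurve:
    def test_analytic_single_pulse_decay(self, rng):
        """cov(d) = m(1-m) e^{-g d/100}: feeding tracts drawn from the
        closed form at g=25 must recover g within 10%."""
        gmap = uniform_map({"chr1": 200.0})
        tracts = synthetic_pulse_tracts(rng, g=25, m=0.3, n_haps=80)
        res = coancestry_curve(tracts, gmap, "B")
        assert res.estimate.g_hat == pytest.approx(25.0, rel=0.10)
        assert res.estimate.details["converged"]

    def test_flat_curve_in_old_admixture_limit(self, rng):
        """With decay far finer than the grid the curve is flat: the fitted
        model varies negligibly across the fitting window."""
        gmap = uniform_map({"chr1": 200.0})
        tracts = synthetic_pulse_tracts(rng, g=2000, m=0.3, n_haps=40)
        res = coancestry_curve(tracts, gmap, "B")
        A, g = res.estimate.details["A"], res.estimate.g_hat
        variation = abs(A * (np.exp(-g * 0.5 / 100.0)
                             - np.exp(-g * 10.0 / 100.0)))
        assert variation < 0.01
        assert np.abs(res.curve["cov"][res.curve["d_cM"] > 1.0]).max() < 0.01

    def test_needs_two_individuals(self):
        gmap = uniform_map({"chr1": 100.0})
        t = tract_frame([("i0_h0", "chr1", 0, 0, 0.0, 100.0, "B"),
                         ("i0_h1", "chr1", 0, 0, 0.0, 100.0, "A")])
        with pytest.raises(ValueError, match=">=2"):
            coancestry_curve(t, gmap, "B")


class TestBootstrap:
    def test_identical_individuals_give_degenerate_draws(self):
        gmap = uniform_map({"chr1": 60.0})
        rows = []
        for i in range(5):
            for h in (0, 1):
                hap = f"i{i}_h{h}"
                rows += [(hap, "chr1", 0, 0, 0.0, 10.0, "B"),
                         (hap, "chr1", 0, 0, 10.0, 40.0, "A"),
                         (hap, "chr1", 0, 0, 40.0, 50.0, "B"),
                         (hap, "chr1", 0, 0, 50.0, 60.0, "A")]
        with pytest.warns(UserWarning):
            est = bootstrap_dates(tract_frame(rows), gmap, "B",
                                  method="tract_mle", B=40, seed=1)
        assert np.allclose(est.bootstrap_draws, est.g_hat)
        assert est.ci[0] == pytest.approx(est.ci[1])

    def test_seed_reproducibility_and_ci(self, small_cohort, small_panels):
        _, _, gmap, _ = small_panels
        a = bootstrap_dates(small_cohort.tracts, gmap, "B", B=60, seed=4)
        b = bootstrap_dates(small_cohort.tracts, gmap, "B", B=60, seed=4)
        np.testing.assert_array_equal(a.bootstrap_draws, b.bootstrap_draws)
        assert a.ci[0] <= a.g_hat <= a.ci[1]

    def test_interval_shrinks_with_cohort_size(self, rng):
        gmap = uniform_map({"chr1": 200.0})
        big = synthetic_pulse_tracts(rng, g=25, m=0.3, n_haps=60)
        haps_small = [f"i{h // 2:03d}_h{h % 2}" for h in range(20)]
        small = big[big["haplotype"].isin(haps_small)]
        e_small = bootstrap_dates(small, gmap, "B", B=150, seed=2)
        e_big = bootstrap_dates(big, gmap, "B", B=150, seed=2)
        assert (e_big.ci[1] - e_big.ci[0]) < (e_small.ci[1] - e_small.ci[0])

    def test_coancestry_bootstrap_runs(self, small_cohort, small_panels):
        _, _, gmap, _ = small_panels
        est = bootstrap_dates(small_cohort.tracts, gmap, "B",
                              method="coancestry", B=60, seed=3)
        assert len(est.bootstrap_draws) == 60
        assert est.ci[0] < est.ci[1]


class TestCalendar:
    @pytest.mark.parametrize("g,ref,year,label", [
        (16, 2000, 1520, "sixteenth century CE"),
        (25, 2000, 1250, "thirteenth century CE"),
        (0, 1995, 1995, "twentieth century CE"),
        # astronomical year -100 is 101 BCE, hence second century BCE
        (70, 2000, -100, "second century BCE"),
    ])
    def test_known_conversions(self, g, ref, year, label):
        y, lab = generations_to_year(g, reference_year=ref)
        assert y == year
        assert lab == label

    def test_negative_g_rejected(self):
        with pytest.raises(ValueError):
            generations_to_year(-1, reference_year=2000)
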