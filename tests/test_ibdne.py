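import numpy as np
import pandas as pd
import pytest

from admixpulse.genmap import uniform_map
from admixpulse.sim import build_source_panels
from admixpulse.ibdne import (detect_ibd, merge_gaps, label_ancestry,
                              estimate_ne, cohort_ne_suite)


@pytest.fixture(scope="module")
def dense_sites():
    gmap = uniform_map({"chr1": 50.0})
    pA, pB, gmap, sites = build_source_panels(2500, 0.2, 40, seed=21,
                                              gmap=gmap)
    return pA, gmap, sites


def tract_frame(rows):
    return pd.DataFrame(rows, columns=["haplotype", "chrom", "start_bp",
                                       "end_bp", "start_cM", "end_cM",
                                       "ancestry"])


class TestDetect:
    def test_identical_haplotypes_full_chromosome(self, dense_sites):
        pA, gmap, sites = dense_sites
        X = np.vstack([pA.haplotypes[0], pA.haplotypes[0]])
        segs = detect_ibd(X, gmap, sites, ["a_h0", "b_h0"], min_cM=2.0)
        assert len(segs) == 1
        assert segs["length_cM"].iloc[0] > 49.0

    def test_planted_blocks_recovered_with_tight_boundaries(self, dense_sites):
        """Plant 5 cM copied blocks between otherwise-unrelated haplotypes;
        boundary error < 0.5 cM."""
        pA, gmap, sites = dense_sites
        cm = sites["cM"].to_numpy()
        rng = np.random.default_rng(3)
        hits, errs = 0, []
        for k in range(10):
            i, j = rng.choice(40, 2, replace=False)
            X = np.vstack([pA.haplotypes[i], pA.haplotypes[j]])
            start = rng.uniform(5, 40)
            block = (cm >= start) & (cm < start + 5)
            X[1, block] = X[0, block]
            segs = detect_ibd(X, gmap, sites, ["a_h0", "b_h0"], min_cM=2.0)
            if len(segs):
                best = segs.iloc[segs["length_cM"].idxmax()]
                hits += 1
                errs.append(abs(best["start_cM"] - start))
                errs.append(abs(best["end_cM"] - (start + 5)))
        assert hits == 10
        assert max(errs) < 0.5

    def test_min_length_contract_and_symmetry(self, dense_sites):
        pA, gmap, sites = dense_sites
        X = pA.haplotypes[:8]
        ids = [f"s{i}_h0" for i in range(8)]
        segs = detect_ibd(X, gmap, sites, ids, min_cM=2.0)
        assert (segs["length_cM"] >= 2.0).all()
        segs_rev = detect_ibd(X[::-1], gmap, sites, ids[::-1], min_cM=2.0)
        key = ["chrom", "start_cM", "end_cM"]
        a = segs[key + ["length_cM"]].sort_values(key).reset_index(drop=True)
        b = segs_rev[key + ["length_cM"]].sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_within_individual_pairs_skipped(self, dense_sites):
        pA, gmap, sites = dense_sites
        X = np.vstack([pA.haplotypes[0], pA.haplotypes[0]])
        segs = detect_ibd(X, gmap, sites, ["a_h0", "a_h1"], min_cM=2.0)
        assert len(segs) == 0

    def test_bad_threshold(self, dense_sites):
        pA, gmap, sites = dense_sites
        with pytest.raises(ValueError):
            detect_ibd(pA.haplotypes[:2], gmap, sites, ["a_h0", "b_h0"],
                       min_cM=0.0)


class TestMergeGaps:
    def build_pair_with_gap(self, dense_sites, gap_cM, n_inconsistent):
        """Two segment calls separated by a constructed gap containing a
        chosen number of IBD-inconsistent sites (segment table built
        directly; merge_gaps accepts calls from any detector)."""
        pA, gmap, sites = dense_sites
        cm = sites["cM"].to_numpy()
        rng = np.random.default_rng(9)
        X = np.vstack([pA.haplotypes[3], pA.haplotypes[17].copy()])
        X[1] = X[0]                          # fully consistent pair
        gap = (cm > 20) & (cm < 20 + gap_cM)
        gap_idx = np.flatnonzero(gap)
        flip = gap_idx[rng.choice(len(gap_idx), n_inconsistent, replace=False)]
        X[1, flip] = 1 - X[1, flip]          # plant gap inconsistencies
        segs = seg_frame([("a_h0", "b_h0", "chr1", 0, 0, 10.0, 20.0),
                          ("a_h0", "b_h0", "chr1", 0, 0, 20.0 + gap_cM,
                           30.0 + gap_cM)])
        return X, segs, gmap, sites

    @pytest.mark.parametrize("gap,n_bad,should_merge", [
        (0.5, 0, True),    # short gap, consistent -> merge
        (0.5, 1, True),    # short gap, 1 inconsistency -> merge
        (0.7, 0, False),   # gap too long
        (0.5, 2, False),   # too many inconsistencies
    ])
    def test_merge_rule_boundaries(self, dense_sites, gap, n_bad, should_merge):
        X, segs, gmap, sites = self.build_pair_with_gap(dense_sites, gap, n_bad)
        merged = merge_gaps(segs, X, sites, ["a_h0", "b_h0"], gmap)
        assert len(merged) == (1 if should_merge else 2)
        if should_merge:
            assert merged["length_cM"].iloc[0] == pytest.approx(20.0 + gap)

    def test_idempotent(self, dense_sites):
        X, segs, gmap, sites = self.build_pair_with_gap(dense_sites, 0.5, 1)
        m1 = merge_gaps(segs, X, sites, ["a_h0", "b_h0"], gmap)
        m2 = merge_gaps(m1, X, sites, ["a_h0", "b_h0"], gmap)
        pd.testing.assert_frame_equal(m1.reset_index(drop=True),
                                      m2.reset_index(drop=True))


def seg_frame(rows):
    df = pd.DataFrame(rows, columns=["hap1", "hap2", "chrom", "start_bp",
                                     "end_bp", "start_cM", "end_cM"])
    df["length_cM"] = df["end_cM"] - df["start_cM"]
    return df


class TestLabelAncestry:
    def full_tracts(self, anc_by_hap, L=50.0):
        rows = []
        for hap, anc in anc_by_hap.items():
            if isinstance(anc, str):
                rows.append((hap, "chr1", 0, 0, 0.0, L, anc))
            else:
                rows += [(hap, "chr1", 0, 0, s, e, a) for s, e, a in anc]
        return tract_frame(rows)

    def test_pure_and_half_proportions(self):
        segs = seg_frame([("a_h0", "b_h0", "chr1", 0, 0, 10.0, 20.0)])
        t = self.full_tracts({"a_h0": "B", "b_h0": "B"})
        lab = label_ancestry(segs, t, "B", seed=0)
        assert lab["ancestry_proportion"].iloc[0] == pytest.approx(1.0)
        assert lab["assigned_ancestry"].iloc[0] == "B"
        t2 = self.full_tracts({"a_h0": "B", "b_h0": "A"})
        lab2 = label_ancestry(segs, t2, "B", seed=0)
        assert lab2["ancestry_proportion"].iloc[0] == pytest.approx(0.5)

    def test_assignment_frequency_matches_proportion(self):
        """Over 10,000 seeded draws at proportion 0.3 the assignment
        frequency is 0.30 +- 0.01."""
        segs = seg_frame([("a_h0", "b_h0", "chr1", 0, 0, 10.0, 20.0)] * 10_000)
        t = self.full_tracts({"a_h0": [(0.0, 30.0, "B"), (30.0, 50.0, "A")],
                              "b_h0": "A"})
        # hap1 span 10-20 fully B -> 1.0; hap2 -> 0.0... need 0.3:
        t = self.full_tracts({"a_h0": [(0.0, 16.0, "B"), (16.0, 50.0, "A")],
                              "b_h0": "A"})
        lab = label_ancestry(segs, t, "B", seed=42)
        assert lab["ancestry_proportion"].iloc[0] == pytest.approx(0.3)
        freq = (lab["assigned_ancestry"] == "B").mean()
        assert freq == pytest.approx(0.30, abs=0.01)

    def test_coordinates_conserved(self):
        segs = seg_frame([("a_h0", "b_h0", "chr1", 0, 0, 5.0, 17.0),
                          ("a_h0", "b_h0", "chr1", 0, 0, 20.0, 30.0)])
        t = self.full_tracts({"a_h0": "B", "b_h0": "A"})
        lab = label_ancestry(segs, t, "B", seed=1)
        assert lab["length_cM"].sum() == pytest.approx(segs["length_cM"].sum())

    def test_uncovered_span_raises(self):
        segs = seg_frame([("a_h0", "b_h0", "chr1", 0, 0, 40.0, 60.0)])
        t = self.full_tracts({"a_h0": "B", "b_h0": "A"}, L=50.0)
        with pytest.raises(ValueError, match="outside"):
            label_ancestry(segs, t, "B", seed=0)


class TestEstimateNe:
    def fake_segments(self, rng, n, chroms, lam=0.7):
        rows = []
        for _ in range(n):
            c = rng.choice(chroms)
            length = rng.exponential(1 / lam) + 1.0
            start = rng.uniform(0, 40)
            rows.append(("a_h0", "b_h0", c, 0, 0, start, start + length))
        return seg_frame(rows)

    def test_doubling_counts_halves_ne(self, rng):
        """With every length bin populated the inversion is exactly linear
        in the counts, so doubling them halves Ne in each bin."""
        gmap = uniform_map({f"chr{i}": 50.0 for i in range(1, 5)})
        segs = self.fake_segments(rng, 2500, list(gmap.chromosomes))
        kw = dict(min_cM=1.0, max_cM=8.0, bootstrap_reps=10,
                  pedigree_depth=60, seed=0)
        t1 = estimate_ne(segs, 40, gmap, **kw)
        t2 = estimate_ne(pd.concat([segs, segs]), 40, gmap, **kw)
        ratio = t2.table["ne"] / t1.table["ne"]
        np.testing.assert_allclose(ratio.dropna(), 0.5, rtol=1e-6)

    def test_ancestry_mode_pair_bookkeeping(self, rng):
        """Haplotype-equivalents: n_pairs = n_eff(n_eff-1)/2 with
        n_eff = n_haplotypes * ancestry fraction."""
        gmap = uniform_map({"chr1": 50.0})
        segs = self.fake_segments(rng, 50, ["chr1"])
        segs["assigned_ancestry"] = "B"
        traj = estimate_ne(segs, 80, gmap, mode="ancestry", ancestry="B",
                           ancestry_fraction=0.25, min_cM=1.0,
                           bootstrap_reps=5, seed=0)
        n_eff = 80 * 0.25
        assert traj.n_pairs == pytest.approx(n_eff * (n_eff - 1) / 2)

    def test_no_segments_censored(self):
        gmap = uniform_map({"chr1": 50.0})
        segs = seg_frame([])
        traj = estimate_ne(segs, 10, gmap, min_cM=1.0, bootstrap_reps=5, seed=0)
        assert traj.table["censored"].all()

    def test_validation(self, rng):
        gmap = uniform_map({"chr1": 50.0})
        segs = self.fake_segments(rng, 10, ["chr1"])
        with pytest.raises(ValueError, match=">=4"):
            estimate_ne(segs, 3, gmap)
        with pytest.raises(ValueError, match="ancestry"):
            estimate_ne(segs, 10, gmap, mode="ancestry", ancestry="B")


class TestCohortSuite:
    def test_five_runs_plus_reference_and_exclusion(self, rng):
        gmap = uniform_map({f"chr{i}": 50.0 for i in range(1, 5)})
        rows = []
        inds = [f"i{k}" for k in range(10)]
        for _ in range(300):
            a, b = rng.choice(10, 2, replace=False)
            c = rng.choice(gmap.chromosomes)
            start = rng.uniform(0, 40)
            rows.append((f"{inds[a]}_h0", f"{inds[b]}_h0", c, 0, 0, start,
                         start + rng.exponential(1.5) + 1.0))
        segs = seg_frame(rows)
        rngp = np.random.default_rng(0)
        segs["ancestry_proportion"] = rngp.random(len(segs))
        segs["assigned_ancestry"] = np.where(segs["ancestry_proportion"] > 0.5,
                                             "B", "non-B")
        props = pd.Series(rngp.uniform(0, 1, 10), index=inds)
        ref = self_ref = segs.iloc[:50].copy()
        suite = cohort_ne_suite(segs, props, 20, gmap, "B",
                                reference_segments=ref,
                                n_reference_haplotypes=20,
                                min_cM=1.0, bootstrap_reps=5,
                                pedigree_depth=60, seed=0)
        assert set(suite) == {"all", "B", "non-B", "B-excl", "non-B-excl",
                              "reference"}
        excluded = set(props.index[props > 0.5])
        assert excluded  # the fixture has high-B individuals to exclude
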