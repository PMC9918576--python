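"""IBD segment detection, gap merging, ancestry labeling, and a moment-based
ancestry-specific effective-population-size estimator.

Identity-by-descent segments between phased haplotypes of different
individuals are detected as maximal runs of allele identity (an identity-run
scanner; adequate when genotype error is negligible, as in simulated data).
Nearby segments of a pair are merged across short, nearly consistent gaps.
Each segment is assigned an ancestry proportion from the local-ancestry
tracts of its two haplotypes and then stochastically labeled with one
ancestry — an unbiased accounting of per-ancestry IBD length.

Ne estimation inverts the standard length-TMRCA relation: a pair coalescing
t generations ago shares segments whose lengths are ~Exp(2t/100 per cM), so
the expected number of segments with length in [a, b) per pair is
sum over chromosomes of L_c * r * (e^{-r a} - e^{-r b}) with r = 2t/100,
and E[TMRCA | length l] ~ 100/(2l).  Under piecewise-constant Ne the
coalescence probability per generation is 1/(2N), so for a generation bin
[t1, t2) mapped to its length bin, N̂ = n_pairs * sum_t f(t) / (2 * count).
Confidence intervals come from resampling chromosomes with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .genmap import GeneticMap

SEGMENT_COLUMNS = ["hap1", "hap2", "chrom", "start_bp", "end_bp",
                   "start_cM", "end_cM", "length_cM"]

DEFAULT_GEN_BINS = ((4, 10), (10, 20), (20, 30), (30, 50))


@dataclass
class NeTrajectory:
    """Per-generation-bin Ne estimates with bootstrap percentile bounds."""

    table: pd.DataFrame   # gen_lo, gen_hi, gen_mid, ne, lo2_5, hi97_5, n_segments
    mode: str
    n_pairs: float


def _individual(hap_id: str) -> str:
    return hap_id.rsplit("_h", 1)[0]


def detect_ibd(haplotypes: np.ndarray, gmap: GeneticMap, sites: pd.DataFrame,
               hap_ids: list[str], min_cM: float = 2.0,
               mismatch_rate: float = 0.0) -> pd.DataFrame:
    """Scan all cross-individual haplotype pairs for shared segments.

    A segment is a maximal run of allele identity spanning at least
    `min_cM`; with `mismatch_rate` > 0, runs may be chained across isolated
    mismatches as long as the mismatch density stays at or below
    `mismatch_rate` per cM.  Within-individual (homozygosity-by-descent)
    pairs are not scanned.
    """
    if min_cM <= 0:
        raise ValueError("min_cM must be positive")
    X = np.asarray(haplotypes, dtype=np.int8)
    chrom_arr = sites["chrom"].to_numpy()
    cm_arr = sites["cM"].to_numpy()
    chrom_idx = {c: np.flatnonzero(chrom_arr == c) for c in pd.unique(chrom_arr)}
    rows = []
    H = X.shape[0]
    for i in range(H):
        for j in range(i + 1, H):
            if _individual(hap_ids[i]) == _individual(hap_ids[j]):
                continue
            for chrom, idx in chrom_idx.items():
                cm = cm_arr[idx]
                mism = np.flatnonzero(X[i, idx] != X[j, idx])
                for s, e in _identity_runs(mism, len(idx), cm, mismatch_rate):
                    length = cm[e] - cm[s]
                    if length >= min_cM:
                        s_bp, e_bp = gmap.cM_to_bp(chrom, [cm[s], cm[e]])
                        rows.append((hap_ids[i], hap_ids[j], chrom,
                                     int(s_bp), int(e_bp),
                                     float(cm[s]), float(cm[e]), float(length)))
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def _identity_runs(mismatch_idx: np.ndarray, n_sites: int, cm: np.ndarray,
                   mismatch_rate: float):
    """Yield (first, last site index) of maximal identity runs, optionally
    chaining across mismatches up to `mismatch_rate` per cM."""
    bounds = np.concatenate(([-1], mismatch_idx, [n_sites]))
    runs = [(int(bounds[k] + 1), int(bounds[k + 1] - 1))
            for k in range(len(bounds) - 1)
            if bounds[k + 1] - bounds[k] > 1]
    if mismatch_rate <= 0 or len(runs) < 2:
        yield from runs
        return
    merged = [list(runs[0])]
    n_mism = [0]
    for s, e in runs[1:]:
        cand_mism = n_mism[-1] + 1
        span = cm[e] - cm[merged[-1][0]]
        if span > 0 and cand_mism / span <= mismatch_rate:
            merged[-1][1] = e
            n_mism[-1] = cand_mism
        else:
            merged.append([s, e])
            n_mism.append(0)
    yield from ((s, e) for s, e in merged)


def merge_gaps(segments: pd.DataFrame, haplotypes: np.ndarray,
               sites: pd.DataFrame, hap_ids: list[str], gmap: GeneticMap,
               max_gap_cM: float = 0.6, max_inconsistent: int = 1) -> pd.DataFrame:
    """Merge adjacent segments of a pair across short, consistent gaps.

    Two segments are merged when the gap between them is shorter than
    `max_gap_cM` (strict) and the gap contains at most `max_inconsistent`
    sites whose alleles contradict IBD between the two haplotypes.
    Idempotent: re-running on merged output changes nothing.
    """
    if segments.empty:
        return segments.copy()
    X = np.asarray(haplotypes, dtype=np.int8)
    hap_pos = {h: k for k, h in enumerate(hap_ids)}
    chrom_arr = sites["chrom"].to_numpy()
    cm_arr = sites["cM"].to_numpy()
    rows = []
    for (h1, h2, chrom), grp in segments.groupby(["hap1", "hap2", "chrom"],
                                                 sort=False):
        grp = grp.sort_values("start_cM")
        idx = np.flatnonzero(chrom_arr == chrom)
        cm = cm_arr[idx]
        diff = X[hap_pos[h1], idx] != X[hap_pos[h2], idx]
        cur = grp.iloc[0].to_dict()
        for _, nxt in grp.iloc[1:].iterrows():
            gap = nxt["start_cM"] - cur["end_cM"]
            in_gap = (cm > cur["end_cM"]) & (cm < nxt["start_cM"])
            n_bad = int(diff[in_gap].sum())
            if gap < max_gap_cM and n_bad <= max_inconsistent:
                cur["end_cM"] = nxt["end_cM"]
                cur["end_bp"] = nxt["end_bp"]
            else:
                rows.append(cur)
                cur = nxt.to_dict()
        rows.append(cur)
    out = pd.DataFrame(rows)[SEGMENT_COLUMNS[:-1] + ["length_cM"]]
    out["length_cM"] = out["end_cM"] - out["start_cM"]
    return out.reset_index(drop=True)


def label_ancestry(segments: pd.DataFrame, tracts: pd.DataFrame,
                   ancestry: str, seed: int = 0) -> pd.DataFrame:
    """Assign each segment an ancestry proportion and a stochastic label.

    The proportion is the mean, over the segment's two haplotypes, of the
    fraction of the segment's cM span lying in `ancestry` tracts; the label
    is drawn Bernoulli(proportion), which makes the total labeled IBD length
    per ancestry unbiased.  A dedicated seed stream keeps ancestry-unaware
    results unaffected by labeling.
    """
    out = segments.copy()
    if out.empty:
        out["ancestry_proportion"] = pd.Series(dtype=float)
        out["assigned_ancestry"] = pd.Series(dtype=object)
        return out
    grouped = {k: g.sort_values("start_cM") for k, g in
               tracts.groupby(["haplotype", "chrom"], sort=False)}

    def span_fraction(hap, chrom, lo, hi):
        grp = grouped.get((hap, chrom))
        if grp is None:
            raise ValueError(f"no tracts covering {hap} on {chrom}")
        s = grp["start_cM"].to_numpy()
        e = grp["end_cM"].to_numpy()
        if lo < s[0] - 1e-9 or hi > e[-1] + 1e-9:
            raise ValueError(f"segment [{lo}, {hi}] outside tracts of {hap}")
        overlap = np.maximum(0.0, np.minimum(e, hi) - np.maximum(s, lo))
        anc = (grp["ancestry"].to_numpy() == ancestry)
        return overlap[anc].sum() / max(hi - lo, 1e-12)

    props = np.array([
        0.5 * (span_fraction(r.hap1, r.chrom, r.start_cM, r.end_cM)
               + span_fraction(r.hap2, r.chrom, r.start_cM, r.end_cM))
        for r in out.itertuples()
    ])
    rng = np.random.default_rng(seed)
    out["ancestry_proportion"] = props
    out["assigned_ancestry"] = np.where(rng.random(len(out)) < props,
                                        ancestry, f"non-{ancestry}")
    return out


# ---------------------------------------------------------------------------
# Ne estimation
# ---------------------------------------------------------------------------

def _length_bins(min_cM: float, max_cM: float, n_bins: int = 12):
    """Log-spaced segment-length bins between the detection threshold and
    the longest informative length."""
    edges = np.geomspace(min_cM, max_cM, n_bins + 1)
    return list(zip(edges[:-1], edges[1:]))


def _design_matrix(gen_bins, len_bins, chrom_lengths, pedigree_depth):
    """A[c, j, i]: expected segments per coalesced-pair-probability unit from
    generation bin i into length bin j on chromosome c.

    The coalescence probability is treated as a constant x_i per generation
    within bin i (survival ignored, valid for t << 2N); a pair coalescing t
    generations ago yields L*r*(e^{-ra} - e^{-rb}) expected segments with
    length in [a, b), r = 2t/100 per cM.
    """
    chroms = list(chrom_lengths)
    A = np.zeros((len(chroms), len(len_bins), len(gen_bins)))
    for i, (t1, t2) in enumerate(gen_bins):
        for t in range(int(t1), int(min(t2, pedigree_depth + 1))):
            r = 2.0 * t / 100.0
            for j, (a, b) in enumerate(len_bins):
                val = r * (np.exp(-r * a) - np.exp(-r * b))
                for c_i, c in enumerate(chroms):
                    A[c_i, j, i] += chrom_lengths[c] * val
    return A


def estimate_ne(segments: pd.DataFrame, n_haplotypes: int, gmap: GeneticMap,
                mode: str = "all", ancestry: str | None = None,
                ancestry_fraction: float | None = None,
                gen_bins=DEFAULT_GEN_BINS, min_cM: float = 2.0,
                max_cM: float = 50.0, pedigree_depth: int | None = None,
                smooth: float = 1.0, bootstrap_reps: int = 80,
                seed: int = 0) -> NeTrajectory:
    """Piecewise-constant Ne by non-negative linear inversion of binned
    IBD segment counts.

    The genome is binned by segment length (bin edges at the images
    100/(2t) of the generation-bin edges, i.e. E[TMRCA | length l] ~
    100/(2l)); expected counts are linear in the per-generation coalescence
    probabilities x_i = 1/(2 Ne_i) of each generation bin, with every
    cross-bin contribution retained in the design matrix.  x >= 0 is solved
    by non-negative least squares with Poisson (sqrt-count) weighting, and
    Ne_i = 1/(2 x_i).  Nuisance generation bins [1, first) and
    [last, pedigree_depth] absorb coalescences outside the reported range;
    `pedigree_depth` truncates the model when the cohort has a known founding
    depth (simulated cohorts).  `mode` selects all segments or only those
    assigned to `ancestry`; ancestry modes adjust the pair count to the
    ancestry's haplotype-equivalents (n_haplotypes * ancestry_fraction).
    A generation bin with no informative counts is reported censored (NaN).
    Percentile intervals come from resampling chromosomes with replacement.
    """
    if n_haplotypes < 4:
        raise ValueError("need >=4 haplotypes")
    if min_cM <= 0:
        raise ValueError("min_cM must be positive")
    if mode == "all":
        segs = segments
        n_eff = float(n_haplotypes)
    else:
        if ancestry is None or "assigned_ancestry" not in segments:
            raise ValueError("ancestry mode needs labeled segments and an ancestry")
        segs = segments[segments["assigned_ancestry"] == ancestry]
        if ancestry_fraction is None:
            raise ValueError("ancestry mode needs ancestry_fraction")
        n_eff = n_haplotypes * ancestry_fraction
    n_pairs = n_eff * (n_eff - 1) / 2.0
    chrom_lengths = {c: gmap.length_cM(c) for c in gmap.chromosomes}
    chroms = list(chrom_lengths)

    t_lo = int(min(t1 for t1, _ in gen_bins))
    t_hi = int(max(t2 for _, t2 in gen_bins))
    if pedigree_depth is None:
        pedigree_depth = 4 * t_hi
    all_bins = []
    if t_lo > 1:
        all_bins.append((1, t_lo))
    all_bins += [tuple(b) for b in gen_bins]
    if pedigree_depth + 1 > t_hi:
        all_bins.append((t_hi, pedigree_depth + 1))
    report = [all_bins.index(tuple(b)) for b in gen_bins]

    len_bins = _length_bins(min_cM, max_cM)
    A = _design_matrix(all_bins, len_bins, chrom_lengths, pedigree_depth)
    counts = np.zeros((len(chroms), len(len_bins)))
    if len(segs):
        for c_i, c in enumerate(chroms):
            in_c = segs["chrom"] == c
            lens = segs.loc[in_c, "length_cM"].to_numpy()
            for j, (a, b) in enumerate(len_bins):
                counts[c_i, j] = ((lens >= a) & (lens < b)).sum()

    def solve(chrom_pick):
        Ac = A[chrom_pick].sum(axis=0) * n_pairs
        y = counts[chrom_pick].sum(axis=0)
        w = 1.0 / np.sqrt(np.maximum(y, 1.0))
        Aw = Ac * w[:, None]
        yw = y * w
        # first-difference smoothing on the coalescence intensities
        # (the inversion is otherwise ill-conditioned: neighbouring
        # generation bins produce nearly collinear length profiles)
        nb = Ac.shape[1]
        lam = smooth * np.linalg.norm(Aw) / max(np.sqrt(nb - 1), 1.0)
        D = np.zeros((nb - 1, nb))
        for i in range(nb - 1):
            D[i, i], D[i, i + 1] = lam, -lam
        try:
            x, _ = nnls(np.vstack([Aw, D]), np.concatenate([yw, np.zeros(nb - 1)]))
        except RuntimeError:
            return np.full(len(all_bins), np.nan)
        with np.errstate(divide="ignore"):
            return np.where(x > 0, 1.0 / (2.0 * x), np.nan)

    all_idx = np.arange(len(chroms))
    ne_full = solve(all_idx)
    rng = np.random.default_rng(seed)
    boots = np.full((bootstrap_reps, len(all_bins)), np.nan)
    for rep in range(bootstrap_reps):
        boots[rep] = solve(rng.integers(0, len(chroms), len(chroms)))
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lo = np.nanpercentile(boots, 2.5, axis=0)
        hi = np.nanpercentile(boots, 97.5, axis=0)

    rows = []
    for k, i in enumerate(report):
        t1, t2 = gen_bins[k]
        a = max(100.0 / (2.0 * t2), min_cM)
        b = 100.0 / (2.0 * t1)
        if len(segs):
            lens_all = segs["length_cM"].to_numpy()
            n_seg = int(((lens_all >= a) & (lens_all < b)).sum())
        else:
            n_seg = 0
        rows.append({"gen_lo": t1, "gen_hi": t2,
                     "gen_mid": float(np.sqrt(t1 * t2)),
                     "length_lo_cM": a, "length_hi_cM": b,
                     "n_segments": n_seg,
                     "ne": ne_full[i], "lo2_5": lo[i], "hi97_5": hi[i],
                     "censored": bool(np.isnan(ne_full[i]))})
    table = pd.DataFrame(rows)
    label = mode if mode == "all" else f"{ancestry}"
    return NeTrajectory(table, label, n_pairs)


def cohort_ne_suite(segments_labeled: pd.DataFrame, proportions: pd.Series,
                    n_haplotypes: int, gmap: GeneticMap, ancestry: str,
                    other: str | None = None, exclude_over: float = 0.5,
                    reference_segments: pd.DataFrame | None = None,
                    n_reference_haplotypes: int | None = None,
                    **kwargs) -> dict[str, NeTrajectory]:
    """The five per-cohort Ne runs, plus an optional reference-panel run.

    Runs: ancestry-unaware; each ancestry on all individuals; each ancestry
    excluding individuals whose target-ancestry proportion exceeds
    `exclude_over`.  `proportions` are per-individual target-ancestry
    fractions.  When reference-panel segments are supplied, a sixth,
    reference-only trajectory is added.
    """
    other = other if other is not None else f"non-{ancestry}"
    frac = float(proportions.mean())
    out = {
        "all": estimate_ne(segments_labeled, n_haplotypes, gmap, mode="all",
                           **kwargs),
        ancestry: estimate_ne(segments_labeled, n_haplotypes, gmap,
                              mode="ancestry", ancestry=ancestry,
                              ancestry_fraction=frac, **kwargs),
        other: estimate_ne(segments_labeled, n_haplotypes, gmap,
                           mode="ancestry", ancestry=other,
                           ancestry_fraction=1.0 - frac, **kwargs),
    }
    keep_ind = set(proportions.index[proportions <= exclude_over])
    if keep_ind:
        sub = segments_labeled[
            segments_labeled["hap1"].map(_individual).isin(keep_ind)
            & segments_labeled["hap2"].map(_individual).isin(keep_ind)]
        n_sub = 2 * len(keep_ind)
        frac_sub = float(proportions[proportions <= exclude_over].mean())
        if n_sub >= 4:
            out[f"{ancestry}-excl"] = estimate_ne(
                sub, n_sub, gmap, mode="ancestry", ancestry=ancestry,
                ancestry_fraction=frac_sub, **kwargs)
            out[f"{other}-excl"] = estimate_ne(
                sub, n_sub, gmap, mode="ancestry", ancestry=other,
                ancestry_fraction=1.0 - frac_sub, **kwargs)
    else:
        import warnings
        warnings.warn("all individuals excluded; ancestry-specific subset skipped")
    if reference_segments is not None:
        out["reference"] = estimate_ne(reference_segments,
                                       n_reference_haplotypes, gmap,
                                       mode="all", **kwargs)
    return out
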