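"""Two-ancestry local ancestry inference on phased haplotypes.

A transparent two-state haplotype HMM assigns each site of a phased query
haplotype to one of two source ancestries.  Emissions are the source-panel
allele frequencies with an error floor; transitions over a genetic distance
d cM follow the pulse-admixture expectation 1 - exp(-g d / 100), scaled by
the prior ancestry fractions.  The module also provides ancestry masking
(the input to ancestry-specific PCA), per-individual genome-wide ancestry
proportions, and a cross-method concordance check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genmap import GeneticMap
from .sim import SourcePanel, realized_fractions

MISSING = np.int8(-1)


@dataclass
class LAIResult:
    """Viterbi tracts plus per-site posterior probability of each ancestry."""

    tracts: pd.DataFrame          # haplotype, chrom, start/end bp+cM, ancestry, posterior
    posterior: np.ndarray         # (n_haps, n_sites) P(state = second source)
    sources: tuple[str, str]
    prior: tuple[float, float]
    hap_ids: list[str]


def _transition_blocks(d_cM: np.ndarray, g: float, prior: np.ndarray):
    """Per-interval 2x2 transition matrices for the pulse-admixture HMM."""
    stay = np.exp(-g * d_cM / 100.0)                      # (S-1,)
    T = np.empty((len(d_cM), 2, 2))
    for j in range(2):
        for k in range(2):
            T[:, j, k] = (1.0 - stay) * prior[k] + (stay if j == k else 0.0)
    return T


def _emissions(X: np.ndarray, freqs: list[np.ndarray], error_rate: float):
    """P(observed allele | state) per site; missing alleles emit 1."""
    E = np.empty((2, *X.shape))
    for s in range(2):
        f = np.clip(freqs[s], error_rate, 1.0 - error_rate)
        E[s] = np.where(X == 1, f, 1.0 - f)
        E[s][X == MISSING] = 1.0
    return E


def infer_local_ancestry(
    haplotypes: np.ndarray,
    panelA: SourcePanel,
    panelB: SourcePanel,
    gmap: GeneticMap,
    sites: pd.DataFrame,
    generations_prior: float = 25.0,
    error_rate: float = 0.01,
    min_tract_cM: float = 0.5,
    hap_ids: list[str] | None = None,
    em_rounds: int = 1,
) -> LAIResult:
    """Viterbi tracts and posteriors for each phased query haplotype.

    The prior ancestry fraction starts at (0.5, 0.5) and is re-estimated
    once from the mean posterior (one EM-style round) before the final pass,
    so no external global-ancestry estimate is needed.  Tract calls shorter
    than `min_tract_cM` are merged into the flanking tract with the higher
    mean posterior to suppress switch noise.
    """
    X = np.asarray(haplotypes, dtype=np.int8)
    if X.shape[1] != len(sites):
        raise ValueError("haplotypes and site table disagree on the site count")
    for p in (panelA, panelB):
        if p.haplotypes.shape[1] != len(sites):
            raise ValueError(f"panel {p.source_id} does not share the query site set")
    if hap_ids is None:
        hap_ids = [f"hap{i}" for i in range(X.shape[0])]
    sources = (panelA.source_id, panelB.source_id)
    freqs = [panelA.allele_freqs, panelB.allele_freqs]

    chrom_arr = sites["chrom"].to_numpy()
    cm_arr = sites["cM"].to_numpy()
    chroms = [c for c in gmap.chromosomes if (chrom_arr == c).any()]

    prior = np.array([0.5, 0.5])
    for _ in range(max(em_rounds, 0)):
        post = _posteriors(X, freqs, chrom_arr, cm_arr, chroms,
                           generations_prior, error_rate, prior)
        pB = float(np.mean(post))
        prior = np.clip(np.array([1.0 - pB, pB]), 1e-3, 1.0 - 1e-3)
    post = _posteriors(X, freqs, chrom_arr, cm_arr, chroms,
                       generations_prior, error_rate, prior)
    paths = _viterbi(X, freqs, chrom_arr, cm_arr, chroms,
                     generations_prior, error_rate, prior)
    tracts = _paths_to_tracts(paths, post, sites, gmap, chroms, hap_ids,
                              sources, min_tract_cM)
    return LAIResult(tracts, post, sources, (float(prior[0]), float(prior[1])), hap_ids)


def _posteriors(X, freqs, chrom_arr, cm_arr, chroms, g, err, prior):
    post = np.empty(X.shape)
    for chrom in chroms:
        idx = np.flatnonzero(chrom_arr == chrom)
        E = _emissions(X[:, idx], freqs_slice(freqs, idx), err)  # (2, H, S)
        T = _transition_blocks(np.diff(cm_arr[idx]), g, prior)
        post[:, idx] = _forward_backward(E, T, prior)
    return post


def freqs_slice(freqs, idx):
    return [f[idx] for f in freqs]


def _forward_backward(E, T, prior):
    """Scaled forward-backward; returns P(state=1 | data) per hap and site."""
    _, H, S = E.shape
    alpha = np.empty((S, H, 2))
    scale = np.empty((S, H))
    a = prior[None, :] * E[:, :, 0].T
    scale[0] = a.sum(axis=1)
    alpha[0] = a / scale[0][:, None]
    for t in range(1, S):
        a = alpha[t - 1] @ T[t - 1] * E[:, :, t].T
        scale[t] = a.sum(axis=1)
        alpha[t] = a / scale[t][:, None]
    beta = np.ones((H, 2))
    post = np.empty((S, H))
    post[S - 1] = alpha[S - 1][:, 1]
    for t in range(S - 2, -1, -1):
        beta = (beta * E[:, :, t + 1].T) @ T[t].T
        beta /= beta.sum(axis=1, keepdims=True)
        g = alpha[t] * beta
        post[t] = (g[:, 1] / g.sum(axis=1))
    return post.T


def _viterbi(X, freqs, chrom_arr, cm_arr, chroms, g, err, prior):
    paths = np.empty(X.shape, dtype=np.int8)
    for chrom in chroms:
        idx = np.flatnonzero(chrom_arr == chrom)
        E = _emissions(X[:, idx], freqs_slice(freqs, idx), err)  # (2, H, S)
        logT = np.log(_transition_blocks(np.diff(cm_arr[idx]), g, prior))
        logE = np.log(np.maximum(E, 1e-300))
        H, S = E.shape[1], E.shape[2]
        delta = np.log(prior)[None, :] + logE[:, :, 0].T
        psi = np.empty((S, H, 2), dtype=np.int8)
        for t in range(1, S):
            cand = delta[:, :, None] + logT[t - 1][None, :, :]  # (H, from, to)
            psi[t] = cand.argmax(axis=1)
            delta = cand.max(axis=1) + logE[:, :, t].T
        path = np.empty((S, H), dtype=np.int8)
        path[S - 1] = delta.argmax(axis=1)
        for t in range(S - 2, -1, -1):
            path[t] = np.take_along_axis(psi[t + 1], path[t + 1][:, None], axis=1)[:, 0]
        paths[:, idx] = path.T
    return paths


def _paths_to_tracts(paths, post, sites, gmap, chroms, hap_ids, sources,
                     min_tract_cM) -> pd.DataFrame:
    chrom_arr = sites["chrom"].to_numpy()
    cm_arr = sites["cM"].to_numpy()
    rows = []
    for h, hap_id in enumerate(hap_ids):
        for chrom in chroms:
            idx = np.flatnonzero(chrom_arr == chrom)
            states = paths[h, idx]
            cm = cm_arr[idx]
            pB = post[h, idx]
            lo = float(gmap.chrom_cM[chrom][0])
            hi = float(gmap.chrom_cM[chrom][-1])
            # run-length encode, boundaries midway between flanking sites
            change = np.flatnonzero(states[1:] != states[:-1])
            bounds = [lo] + [float((cm[i] + cm[i + 1]) / 2) for i in change] + [hi]
            seg_states = states[np.concatenate(([0], change + 1))]
            seg_slices = np.split(np.arange(len(idx)), change + 1)
            tracts = [
                {"start": bounds[k], "end": bounds[k + 1], "state": int(seg_states[k]),
                 "post": float(np.mean(np.where(seg_states[k] == 1,
                                                pB[seg_slices[k]],
                                                1.0 - pB[seg_slices[k]])))}
                for k in range(len(seg_states))
            ]
            tracts = _merge_short(tracts, min_tract_cM)
            for t in tracts:
                s_bp, e_bp = gmap.cM_to_bp(chrom, [t["start"], t["end"]])
                rows.append((hap_id, chrom, int(s_bp), int(e_bp),
                             t["start"], t["end"], sources[t["state"]], t["post"]))
    return pd.DataFrame(rows, columns=["haplotype", "chrom", "start_bp", "end_bp",
                                       "start_cM", "end_cM", "ancestry", "posterior"])


def _merge_short(tracts: list[dict], min_cM: float) -> list[dict]:
    """Absorb tracts shorter than min_cM into the higher-posterior neighbour."""
    changed = True
    while changed and len(tracts) > 1:
        changed = False
        for k, t in enumerate(tracts):
            if t["end"] - t["start"] >= min_cM:
                continue
            nbrs = [j for j in (k - 1, k + 1) if 0 <= j < len(tracts)]
            j = max(nbrs, key=lambda j: tracts[j]["post"])
            absorber = tracts[j]
            absorber["start"] = min(absorber["start"], t["start"])
            absorber["end"] = max(absorber["end"], t["end"])
            del tracts[k]
            changed = True
            break
    # merge adjacent same-state tracts produced by the absorption
    out = [tracts[0]]
    for t in tracts[1:]:
        if t["state"] == out[-1]["state"]:
            w0 = out[-1]["end"] - out[-1]["start"]
            w1 = t["end"] - t["start"]
            out[-1]["post"] = (out[-1]["post"] * w0 + t["post"] * w1) / (w0 + w1)
            out[-1]["end"] = t["end"]
        else:
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# masking, proportions, concordance
# ---------------------------------------------------------------------------

@dataclass
class MaskedHaplotypeMatrix:
    """Haplotype alleles with non-target-ancestry sites set to missing."""

    alleles: np.ndarray           # (n_haps, n_sites) int8, -1 = missing
    target: str
    hap_ids: list[str]
    retained: np.ndarray = field(default=None)  # per-hap non-missing count

    def __post_init__(self) -> None:
        if self.retained is None:
            self.retained = (self.alleles != MISSING).sum(axis=1)


def site_ancestry(tracts: pd.DataFrame, sites: pd.DataFrame,
                  hap_ids: list[str]) -> np.ndarray:
    """Ancestry label of every site of every haplotype by tract lookup."""
    chrom_arr = sites["chrom"].to_numpy()
    cm_arr = sites["cM"].to_numpy()
    out = np.full((len(hap_ids), len(sites)), None, dtype=object)
    grouped = dict(tuple(tracts.groupby(["haplotype", "chrom"], sort=False)))
    for h, hap in enumerate(hap_ids):
        for chrom in sites["chrom"].unique():
            idx = np.flatnonzero(chrom_arr == chrom)
            grp = grouped.get((hap, chrom))
            if grp is None:
                raise ValueError(f"no tracts for haplotype {hap} on {chrom}")
            grp = grp.sort_values("start_cM")
            ends = grp["end_cM"].to_numpy()
            anc = grp["ancestry"].to_numpy()
            k = np.searchsorted(ends, cm_arr[idx], side="right")
            if np.any(k >= len(ends)):
                bad = cm_arr[idx][k >= len(ends)]
                raise ValueError(f"site cM {bad[:3]} outside tracts on {chrom}")
            out[h, idx] = anc[k]
    return out


def mask_by_ancestry(haplotypes: np.ndarray, tracts: pd.DataFrame, target: str,
                     sites: pd.DataFrame, hap_ids: list[str]) -> MaskedHaplotypeMatrix:
    """Keep alleles inside target-ancestry tracts; set the rest to missing."""
    X = np.asarray(haplotypes, dtype=np.int8).copy()
    anc = site_ancestry(tracts, sites, hap_ids)
    X[anc != target] = MISSING
    return MaskedHaplotypeMatrix(X, target, list(hap_ids))


def individual_proportions(tracts: pd.DataFrame, ancestry: str) -> pd.Series:
    """Genome-wide fraction of `ancestry` per individual, cM-weighted over
    both haplotypes and all chromosomes."""
    return realized_fractions(tracts, ancestry)


@dataclass
class ConcordanceResult:
    r2: float
    slope: float
    intercept: float
    paired_test_p: float
    n: int


def proportion_concordance(tableA: pd.Series, tableB: pd.Series) -> ConcordanceResult:
    """Least-squares fit of B on A plus a paired two-sided t-test.

    Used to compare per-individual ancestry proportions from two inference
    routes; high r^2 and a flat paired difference indicate concordance.
    """
    a, b = tableA.align(tableB, join="inner")
    if len(a) < 3:
        raise ValueError("concordance needs >=3 shared individuals")
    if np.std(a.to_numpy()) == 0:
        raise ValueError("degenerate input: zero variance in tableA")
    fit = stats.linregress(a.to_numpy(), b.to_numpy())
    diff = (a - b).to_numpy()
    if np.std(diff) == 0:  # degenerate paired test: constant difference
        p = 1.0 if np.allclose(diff, 0) else 0.0
    else:
        p = float(stats.ttest_rel(a, b).pvalue)
    return ConcordanceResult(float(fit.rvalue ** 2), float(fit.slope),
                             float(fit.intercept), p, len(a))

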