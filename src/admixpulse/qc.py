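"""Variant/sample quality control, kinship pruning and LD pruning.

Genotypes are dosage matrices of shape (n_samples, n_sites) with values
0/1/2 and -1 for missing.  The filter chain mirrors standard array-QC
practice: per-site missingness, Hardy-Weinberg exact test, minor allele
frequency, duplicate site ids, then per-sample missingness.  Relatedness
uses the KING-robust within-pair kinship estimator with greedy pruning at
the conventional third-degree cutoff (0.0442).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

KING_THIRD_DEGREE = 0.0442


@dataclass
class FilterReport:
    """Counts of sites/samples removed per rule; removed + retained = input."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "n_retained": self.n_retained,
                "removed": dict(self.removed), "thresholds": dict(self.thresholds)}


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg p-value from genotype counts.

    Conditional on the allele counts, the heterozygote count follows the
    exact distribution P(h) ∝ 2^h / (a! h! c!); the p-value sums the
    probabilities of all heterozygote counts no more probable than the
    observed one (the standard exact formulation, no mid-p).
    """
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    n_r = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # rare allele count
    n_c = 2 * n - n_r
    hs = np.arange(n_r % 2, n_r + 1, 2)
    # log P(h) up to the common normalising constant
    logp = (hs * np.log(2.0) - gammaln((n_r - hs) / 2 + 1)
            - gammaln(hs + 1) - gammaln((n_c - hs) / 2 + 1))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = n_Aa
    return float(p[p <= p[hs == obs][0] * (1 + 1e-12)].sum())


def _site_stats(G: np.ndarray):
    miss = G < 0
    n_obs = (~miss).sum(axis=0)
    n_AA = (G == 0).sum(axis=0)
    n_Aa = (G == 1).sum(axis=0)
    n_aa = (G == 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = (2 * n_aa + n_Aa) / (2 * n_obs)
    maf = np.minimum(freq, 1 - freq)
    return miss.mean(axis=0), maf, n_AA, n_Aa, n_aa


def filter_variants(
    G: np.ndarray,
    miss_max: float = 0.05,
    hwe_p_min: float = 1e-5,
    maf_min: float = 0.05,
    site_ids=None,
) -> tuple[np.ndarray, np.ndarray, FilterReport]:
    """Remove sites failing missingness, HWE, MAF or duplicate-id rules.

    Returns (filtered genotypes, kept site indices, report).  A removed site
    is attributed to the first rule it violates, in the order missingness,
    HWE, MAF, duplicate id, so the per-rule counts sum to the removed total.
    Site order is preserved.
    """
    G = np.asarray(G)
    n_sites = G.shape[1]
    miss_frac, maf, n_AA, n_Aa, n_aa = _site_stats(G)
    bad_miss = miss_frac > miss_max
    hwe_p = np.ones(n_sites)
    for j in np.flatnonzero(~bad_miss):
        hwe_p[j] = hwe_exact_p(int(n_AA[j]), int(n_Aa[j]), int(n_aa[j]))
    bad_hwe = (hwe_p < hwe_p_min) & ~bad_miss
    bad_maf = (np.nan_to_num(maf) < maf_min) & ~bad_miss & ~bad_hwe
    bad_dup = np.zeros(n_sites, dtype=bool)
    if site_ids is not None:
        ids = pd.Series(site_ids)
        bad_dup = ids.duplicated(keep=False).to_numpy() & ~bad_miss & ~bad_hwe & ~bad_maf
    keep = ~(bad_miss | bad_hwe | bad_maf | bad_dup)
    report = FilterReport(
        n_input=n_sites,
        removed={"missingness": int(bad_miss.sum()), "hwe": int(bad_hwe.sum()),
                 "maf": int(bad_maf.sum()), "duplicate_id": int(bad_dup.sum())},
        thresholds={"miss_max": miss_max, "hwe_p_min": hwe_p_min, "maf_min": maf_min},
    )
    return G[:, keep], np.flatnonzero(keep), report


def filter_samples(G: np.ndarray, miss_max: float = 0.10
                   ) -> tuple[np.ndarray, np.ndarray, FilterReport]:
    """Remove samples with missingness above `miss_max` (strict >)."""
    G = np.asarray(G)
    miss_frac = (G < 0).mean(axis=1)
    keep = miss_frac <= miss_max
    report = FilterReport(
        n_input=G.shape[0],
        removed={"missingness": int((~keep).sum())},
        thresholds={"miss_max": miss_max},
    )
    return G[keep], np.flatnonzero(keep), report


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipResult:
    kinship: pd.DataFrame     # symmetric sample x sample phi matrix
    pruned: list              # sample ids removed by greedy pruning
    kept: list
    threshold: float


def king_kinship(G: np.ndarray, sample_ids=None) -> pd.DataFrame:
    """KING-robust pairwise kinship from identity-state counts.

    phi_ij = (N_het,het - 2 N_opposite_hom) / (N_het_i + N_het_j), counted
    over sites where both samples are genotyped.  Duplicates give ~0.5,
    parent-offspring ~0.25, unrelated ~0.  Invariant under allele-label
    flips at any site.
    """
    G = np.asarray(G)
    if G.shape[0] < 2:
        raise ValueError("kinship needs >=2 samples")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(G.shape[0])]
    H = (G == 1).astype(np.float64)
    A0 = (G == 0).astype(np.float64)
    A2 = (G == 2).astype(np.float64)
    M = (G >= 0).astype(np.float64)
    n_hethet = H @ H.T
    n_opp = A0 @ A2.T + A2 @ A0.T
    het_in_overlap = H @ M.T          # het count of i over sites typed in j
    denom = het_in_overlap + het_in_overlap.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (n_hethet - 2.0 * n_opp) / denom
    phi = np.clip(np.nan_to_num(phi, nan=0.0), -0.5, 0.5)
    np.fill_diagonal(phi, 0.5)
    return pd.DataFrame(phi, index=sample_ids, columns=sample_ids)


def kinship_prune(G: np.ndarray, threshold: float = KING_THIRD_DEGREE,
                  sample_ids=None) -> KinshipResult:
    """Greedily remove samples until no pair has kinship >= threshold.

    Each round removes the sample with the most violating pairs (ties broken
    by sample order), which removes few samples in practice.
    """
    phi_df = king_kinship(G, sample_ids)
    ids = list(phi_df.index)
    phi = phi_df.to_numpy().copy()
    np.fill_diagonal(phi, 0.0)
    active = np.ones(len(ids), dtype=bool)
    pruned = []
    while True:
        viol = (phi >= threshold) & active[:, None] & active[None, :]
        counts = viol.sum(axis=1)
        if counts.max() == 0:
            break
        worst = int(np.argmax(counts))  # argmax takes the first max: id-order ties
        active[worst] = False
        pruned.append(ids[worst])
    kept = [ids[i] for i in np.flatnonzero(active)]
    return KinshipResult(phi_df, pruned, kept, threshold)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x >= 0) & (y >= 0)
    if ok.sum() < 3:
        return 0.0
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    if xs.std() == 0 or ys.std() == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_prune(G: np.ndarray, positions: np.ndarray, window_kb: float = 50,
             step_snps: int = 5, r2_max: float = 0.5) -> np.ndarray:
    """Greedy windowed LD pruning; returns indices of retained sites.

    Windows of `window_kb` advance by `step_snps` sites; within a window the
    later member of any retained pair with r^2 > r2_max is dropped.
    Deterministic: the earlier site always wins.
    """
    G = np.asarray(G)
    positions = np.asarray(positions)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    n = G.shape[1]
    keep = np.ones(n, dtype=bool)
    win_bp = window_kb * 1000.0
    for start in range(0, n, step_snps):
        if not keep[start:].any():
            break
        end = int(np.searchsorted(positions, positions[start] + win_bp, side="right"))
        idx = [j for j in range(start, end) if keep[j]]
        for a in range(len(idx)):
            if not keep[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if not keep[idx[b]]:
                    continue
                if _pairwise_r2(G[:, idx[a]], G[:, idx[b]]) > r2_max:
                    keep[idx[b]] = False
    return np.flatnonzero(keep)
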