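"""Ancestry-specific PCA: joint embedding of masked query haplotypes with
reference haplotypes by classical MDS on Euclidean allele distances.

Query haplotypes are first masked so that only sites inside tracts of the
target ancestry remain (see :mod:`admixpulse.lai`); they are then embedded
together with candidate source-population haplotypes.  Because masked sites
are missing not at random by position but (approximately) at random with
respect to the reference panels, pairwise distances are computed over
jointly observed sites and rescaled to the full site count:

    d(i, j) = sqrt( S(i, j) * M / C(i, j) )

with S the sum of squared 0/1 allele differences over the C jointly
non-missing sites and M the total (post-pruning) site count.  Classical MDS
(double centering + top eigenvectors) of this distance matrix is the
ancestry-specific PC space; source attribution reads off which reference
cluster the masked haplotypes fall nearest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lai import MaskedHaplotypeMatrix, MISSING
from . import qc


@dataclass
class ASPCAEmbedding:
    coords: pd.DataFrame          # haplotype, role, population, PC1..PCk
    eigenvalues: np.ndarray
    n_sites: int

    def pcs(self) -> np.ndarray:
        cols = [c for c in self.coords.columns if c.startswith("PC")]
        return self.coords[cols].to_numpy()


@dataclass
class DistanceSummary:
    """Mean embedding distance from each query haplotype to each reference
    population (all distances >= 0)."""

    distances: pd.DataFrame       # query haplotype x reference population


def threshold_select(proportions: pd.Series, theta: float) -> list:
    """Individuals whose target-ancestry proportion is >= theta (inclusive)."""
    if not (0.0 <= theta <= 1.0):
        raise ValueError("theta must be in [0, 1]")
    return list(proportions.index[proportions >= theta])


def missing_aware_distances(X: np.ndarray,
                            allow_missing_pairs: bool = False) -> np.ndarray:
    """Pairwise rescaled Euclidean distances on 0/1 alleles with missing.

    Pairs with no jointly observed sites are an error unless
    `allow_missing_pairs`, in which case their distance is imputed from the
    cohort-average mismatch rate (needed when jointly embedding
    complementary maskings of the same individuals).
    """
    X = np.asarray(X)
    W = (X != MISSING).astype(np.float64)
    V = np.where(X == 1, 1.0, 0.0) * W
    C = W @ W.T
    if np.any(C == 0) and not allow_missing_pairs:
        i, j = np.argwhere(C == 0)[0]
        raise ValueError(f"haplotype pair ({i}, {j}) has no jointly observed sites")
    S = V @ W.T + W @ V.T - 2.0 * V @ V.T
    M = X.shape[1]
    np.fill_diagonal(S, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        D2 = S * M / C
    if np.any(C == 0):
        off = ~np.eye(len(X), dtype=bool)
        ok = (C > 0) & off
        D2[(C == 0) & off] = (S[ok] / C[ok]).mean() * M
        np.fill_diagonal(D2, 0.0)
    return np.sqrt(np.maximum(D2, 0.0))


def classical_mds(D: np.ndarray, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS: coordinates from the top-k eigenpairs of
    the double-centered squared-distance matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.maximum(evals[:k], 0.0)
    coords = evecs[:, :k] * np.sqrt(pos)[None, :]
    return coords, evals


def embed(masked: MaskedHaplotypeMatrix, references: dict[str, np.ndarray],
          sites: pd.DataFrame | None = None, n_components: int = 2,
          ld_prune: bool = True, prune_params: dict | None = None,
          allow_missing_pairs: bool = False) -> ASPCAEmbedding:
    """Joint classical-MDS embedding of masked queries and reference haplotypes.

    `references` maps population label -> (n_haps, n_sites) 0/1 matrix on
    the same site set as the masked queries.  Sites are LD-pruned on the
    pooled reference haplotypes first (same windowed r^2 rule as the global
    PCA) when `ld_prune` is set and a site table with bp positions is given.
    """
    ref_pops = list(references)
    ref_mats = [np.asarray(references[p], dtype=np.int8) for p in ref_pops]
    for p, m in zip(ref_pops, ref_mats):
        if m.shape[1] != masked.alleles.shape[1]:
            raise ValueError(f"reference {p!r} does not share the query site set")

    keep = np.arange(masked.alleles.shape[1])
    if ld_prune and sites is not None:
        params = {"window_kb": 50, "step_snps": 5, "r2_max": 0.5}
        params.update(prune_params or {})
        pooled = np.vstack(ref_mats)
        pos = sites["pos_bp"].to_numpy()
        keep = np.concatenate([
            idx[qc.ld_prune(pooled[:, idx], pos[idx], **params)]
            for idx in _chrom_blocks(sites)
        ])

    X = np.vstack([masked.alleles[:, keep]] + [m[:, keep] for m in ref_mats])
    D = missing_aware_distances(X, allow_missing_pairs)
    coords, evals = classical_mds(D, n_components)

    hap_ids = list(masked.hap_ids)
    roles = ["query"] * len(hap_ids)
    pops = ["query"] * len(hap_ids)
    for p, m in zip(ref_pops, ref_mats):
        hap_ids += [f"{p}_h{i}" for i in range(m.shape[0])]
        roles += ["reference"] * m.shape[0]
        pops += [p] * m.shape[0]
    df = pd.DataFrame({"haplotype": hap_ids, "role": roles, "population": pops})
    for c in range(n_components):
        df[f"PC{c + 1}"] = coords[:, c]
    return ASPCAEmbedding(df, evals, len(keep))


def _chrom_blocks(sites: pd.DataFrame):
    chrom = sites["chrom"].to_numpy()
    for c in pd.unique(chrom):
        yield np.flatnonzero(chrom == c)


def sanity_joint_embedding(
    masked_target: MaskedHaplotypeMatrix,
    masked_other: MaskedHaplotypeMatrix,
    references: dict[str, np.ndarray],
    expected: dict[str, str],
    sites: pd.DataFrame | None = None,
    **kwargs,
) -> tuple[ASPCAEmbedding, pd.DataFrame]:
    """Embed both maskings of the same individuals with all references and
    check each masked haplotype lands nearest the reference centroid of its
    own target ancestry (`expected` maps reference population -> the masking
    target it represents).  Haplotypes with zero retained sites are dropped
    with a warning.  Returns the embedding and a per-haplotype assignment
    table with a `correct` column.
    """
    parts, labels, targets = [], [], []
    for mh in (masked_target, masked_other):
        nonempty = mh.retained > 0
        if not nonempty.all():
            warnings.warn(f"excluding {int((~nonempty).sum())} haplotype(s) with "
                          f"no sites retained for target {mh.target!r}")
        parts.append(MaskedHaplotypeMatrix(
            mh.alleles[nonempty], mh.target,
            [h for h, ok in zip(mh.hap_ids, nonempty) if ok]))
        labels += [f"{h}|{mh.target}" for h, ok in zip(mh.hap_ids, nonempty) if ok]
        targets += [mh.target] * int(nonempty.sum())

    combined = MaskedHaplotypeMatrix(
        np.vstack([p.alleles for p in parts]), "joint", labels)
    emb = embed(combined, references, sites=sites, allow_missing_pairs=True,
                **kwargs)

    pcs = emb.pcs()
    is_query = (emb.coords["role"] == "query").to_numpy()
    centroids = {p: pcs[(emb.coords["population"] == p).to_numpy()].mean(axis=0)
                 for p in references}
    rows = []
    for i, (lab, tgt) in enumerate(zip(labels, targets)):
        dists = {p: float(np.linalg.norm(pcs[i] - c)) for p, c in centroids.items()}
        nearest = min(dists, key=dists.get)
        rows.append((lab, tgt, nearest, expected.get(nearest), dists[nearest]))
    table = pd.DataFrame(rows, columns=["haplotype", "target", "nearest_population",
                                        "nearest_ancestry", "distance"])
    table["correct"] = table["target"] == table["nearest_ancestry"]
    return emb, table


def population_distances(embedding: ASPCAEmbedding) -> DistanceSummary:
    """Mean embedding distance from every query haplotype to every reference
    population (averaged over that population's haplotypes)."""
    pcs = embedding.pcs()
    role = embedding.coords["role"].to_numpy()
    pop = embedding.coords["population"].to_numpy()
    q_idx = np.flatnonzero(role == "query")
    ref_pops = pd.unique(pop[role == "reference"])
    if len(q_idx) == 0 or len(ref_pops) == 0:
        raise ValueError("embedding needs >=1 query and >=1 reference population")
    out = {}
    for p in ref_pops:
        r = pcs[pop == p]
        diff = pcs[q_idx][:, None, :] - r[None, :, :]
        out[p] = np.sqrt((diff ** 2).sum(axis=2)).mean(axis=1)
    df = pd.DataFrame(out, index=embedding.coords["haplotype"].to_numpy()[q_idx])
    return DistanceSummary(df)


def group_distance_test(summary: DistanceSummary, popX: str, popY: str
                        ) -> tuple[float, float, str]:
    """Welch two-sided t-test of per-haplotype mean distances to popX vs popY.

    Returns (t, p, direction) where direction names the closer population
    (the sign of the mean difference).
    """
    dx = summary.distances[popX].to_numpy()
    dy = summary.distances[popY].to_numpy()
    if len(dx) < 2:
        raise ValueError("need >=2 query haplotypes")
    if np.std(dx) == 0 and np.std(dy) == 0:
        if np.allclose(dx, dy):
            return 0.0, 1.0, "tie"
        raise ValueError("degenerate input: zero variance in both arms")
    t, p = stats.ttest_ind(dx, dy, equal_var=False)
    direction = "tie" if np.isclose(dx.mean(), dy.mean()) else \
        (popX if dx.mean() < dy.mean() else popY)
    return float(t), float(p), direction
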