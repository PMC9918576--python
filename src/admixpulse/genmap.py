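"""Genetic maps: piecewise-linear bp <-> cM interpolation per chromosome.

A :class:`GeneticMap` stores, for every chromosome, an ordered list of
(physical position in bp, genetic position in cM) anchor points.  Physical
positions must be strictly increasing and genetic positions non-decreasing;
interpolation is defined between the first and the last anchor.  Synthetic
maps default to a uniform 1 cM/Mb recombination rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Approximate sex-averaged genetic lengths (cM) of the 22 human autosomes,
# used only to give synthetic genomes realistic relative chromosome sizes.
HUMAN_AUTOSOME_CM = np.array(
    [286.0, 269.0, 223.0, 214.0, 204.0, 192.0, 187.0, 168.0, 166.0, 181.0,
     158.0, 175.0, 126.0, 120.0, 142.0, 134.0, 128.0, 117.0, 107.0, 108.0,
     62.0, 74.0]
)


@dataclass
class GeneticMap:
    """Per-chromosome bp/cM anchors with linear interpolation."""

    chrom_bp: dict[str, np.ndarray]
    chrom_cM: dict[str, np.ndarray]
    name: str = "map"

    def __post_init__(self) -> None:
        for chrom in self.chrom_bp:
            bp = np.asarray(self.chrom_bp[chrom], dtype=np.int64)
            cm = np.asarray(self.chrom_cM[chrom], dtype=float)
            if bp.shape != cm.shape or bp.ndim != 1 or bp.size < 2:
                raise ValueError(f"{chrom}: need >=2 paired (bp, cM) anchors")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"{chrom}: physical positions must be strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"{chrom}: genetic positions must be non-decreasing")
            self.chrom_bp[chrom] = bp
            self.chrom_cM[chrom] = cm

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_bp)

    def length_cM(self, chrom: str) -> float:
        cm = self.chrom_cM[chrom]
        return float(cm[-1] - cm[0])

    def total_cM(self) -> float:
        return float(sum(self.length_cM(c) for c in self.chromosomes))

    def bp_to_cM(self, chrom: str, bp) -> np.ndarray:
        bp = np.asarray(bp, dtype=float)
        anchors_bp = self.chrom_bp[chrom]
        if np.any(bp < anchors_bp[0]) or np.any(bp > anchors_bp[-1]):
            raise ValueError(f"{chrom}: bp outside the mapped interval")
        return np.interp(bp, anchors_bp, self.chrom_cM[chrom])

    def cM_to_bp(self, chrom: str, cm) -> np.ndarray:
        cm = np.asarray(cm, dtype=float)
        anchors_cm = self.chrom_cM[chrom]
        if np.any(cm < anchors_cm[0]) or np.any(cm > anchors_cm[-1]):
            raise ValueError(f"{chrom}: cM outside the mapped interval")
        out = np.interp(cm, anchors_cm, self.chrom_bp[chrom].astype(float))
        return np.rint(out).astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chromosomes:
            for bp, cm in zip(self.chrom_bp[chrom], self.chrom_cM[chrom]):
                rows.append((chrom, f"{chrom}:{bp}", float(cm), int(bp)))
        return pd.DataFrame(rows, columns=["chrom", "snp_id", "cM", "bp"])

    def write(self, path) -> None:
        """Write a 4-column (chrom, snp_id, cM, bp) text map."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        chrom_bp, chrom_cm = {}, {}
        for chrom, grp in df.groupby("chrom", sort=False):
            chrom_bp[chrom] = grp["bp"].to_numpy(dtype=np.int64)
            chrom_cm[chrom] = grp["cM"].to_numpy(dtype=float)
        return cls(chrom_bp, chrom_cm)


def uniform_map(chrom_lengths_cM: dict[str, float], cM_per_Mb: float = 1.0) -> GeneticMap:
    """Uniform-rate map; two anchors per chromosome, starting at 0 cM / bp 1."""
    chrom_bp, chrom_cm = {}, {}
    for chrom, L in chrom_lengths_cM.items():
        end_bp = int(round(L / cM_per_Mb * 1e6))
        chrom_bp[chrom] = np.array([1, end_bp], dtype=np.int64)
        chrom_cm[chrom] = np.array([0.0, float(L)])
    return GeneticMap(chrom_bp, chrom_cm)


def default_genome(total_cM: float = 3500.0, n_chrom: int = 22) -> dict[str, float]:
    """Chromosome lengths (cM) shaped like the human autosomes, rescaled."""
    base = HUMAN_AUTOSOME_CM[:n_chrom] if n_chrom <= 22 else np.resize(HUMAN_AUTOSOME_CM, n_chrom)
    lengths = base / base.sum() * total_cM
    return {f"chr{i + 1}": float(L) for i, L in enumerate(lengths)}
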