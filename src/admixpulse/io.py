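"""Reading and writing cohort artifacts.

Formats: phased VCF v4.2 (GT with "|", per-site genetic position in the
INFO CM field), truth/inferred tract TSV (0-based half-open bp plus cM
columns), 4-column genetic-map text, and JSON metadata.  `write_cohort` /
`read_cohort` round-trip a :class:`~admixpulse.sim.SimulatedCohort` exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genmap import GeneticMap
from .sim import SimulatedCohort

TRACT_HEADER = ("# ancestry tracts; bp coordinates 0-based half-open; "
                "cM coordinates authoritative for lengths\n")


def write_vcf(haplotypes: np.ndarray, sites: pd.DataFrame,
              sample_ids: list[str], path) -> None:
    """Write phased haplotypes as VCF v4.2 (GT separator '|')."""
    X = np.asarray(haplotypes)
    if X.shape[0] != 2 * len(sample_ids):
        raise ValueError("need two haplotypes per sample")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=String,Description='
                 '"Genetic position in cM">\n')  # String keeps full precision
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sites["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for j, row in enumerate(sites.itertuples()):
            gts = "\t".join(
                f"{_allele(X[2 * i, j])}|{_allele(X[2 * i + 1, j])}"
                for i in range(len(sample_ids)))
            fh.write(f"{row.chrom}\t{row.pos_bp}\t{row.id}\tA\tG\t.\t.\t"
                     f"CM={row.cM:.10g}\tGT\t{gts}\n")


def _allele(a) -> str:
    return "." if a < 0 else str(int(a))


def read_vcf(path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read a phased VCF into (haplotypes, sites, sample ids)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    haps, rows = [], []
    for var in vcf:
        cm = var.INFO.get("CM")
        rows.append((var.CHROM, var.POS, float(cm) if cm is not None else np.nan,
                     var.ID))
        col = np.full(2 * len(samples), -1, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            col[2 * i] = gt[0] if gt[0] >= 0 else -1
            col[2 * i + 1] = gt[1] if gt[1] >= 0 else -1
        haps.append(col)
    sites = pd.DataFrame(rows, columns=["chrom", "pos_bp", "cM", "id"])
    X = np.array(haps, dtype=np.int8).T if haps else np.empty((2 * len(samples), 0),
                                                              dtype=np.int8)
    return X, sites, samples


def write_tracts(tracts: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(TRACT_HEADER)
        tracts.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_tracts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       dtype={"chrom": str, "haplotype": str})


def write_cohort(cohort: SimulatedCohort, out_prefix) -> dict[str, Path]:
    """Write VCF + tract TSV + map + metadata; returns the file paths."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": prefix.with_suffix(".vcf"),
        "tracts": Path(str(prefix) + ".tracts.tsv"),
        "map": Path(str(prefix) + ".map.tsv"),
        "meta": Path(str(prefix) + ".meta.json"),
    }
    if cohort.haplotypes is None:
        raise ValueError("cohort has no genotypes to write")
    write_vcf(cohort.haplotypes, cohort.sites, cohort.sample_ids, paths["vcf"])
    write_tracts(cohort.tracts, paths["tracts"])
    cohort.gmap.write(paths["map"])
    with open(paths["meta"], "w") as fh:
        json.dump({"sample_ids": cohort.sample_ids, "meta": cohort.meta}, fh,
                  indent=1)
    return paths


def read_cohort(out_prefix) -> SimulatedCohort:
    prefix = Path(out_prefix)
    X, sites, samples = read_vcf(prefix.with_suffix(".vcf"))
    tracts = read_tracts(str(prefix) + ".tracts.tsv")
    gmap = GeneticMap.read(str(prefix) + ".map.tsv")
    with open(str(prefix) + ".meta.json") as fh:
        meta = json.load(fh)
    return SimulatedCohort(X, sites, tracts, gmap, meta["sample_ids"],
                           meta["meta"])


def write_segments(segments: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# IBD segments; bp 0-based half-open; lengths in cM\n")
        segments.to_csv(fh, sep="\t", index=False, float_format="%.10g")
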