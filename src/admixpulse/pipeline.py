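"""Config-driven orchestration of the full analysis chain.

`RunConfig` gathers every tunable of the other modules with its default, so
a run is fully described by one serializable object; `run_pipeline` executes
simulate -> qc -> lai -> {aspca, dating, waves, ibdne} as selected and
writes a manifest (seeds, configuration, output hashes).  Identical configs
produce byte-identical outputs.  `make_fixtures` writes the deterministic
micro-datasets used in tests and examples.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, qc, lai, aspca, dating, waves, ibdne
from .genmap import uniform_map, default_genome
from .sim import (Scenario, scenario_presets, build_source_panels,
                  simulate_cohort, one_pulse)


def _default_scenario() -> dict:
    return Scenario("demo-one-wave-25", one_pulse(25), N=100, sample_n=40,
                    n_haps_per_source=126, fst=0.15, total_cM=200.0,
                    n_chrom=4, n_snps=8000).to_dict()


@dataclass
class RunConfig:
    """Every stage's tunables, with defaults; JSON round-trip stable."""

    out_dir: str
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: ["simulate", "qc", "lai",
                                                       "aspca", "dating"])
    scenario: dict = field(default_factory=_default_scenario)
    qc_params: dict = field(default_factory=lambda: {
        "miss_max": 0.05, "hwe_p_min": 1e-5, "maf_min": 0.05,
        "sample_miss_max": 0.10, "kinship_threshold": 0.0442,
        "ld_window_kb": 50, "ld_step_snps": 5, "ld_r2_max": 0.5})
    lai_params: dict = field(default_factory=lambda: {
        "generations_prior": 25.0, "error_rate": 0.01, "min_tract_cM": 0.5})
    aspca_params: dict = field(default_factory=lambda: {
        "theta": 0.5, "n_components": 2})
    dating_params: dict = field(default_factory=lambda: {
        "bin_cM": 0.5, "max_cM": 30.0, "fit_max_cM": 10.0, "B": 1000,
        "censoring": False})
    waves_params: dict = field(default_factory=lambda: {
        "nboot": 1000, "subset_max_cM": 10.0, "scale_cM": 200.0,
        "tracts": "truth"})
    ibd_params: dict = field(default_factory=lambda: {
        "min_cM": 2.0, "max_gap_cM": 0.6, "max_inconsistent": 1,
        "bootstrap_reps": 80, "exclude_over": 0.5})

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def validate(self) -> None:
        if not self.out_dir:
            raise ValueError("config field 'out_dir' is required")
        known = {"simulate", "qc", "lai", "aspca", "dating", "waves", "ibdne"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(config.to_json()), "outputs": {}}
    sc = Scenario.from_dict(config.scenario)
    stage = "simulate"
    try:
        gmap = uniform_map(default_genome(sc.total_cM, sc.n_chrom))
        pA, pB, gmap, sites = build_source_panels(
            sc.n_snps, sc.fst, sc.n_haps_per_source, seed=config.seed,
            gmap=gmap)
        coh = simulate_cohort((pA, pB), gmap, sites, sc.pulses, sc.N,
                              sc.sample_n, seed=config.seed + 1)
        minor = sc.pulses.sources[-1]
        paths = io.write_cohort(coh, out / "cohort")
        manifest["outputs"]["simulate"] = {k: str(v) for k, v in paths.items()}

        if "qc" in config.stages:
            stage = "qc"
            p = config.qc_params
            G = coh.genotypes()
            G2, kept_sites, rep_v = qc.filter_variants(
                G, p["miss_max"], p["hwe_p_min"], p["maf_min"],
                site_ids=coh.sites["id"])
            G3, kept_samples, rep_s = qc.filter_samples(G2, p["sample_miss_max"])
            kin = qc.kinship_prune(G3, p["kinship_threshold"],
                                   [coh.sample_ids[i] for i in kept_samples])
            report = {"variants": rep_v.to_dict(), "samples": rep_s.to_dict(),
                      "kinship_pruned": kin.pruned}
            (out / "qc.json").write_text(json.dumps(report, indent=1))
            manifest["outputs"]["qc"] = {"report": str(out / "qc.json")}

        tracts = None
        props = None
        if "lai" in config.stages:
            stage = "lai"
            p = config.lai_params
            res = lai.infer_local_ancestry(
                coh.haplotypes, pA, pB, gmap, sites,
                generations_prior=p["generations_prior"],
                error_rate=p["error_rate"], min_tract_cM=p["min_tract_cM"],
                hap_ids=coh.haplotype_ids)
            tracts = res.tracts
            io.write_tracts(tracts, out / "lai.tracts.tsv")
            props = lai.individual_proportions(tracts, minor)
            props.to_csv(out / "proportions.tsv", sep="\t")
            truth_props = lai.individual_proportions(coh.tracts, minor)
            conc = lai.proportion_concordance(truth_props, props)
            manifest["outputs"]["lai"] = {
                "tracts": str(out / "lai.tracts.tsv"),
                "proportions": str(out / "proportions.tsv"),
                "concordance_r2_vs_truth": conc.r2}

        if "aspca" in config.stages:
            stage = "aspca"
            p = config.aspca_params
            chosen = aspca.threshold_select(props, p["theta"])
            hap_sel = [h for h in coh.haplotype_ids
                       if h.rsplit("_h", 1)[0] in set(chosen)]
            if len(hap_sel) >= 2:
                idx = [coh.haplotype_ids.index(h) for h in hap_sel]
                masked = lai.mask_by_ancestry(
                    coh.haplotypes[idx],
                    tracts[tracts["haplotype"].isin(hap_sel)], minor,
                    sites, hap_sel)
                emb = aspca.embed(masked,
                                  {pA.source_id: pA.haplotypes,
                                   pB.source_id: pB.haplotypes},
                                  sites=sites,
                                  n_components=p["n_components"])
                emb.coords.to_csv(out / "aspca.tsv", sep="\t", index=False)
                summ = aspca.population_distances(emb)
                summ.distances.to_csv(out / "aspca.distances.tsv", sep="\t")
                manifest["outputs"]["aspca"] = {
                    "embedding": str(out / "aspca.tsv"),
                    "distances": str(out / "aspca.distances.tsv"),
                    "n_selected": len(chosen)}
            else:
                manifest["outputs"]["aspca"] = {"skipped":
                                                "fewer than 2 haplotypes pass theta"}

        if "dating" in config.stages:
            stage = "dating"
            p = config.dating_params
            use = tracts if tracts is not None else coh.tracts
            est = dating.bootstrap_dates(use, gmap, minor, method="tract_mle",
                                         B=p["B"], seed=config.seed + 2,
                                         censoring=p["censoring"])
            curve = dating.coancestry_curve(use, gmap, minor,
                                            bin_cM=p["bin_cM"],
                                            max_cM=p["max_cM"],
                                            fit_max_cM=p["fit_max_cM"])
            result = {"tract_mle": {"g_hat": est.g_hat, "ci": est.ci,
                                    "B": p["B"]},
                      "coancestry": {"g_hat": curve.estimate.g_hat,
                                     "converged":
                                     curve.estimate.details["converged"]}}
            (out / "dates.json").write_text(json.dumps(result, indent=1))
            manifest["outputs"]["dating"] = {"dates": str(out / "dates.json")}

        if "waves" in config.stages:
            stage = "waves"
            p = config.waves_params
            use = tracts if tracts is not None else coh.tracts
            observed = dating.collect_tract_lengths(use, minor, gmap)
            samples = waves.run_scenarios(config.seed + 3,
                                          tracts=p["tracts"],
                                          scale_cM=p["scale_cM"])
            table = waves.compare_all(observed, samples,
                                      subset_max_cM=p["subset_max_cM"],
                                      nboot=p["nboot"], seed=config.seed + 4)
            table.to_csv(out / "waves.tsv", sep="\t", index=False)
            manifest["outputs"]["waves"] = {
                "table": str(out / "waves.tsv"),
                "best_fit_full": waves.best_fit(table, "full")}

        if "ibdne" in config.stages:
            stage = "ibdne"
            p = config.ibd_params
            segs = ibdne.detect_ibd(coh.haplotypes, gmap, sites,
                                    coh.haplotype_ids, min_cM=p["min_cM"])
            segs = ibdne.merge_gaps(segs, coh.haplotypes, sites,
                                    coh.haplotype_ids, gmap,
                                    p["max_gap_cM"], p["max_inconsistent"])
            use = tracts if tracts is not None else coh.tracts
            labeled = ibdne.label_ancestry(segs, use, minor,
                                           seed=config.seed + 5)
            io.write_segments(labeled, out / "ibd.tsv")
            props_u = lai.individual_proportions(use, minor)
            suite = ibdne.cohort_ne_suite(
                labeled, props_u, 2 * len(coh.sample_ids), gmap, minor,
                exclude_over=p["exclude_over"], min_cM=p["min_cM"],
                bootstrap_reps=p["bootstrap_reps"], seed=config.seed + 6)
            ne_tables = []
            for name, traj in suite.items():
                t = traj.table.copy()
                t["mode"] = name
                ne_tables.append(t)
            pd.concat(ne_tables).to_csv(out / "ne.tsv", sep="\t", index=False)
            manifest["outputs"]["ibdne"] = {"segments": str(out / "ibd.tsv"),
                                            "trajectories": str(out / "ne.tsv")}
    except Exception as err:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest["hashes"] = {
        str(f.relative_to(out)): _sha256(f)
        for f in sorted(out.rglob("*")) if f.is_file() and f.name != "manifest.json"}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest


def make_fixtures(out_dir) -> dict:
    """Deterministic micro-datasets for tests: a 2-chromosome, 200-SNP,
    6-individual cohort with known tracts, and a planted 6 cM IBD block."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gmap = uniform_map({"chr1": 40.0, "chr2": 30.0})
    pA, pB, gmap, sites = build_source_panels(200, 0.2, 30, seed=1234,
                                              gmap=gmap)
    coh = simulate_cohort((pA, pB), gmap, sites, one_pulse(10), N=30,
                          sample_n=6, seed=1234)
    # plant an IBD block: copy chr1 10-16 cM of ind000_h0 into ind001_h0
    cm = sites["cM"].to_numpy()
    in_block = (sites["chrom"].to_numpy() == "chr1") & (cm >= 10) & (cm < 16)
    coh.haplotypes[2] = coh.haplotypes[2].copy()
    coh.haplotypes[2][in_block] = coh.haplotypes[0][in_block]
    paths = io.write_cohort(coh, out / "micro")
    planted = pd.DataFrame([("ind000_h0", "ind001_h0", "chr1", 10.0, 16.0)],
                           columns=["hap1", "hap2", "chrom", "start_cM",
                                    "end_cM"])
    planted.to_csv(out / "planted_ibd.tsv", sep="\t", index=False)
    paths["planted_ibd"] = out / "planted_ibd.tsv"
    return {k: str(v) for k, v in paths.items()}
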