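"""One-wave vs two-wave discrimination from ancestry-segment lengths.

A single recent admixture pulse leaves an approximately exponential
minor-ancestry tract-length distribution; adding an older pulse mixes in a
large number of short tracts while a more recent pulse contributes a long
tail.  Scenario simulations are compared to an observed tract-length sample
with a bootstrap two-sample Kolmogorov-Smirnov test (pooled-resample null),
on the full distributions and on the <=10 cM subset where most segments lie.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genmap import uniform_map, default_genome
from .sim import Scenario, scenario_presets, build_source_panels, simulate_cohort
from .dating import TractLengthSample, collect_tract_lengths
from .lai import infer_local_ancestry


@dataclass
class WaveComparison:
    scenario_a: str
    scenario_b: str
    subset: str               # "full" or "<=10cM"
    n_a: int
    n_b: int
    D: float
    p: float
    nboot: int
    seed: int


def run_scenarios(seed: int, scenarios: list[Scenario] | None = None,
                  minor: str = "B", tracts: str = "lai",
                  scale_cM: float | None = None) -> dict[str, TractLengthSample]:
    """Simulate every preset scenario and collect minor-ancestry tract lengths.

    `tracts="lai"` infers tracts with the HMM on the simulated genotypes
    (the full pipeline route); `tracts="truth"` uses the simulator's exact
    tracts.  `scale_cM` overrides the scenario genome size, for fast runs.
    """
    if scenarios is None:
        scenarios = scenario_presets()
    out = {}
    for i, sc in enumerate(scenarios):
        total = scale_cM if scale_cM is not None else sc.total_cM
        gmap = uniform_map(default_genome(total, sc.n_chrom))
        n_snps = sc.n_snps if tracts == "lai" else min(sc.n_snps, 10)
        pA, pB, gmap, sites = build_source_panels(
            n_snps, sc.fst, sc.n_haps_per_source, seed=seed * 1009 + i, gmap=gmap)
        coh = simulate_cohort((pA, pB), gmap, sites, sc.pulses, sc.N,
                              sc.sample_n, seed=seed * 1013 + i,
                              with_genotypes=(tracts == "lai"))
        if tracts == "lai":
            res = infer_local_ancestry(coh.haplotypes, pA, pB, gmap, sites,
                                       hap_ids=coh.haplotype_ids)
            tr = res.tracts
        elif tracts == "truth":
            tr = coh.tracts
        else:
            raise ValueError("tracts must be 'lai' or 'truth'")
        out[sc.name] = collect_tract_lengths(tr, minor, gmap)
    return out


def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS statistic D = sup |ECDF_a - ECDF_b|."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    allv = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, allv, side="right") / len(a)
    cdf_b = np.searchsorted(b, allv, side="right") / len(b)
    return float(np.abs(cdf_a - cdf_b).max())


def ks_boot(lengths_a, lengths_b, nboot: int = 1000, seed: int = 0,
            label_a: str = "A", label_b: str = "B",
            subset: str = "full") -> WaveComparison:
    """Bootstrap KS test with a pooled-resample null.

    The observed D is compared with `nboot` statistics computed on pairs of
    samples drawn with replacement from the pooled data (the null of a
    common distribution); p = (1 + #{D* >= D}) / (1 + nboot), which is exact
    under ties and never returns 0.
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("both samples need >=5 observations")
    d_obs = ks_statistic(a, b)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    count = 0
    for _ in range(nboot):
        idx = rng.integers(0, len(pooled), len(pooled))
        d = ks_statistic(pooled[idx[:n_a]], pooled[idx[n_a:]])
        if d >= d_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + nboot)
    return WaveComparison(label_a, label_b, subset, len(a), len(b),
                          d_obs, float(p), nboot, seed)


def compare_all(observed: TractLengthSample,
                scenarios: dict[str, TractLengthSample],
                subset_max_cM: float = 10.0, nboot: int = 1000,
                seed: int = 0) -> pd.DataFrame:
    """Compare an observed tract-length sample against every scenario.

    Runs the bootstrap KS on the full distributions and on the subset of
    lengths <= `subset_max_cM`, and ranks scenarios by ascending D; the
    best-fitting scenario is the top row of each subset block.  Scenarios
    whose subset is empty are skipped with a flag row (p = NaN).
    """
    if not scenarios:
        raise ValueError("no scenarios to compare against")
    rows = []
    for k, (name, sc_sample) in enumerate(scenarios.items()):
        pairs = [("full", observed.lengths, sc_sample.lengths)]
        obs_sub = observed.lengths[observed.lengths <= subset_max_cM]
        sc_sub = sc_sample.lengths[sc_sample.lengths <= subset_max_cM]
        pairs.append((f"<={subset_max_cM:g}cM", obs_sub, sc_sub))
        for subset, a, b in pairs:
            if len(a) < 5 or len(b) < 5:
                rows.append(("observed", name, subset, len(a), len(b),
                             np.nan, np.nan, nboot, seed))
                continue
            c = ks_boot(a, b, nboot=nboot, seed=seed * 131 + k,
                        label_a="observed", label_b=name, subset=subset)
            rows.append((c.scenario_a, c.scenario_b, c.subset, c.n_a, c.n_b,
                         c.D, c.p, c.nboot, c.seed))
    df = pd.DataFrame(rows, columns=["scenarioA", "scenarioB", "subset", "n_A",
                                     "n_B", "D", "p", "nboot", "seed"])
    return df.sort_values(["subset", "D"]).reset_index(drop=True)


def best_fit(comparisons: pd.DataFrame, subset: str = "full") -> str:
    """Scenario with the smallest KS distance to the observed sample."""
    sub = comparisons[(comparisons["subset"] == subset) & comparisons["D"].notna()]
    if sub.empty:
        raise ValueError(f"no valid comparisons for subset {subset!r}")
    return sub.sort_values("D").iloc[0]["scenarioB"]
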