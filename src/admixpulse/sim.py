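"""Forward-time pulse-admixture simulation with recombination and truth tracts.

The simulator models a Wright–Fisher population of constant diploid size N
founded by an instantaneous admixture pulse between two divergent source
populations, with optional later pulses.  Source panels are generated under
the Balding–Nichols model at a chosen FST.  Founders copy whole haplotypes
from the panels, so source linkage disequilibrium is preserved; every
subsequent generation each gamete receives a Poisson(L Morgans) number of
crossovers placed uniformly in genetic distance.  Ancestry is tracked as
tracts (intervals in cM referencing a founder haplotype), which makes the
truth local ancestry of every sampled haplotype exact, and genotypes are
materialised from the tracts only when requested.

Coordinates: tract positions are authoritative in cM; bp positions are
derived through the genetic map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genmap import GeneticMap, uniform_map, default_genome

# founder id = source_index * FOUNDER_STRIDE + panel haplotype index
FOUNDER_STRIDE = 1_000_000


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SourcePanel:
    """A reference panel of phased haplotypes from one source population."""

    source_id: str
    haplotypes: np.ndarray  # (n_haps, n_sites) int8 in {0, 1}

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] < 2:
            raise ValueError("a source panel needs >=2 haplotypes")
        if not np.isin(self.haplotypes, [0, 1]).all():
            raise ValueError("panel alleles must be 0/1")

    @property
    def n_haps(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def allele_freqs(self) -> np.ndarray:
        """Empirical per-site allele-1 frequency (column means)."""
        return self.haplotypes.mean(axis=0)


@dataclass(frozen=True)
class Pulse:
    """One admixture pulse: fraction of the population replaced by migrants."""

    generation: int          # generations before present
    source: str
    fraction: float
    founding: bool = False


@dataclass
class PulseSchedule:
    """Ordered admixture pulses; the founding pulses define the initial mix."""

    pulses: list[Pulse]

    def __post_init__(self) -> None:
        founding = [p for p in self.pulses if p.founding]
        later = sorted((p for p in self.pulses if not p.founding),
                       key=lambda p: -p.generation)
        if not founding:
            raise ValueError("schedule needs at least one founding pulse")
        gens = {p.generation for p in founding}
        if len(gens) != 1:
            raise ValueError("founding pulses must share one generation")
        if abs(sum(p.fraction for p in founding) - 1.0) > 1e-9:
            raise ValueError("founding fractions must sum to 1")
        g_seq = [founding[0].generation] + [p.generation for p in later]
        if any(b >= a for a, b in zip(g_seq, g_seq[1:])):
            raise ValueError("pulse generations must strictly decrease toward present")
        for p in later:
            if not (0.0 < p.fraction < 1.0):
                raise ValueError("non-founding pulse fraction must be in (0, 1)")
        self.pulses = founding + later

    @property
    def g_founding(self) -> int:
        return self.pulses[0].generation

    @property
    def sources(self) -> list[str]:
        seen: list[str] = []
        for p in self.pulses:
            if p.source not in seen:
                seen.append(p.source)
        return seen

    def minor_source_fraction(self, source: str) -> float:
        """Founding fraction contributed by `source`."""
        return sum(p.fraction for p in self.pulses if p.founding and p.source == source)

    def to_dict(self) -> dict:
        return {"pulses": [asdict(p) for p in self.pulses]}

    @classmethod
    def from_dict(cls, d: dict) -> "PulseSchedule":
        return cls([Pulse(**p) for p in d["pulses"]])


def one_pulse(g: int, major: str = "A", minor: str = "B", m: float = 0.25) -> PulseSchedule:
    """Single founding pulse, e.g. 3:1 admixture (m = minor fraction)."""
    return PulseSchedule([
        Pulse(g, major, 1.0 - m, founding=True),
        Pulse(g, minor, m, founding=True),
    ])


def two_pulse(g1: int, g2: int, major: str = "A", minor: str = "B",
              m1: float = 0.25, m2: float = 0.25) -> PulseSchedule:
    """Founding pulse at g1 plus a later minor-source pulse at g2."""
    sched = one_pulse(g1, major, minor, m1)
    return PulseSchedule(sched.pulses + [Pulse(g2, minor, m2)])


@dataclass
class Scenario:
    """A named simulation configuration (admixture history + run sizes)."""

    name: str
    pulses: PulseSchedule
    N: int = 100
    sample_n: int = 40
    n_haps_per_source: int = 126
    fst: float = 0.15
    total_cM: float = 3500.0
    n_chrom: int = 22
    n_snps: int = 8000

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pulses"] = self.pulses.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        d["pulses"] = PulseSchedule.from_dict(d["pulses"])
        return cls(**d)


def scenario_presets() -> list[Scenario]:
    """The five study scenarios: one-wave g in {25, 50, 100}; two-wave with a
    second minor-source pulse 25 generations ago added to the two deeper
    histories.  One-wave scenarios use 126 haplotypes per source panel,
    two-wave scenarios 80."""
    presets = [
        Scenario(f"one-wave-{g}", one_pulse(g), n_haps_per_source=126)
        for g in (25, 50, 100)
    ]
    presets += [
        Scenario(f"two-wave-{g}-25", two_pulse(g, 25), n_haps_per_source=80)
        for g in (50, 100)
    ]
    return presets


@dataclass
class SimulatedCohort:
    """Sampled phased haplotypes with exact truth ancestry tracts."""

    haplotypes: np.ndarray | None      # (2*sample_n, n_sites) int8, or None
    sites: pd.DataFrame                # chrom, pos_bp, cM, id
    tracts: pd.DataFrame               # truth tracts, tiling each chromosome
    gmap: GeneticMap
    sample_ids: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def haplotype_ids(self) -> list[str]:
        return [f"{s}_h{k}" for s in self.sample_ids for k in (0, 1)]

    def genotypes(self) -> np.ndarray:
        """Diploid dosage matrix (n_samples, n_sites)."""
        if self.haplotypes is None:
            raise ValueError("cohort was simulated without genotypes")
        return (self.haplotypes[0::2].astype(np.int16)
                + self.haplotypes[1::2]).astype(np.int8)


# ---------------------------------------------------------------------------
# source panels
# ---------------------------------------------------------------------------

def place_sites(gmap: GeneticMap, n_snps: int) -> pd.DataFrame:
    """Spread n_snps across chromosomes proportionally to genetic length."""
    chroms = gmap.chromosomes
    lengths = np.array([gmap.length_cM(c) for c in chroms])
    counts = np.floor(lengths / lengths.sum() * n_snps).astype(int)
    # distribute the remainder to the largest fractional parts
    frac = lengths / lengths.sum() * n_snps - counts
    for i in np.argsort(-frac)[: n_snps - counts.sum()]:
        counts[i] += 1
    rows = []
    for chrom, k in zip(chroms, counts):
        if k == 0:
            continue
        lo, hi = gmap.chrom_cM[chrom][0], gmap.chrom_cM[chrom][-1]
        cm = lo + (np.arange(k) + 0.5) / k * (hi - lo)
        bp = gmap.cM_to_bp(chrom, cm)
        for c, b in zip(cm, bp):
            rows.append((chrom, int(b), float(c)))
    df = pd.DataFrame(rows, columns=["chrom", "pos_bp", "cM"])
    df["id"] = [f"snp{i}" for i in range(len(df))]
    return df


def build_source_panels(
    n_snps: int,
    fst: float,
    n_haps_per_source: int,
    seed: int,
    total_cM: float = 3500.0,
    n_chrom: int = 22,
    gmap: GeneticMap | None = None,
    source_ids: tuple[str, str] = ("A", "B"),
) -> tuple[SourcePanel, SourcePanel, GeneticMap, pd.DataFrame]:
    """Two Balding–Nichols source panels on a shared uniform map.

    Per site, an ancestral frequency p ~ U(0.05, 0.95) is drawn, each source
    frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), and haplotype alleles i.i.d.
    Bernoulli at the source frequency.
    """
    if not (0.0 < fst < 1.0):
        raise ValueError("fst must be in (0, 1)")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    if gmap is None:
        gmap = uniform_map(default_genome(total_cM, n_chrom))
    sites = place_sites(gmap, n_snps)
    p_anc = rng.uniform(0.05, 0.95, size=len(sites))
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    panels = []
    for sid in source_ids:
        p_pop = rng.beta(a, b)
        haps = (rng.random((n_haps_per_source, len(sites))) < p_pop).astype(np.int8)
        panels.append(SourcePanel(sid, haps))
    return panels[0], panels[1], gmap, sites


# ---------------------------------------------------------------------------
# Wright–Fisher forward simulation on tracts
# ---------------------------------------------------------------------------

def _recombine(h1, h2, L: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a diploid parent; h = (segment end positions, founder ids)."""
    k = rng.poisson(L / 100.0)
    if k == 0:
        return h1 if rng.integers(2) == 0 else h2
    cuts = np.unique(rng.uniform(0.0, L, k))
    return _crossover(h1, h2, cuts, L, int(rng.integers(2)))


def _crossover(h1, h2, cuts: np.ndarray, L: float, start: int):
    """Splice two parental haplotypes at the given sorted crossover points."""
    haps = (h1, h2)
    cur = start
    prev = 0.0
    ends_parts, fnd_parts = [], []
    for b in np.append(cuts, L):
        ends, fnd = haps[cur]
        i0 = int(np.searchsorted(ends, prev, side="right"))
        i1 = int(np.searchsorted(ends, b, side="left"))
        if i1 >= len(ends):
            i1 = len(ends) - 1
        e = ends[i0:i1 + 1].copy()
        e[-1] = b
        ends_parts.append(e)
        fnd_parts.append(fnd[i0:i1 + 1])
        prev = b
        cur ^= 1
    ends = np.concatenate(ends_parts)
    fnd = np.concatenate(fnd_parts)
    # drop zero-length pieces, then merge adjacent same-founder segments
    keep = np.empty(len(ends), dtype=bool)
    keep[0] = ends[0] > 0.0
    keep[1:] = ends[1:] > ends[:-1]
    ends, fnd = ends[keep], fnd[keep]
    merge = np.empty(len(ends), dtype=bool)
    merge[-1] = True
    merge[:-1] = fnd[:-1] != fnd[1:]
    return ends[merge], fnd[merge]


def _fresh_founder_hap(source_idx: int, n_panel_haps: int, lengths, rng):
    """Whole-genome single-founder haplotype (one tract per chromosome)."""
    hap_idx = int(rng.integers(n_panel_haps))
    fid = source_idx * FOUNDER_STRIDE + hap_idx
    return [(np.array([L]), np.array([fid], dtype=np.int64)) for L in lengths]


def _integer_counts(fractions: np.ndarray, N: int) -> np.ndarray:
    """Largest-remainder rounding of fractions*N to integers summing to N."""
    raw = fractions * N
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: N - counts.sum()]:
        counts[i] += 1
    return counts


def simulate_cohort(
    panels: tuple[SourcePanel, SourcePanel],
    gmap: GeneticMap,
    sites: pd.DataFrame,
    pulses: PulseSchedule,
    N: int,
    sample_n: int,
    seed: int,
    g_total: int | None = None,
    with_genotypes: bool = True,
    sample_prefix: str = "ind",
) -> SimulatedCohort:
    """Run the forward simulation and sample `sample_n` diploids.

    The population of N diploids is founded `g_total` generations before
    present by the founding pulses (deterministic per-source individual
    counts, largest-remainder rounding); each later pulse at generation g
    replaces round(m*N) randomly chosen individuals with fresh single-source
    founders.  Each generation every child draws two parents uniformly with
    replacement and receives one recombined gamete from each.
    """
    if sample_n > N:
        raise ValueError("sample_n cannot exceed N")
    source_ids = [p.source_id for p in panels]
    for p in pulses.pulses:
        if p.source not in source_ids:
            raise ValueError(f"pulse source {p.source!r} not among panels {source_ids}")
    g_found = pulses.g_founding
    if g_total is None:
        g_total = g_found
    if g_total != g_found:
        raise ValueError("g_total must equal the founding-pulse generation")

    rng = np.random.default_rng(seed)
    chroms = gmap.chromosomes
    lengths = [gmap.length_cM(c) for c in chroms]
    panel_by_source = {p.source_id: p for p in panels}

    # founding population
    founding = [p for p in pulses.pulses if p.founding]
    counts = _integer_counts(np.array([p.fraction for p in founding]), N)
    pop: list[list] = []
    for p, cnt in zip(founding, counts):
        s_idx = source_ids.index(p.source)
        n_panel = panel_by_source[p.source].n_haps
        for _ in range(cnt):
            pop.append(_fresh_founder_hap(s_idx, n_panel, lengths, rng))
            pop.append(_fresh_founder_hap(s_idx, n_panel, lengths, rng))

    later = {p.generation: p for p in pulses.pulses if not p.founding}

    n_chrom = len(chroms)
    lam = np.asarray(lengths) / 100.0
    for gen in range(g_found - 1, -1, -1):
        # batch all randomness for the generation: parent choices, crossover
        # counts (Poisson per Morgan), crossover positions, starting strands
        parents = rng.integers(0, N, size=2 * N)
        ks = rng.poisson(np.broadcast_to(lam, (2 * N, n_chrom)))
        starts = rng.integers(0, 2, size=(2 * N, n_chrom))
        cuts_flat = rng.random(int(ks.sum()))
        offsets = np.concatenate(([0], np.cumsum(ks.ravel())))
        new_pop: list[list] = []
        for g_i in range(2 * N):
            par = parents[g_i]
            h1 = pop[2 * par]
            h2 = pop[2 * par + 1]
            gamete = []
            for c in range(n_chrom):
                k = ks[g_i, c]
                if k == 0:
                    gamete.append(h1[c] if starts[g_i, c] == 0 else h2[c])
                else:
                    lo = offsets[g_i * n_chrom + c]
                    cuts = np.unique(cuts_flat[lo:lo + k]) * lengths[c]
                    gamete.append(_crossover(h1[c], h2[c], cuts, lengths[c],
                                             int(starts[g_i, c])))
            new_pop.append(gamete)
        # consecutive gametes pair into the next generation's diploids
        pop = new_pop
        if gen in later:
            p = later[gen]
            n_mig = int(round(p.fraction * N))
            s_idx = source_ids.index(p.source)
            n_panel = panel_by_source[p.source].n_haps
            for ind in rng.choice(N, size=n_mig, replace=False):
                pop[2 * ind] = _fresh_founder_hap(s_idx, n_panel, lengths, rng)
                pop[2 * ind + 1] = _fresh_founder_hap(s_idx, n_panel, lengths, rng)

    sampled = rng.choice(N, size=sample_n, replace=False)
    sample_ids = [f"{sample_prefix}{i:03d}" for i in range(sample_n)]
    hap_tracts = []
    for ind in sampled:
        hap_tracts.append(pop[2 * ind])
        hap_tracts.append(pop[2 * ind + 1])

    tracts = _tracts_frame(hap_tracts, sample_ids, chroms, gmap, source_ids)
    founder_tracts = _founder_tracts_frame(hap_tracts, sample_ids, chroms)
    haps = None
    if with_genotypes:
        haps = _materialize(hap_tracts, panel_by_source, source_ids, sites, chroms, gmap)

    meta = {
        "pulses": pulses.to_dict(),
        "N": N,
        "sample_n": sample_n,
        "seed": seed,
        "g_total": g_total,
        "sources": source_ids,
    }
    coh = SimulatedCohort(haps, sites, tracts, gmap, sample_ids, meta)
    coh.founder_tracts = founder_tracts
    return coh


def _founder_tracts_frame(hap_tracts, sample_ids, chroms) -> pd.DataFrame:
    """Founder-resolution tracts (which panel haplotype each interval copies)."""
    rows = []
    for h, tract_list in enumerate(hap_tracts):
        hap_id = f"{sample_ids[h // 2]}_h{h % 2}"
        for c, chrom in enumerate(chroms):
            ends, fnd = tract_list[c]
            start = 0.0
            for e, f in zip(ends, fnd):
                rows.append((hap_id, chrom, start, float(e), int(f)))
                start = float(e)
    return pd.DataFrame(rows, columns=["haplotype", "chrom", "start_cM",
                                       "end_cM", "founder"])


def _tracts_frame(hap_tracts, sample_ids, chroms, gmap, source_ids) -> pd.DataFrame:
    rows = []
    for h, tract_list in enumerate(hap_tracts):
        hap_id = f"{sample_ids[h // 2]}_h{h % 2}"
        for c, chrom in enumerate(chroms):
            ends, fnd = tract_list[c]
            src = (fnd // FOUNDER_STRIDE).astype(int)
            # merge adjacent same-source segments
            keep = np.empty(len(ends), dtype=bool)
            keep[-1] = True
            keep[:-1] = src[:-1] != src[1:]
            ends_m, src_m = ends[keep], src[keep]
            start = 0.0
            cm0 = gmap.chrom_cM[chrom][0]
            for e, s in zip(ends_m, src_m):
                s_cm, e_cm = start + cm0, float(e) + cm0
                s_bp, e_bp = gmap.cM_to_bp(chrom, [s_cm, e_cm])
                rows.append((hap_id, chrom, int(s_bp), int(e_bp),
                             s_cm, e_cm, source_ids[s]))
                start = float(e)
    return pd.DataFrame(rows, columns=["haplotype", "chrom", "start_bp", "end_bp",
                                       "start_cM", "end_cM", "ancestry"])


def _materialize(hap_tracts, panel_by_source, source_ids, sites, chroms,
                 gmap: GeneticMap | None = None) -> np.ndarray:
    """Copy alleles for each sampled haplotype from its founder tracts."""
    n_sites = len(sites)
    out = np.zeros((len(hap_tracts), n_sites), dtype=np.int8)
    chrom_col = sites["chrom"].to_numpy()
    cm_col = sites["cM"].to_numpy()
    site_idx_by_chrom = {c: np.flatnonzero(chrom_col == c) for c in chroms}
    # tract ends are relative to the chromosome's cM origin
    rel_cm = {}
    for c in chroms:
        idx = site_idx_by_chrom[c]
        origin = gmap.chrom_cM[c][0] if gmap is not None else 0.0
        rel_cm[c] = cm_col[idx] - origin
    panel_haps = {s: panel_by_source[s].haplotypes for s in source_ids}
    for h, tract_list in enumerate(hap_tracts):
        for c, chrom in enumerate(chroms):
            idx = site_idx_by_chrom[chrom]
            if idx.size == 0:
                continue
            ends, fnd = tract_list[c]
            seg = np.searchsorted(ends, rel_cm[chrom], side="left")
            seg = np.minimum(seg, len(ends) - 1)
            founder = fnd[seg]
            src = founder // FOUNDER_STRIDE
            hap_i = founder % FOUNDER_STRIDE
            for s_idx, sid in enumerate(source_ids):
                m = src == s_idx
                if m.any():
                    out[h, idx[m]] = panel_haps[sid][hap_i[m], idx[m]]
    return out


def realized_fractions(tracts: pd.DataFrame, ancestry: str) -> pd.Series:
    """Per-individual genome fraction of `ancestry` from truth/inferred tracts."""
    t = tracts.copy()
    t["len"] = t["end_cM"] - t["start_cM"]
    t["individual"] = t["haplotype"].str.rsplit("_h", n=1).str[0]
    tot = t.groupby("individual")["len"].sum()
    anc = t[t["ancestry"] == ancestry].groupby("individual")["len"].sum()
    return (anc.reindex(tot.index).fillna(0.0) / tot).rename("fraction")
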