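"""Admixture dating from ancestry tract lengths and coancestry decay curves.

Under a single admixture pulse g generations ago contributing a fraction m
of the genome, minor-ancestry tract lengths are approximately exponential
with rate g(1-m)/100 per cM, and the covariance of the ancestry indicator
between two loci d cM apart decays as m(1-m)·exp(-g d/100).  Both signals
yield estimators of g:

* tract MLE      ĝ = 100 / (L̄ (1-m)) from uncensored tract lengths, or the
                 censored-exponential MLE when tracts touching chromosome
                 ends are to be used;
* coancestry     fit A·exp(-g d/100) + C to the binned autocovariance of
                 the ancestry indicator.

Uncertainty comes from resampling individuals with replacement.  A
tail-based variant dates the most recent pulse of a two-wave history from
tracts longer than a threshold, where the older pulse's contribution is
negligible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import fftconvolve
from scipy.stats import gaussian_kde

from .genmap import GeneticMap


@dataclass
class TractLengthSample:
    """Tract lengths (cM) of one ancestry, with chromosome-end censoring flags."""

    lengths: np.ndarray
    censored: np.ndarray          # tract touches either chromosome end
    ancestry: str
    individuals: np.ndarray       # individual id per tract
    right_censored: np.ndarray | None = None  # right end at a chromosome end

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.right_censored is None:
            self.right_censored = self.censored.copy()
        self.right_censored = np.asarray(self.right_censored, dtype=bool)
        if np.any(self.lengths <= 0):
            raise ValueError("tract lengths must be positive")

    @property
    def uncensored(self) -> np.ndarray:
        return self.lengths[~self.censored]

    def subset_individuals(self, individuals) -> "TractLengthSample":
        m = np.isin(self.individuals, np.asarray(individuals))
        return TractLengthSample(self.lengths[m], self.censored[m],
                                 self.ancestry, self.individuals[m],
                                 self.right_censored[m])


@dataclass
class DateEstimate:
    """Point estimate of generations since admixture, with optional bootstrap."""

    g_hat: float
    method: str
    bootstrap_draws: np.ndarray | None = None
    ci: tuple[float, float] | None = None
    calendar_year: int | None = None
    details: dict = field(default_factory=dict)

    def density(self, grid: np.ndarray | None = None):
        """Kernel-density summary of the bootstrap draws for plotting."""
        if self.bootstrap_draws is None or len(np.unique(self.bootstrap_draws)) < 2:
            raise ValueError("density requires non-degenerate bootstrap draws")
        draws = self.bootstrap_draws
        if grid is None:
            grid = np.linspace(draws.min() * 0.5, draws.max() * 1.5, 256)
        return grid, gaussian_kde(draws)(grid)


# ---------------------------------------------------------------------------
# tract lengths
# ---------------------------------------------------------------------------

def collect_tract_lengths(tracts: pd.DataFrame, ancestry: str,
                          gmap: GeneticMap, tol: float = 1e-9) -> TractLengthSample:
    """One length per maximal run of `ancestry`; runs abutting a chromosome
    end are flagged censored."""
    t = tracts[tracts["ancestry"] == ancestry]
    lengths, censored, right_cens, individuals = [], [], [], []
    for chrom in t["chrom"].unique():
        lo = float(gmap.chrom_cM[chrom][0])
        hi = float(gmap.chrom_cM[chrom][-1])
        sub = t[t["chrom"] == chrom]
        for hap, grp in sub.groupby("haplotype", sort=False):
            grp = grp.sort_values("start_cM")
            # tracts of one ancestry within a tiling set are already maximal
            for _, row in grp.iterrows():
                lengths.append(row["end_cM"] - row["start_cM"])
                right = hi - row["end_cM"] < tol
                censored.append(row["start_cM"] - lo < tol or right)
                right_cens.append(right)
                individuals.append(hap.rsplit("_h", 1)[0])
    return TractLengthSample(np.array(lengths, dtype=float),
                             np.array(censored, dtype=bool),
                             ancestry, np.array(individuals, dtype=object),
                             np.array(right_cens, dtype=bool))


def date_from_tracts(sample: TractLengthSample, m: float,
                     censoring: bool = False) -> DateEstimate:
    """Single-pulse date from minor-ancestry tract lengths.

    With `censoring=False` chromosome-end tracts are dropped and
    ĝ = 100 / (L̄ (1-m)); with `censoring=True` all tracts enter the
    censored-exponential MLE λ̂ = n_events / Σ lengths, where an event is a
    tract whose right end is interior (right-censored tracts contribute
    exposure but no event; left-truncation is harmless by memorylessness).
    """
    if not (0.0 < m < 1.0):
        raise ValueError("m must be in (0, 1)")
    n_unc = int((~sample.censored).sum())
    if not censoring and n_unc < 10:
        raise ValueError("need >=10 uncensored tracts (or censoring=True)")
    if censoring:
        n_events = int((~sample.right_censored).sum())
        if n_events == 0:
            raise ValueError("all tracts censored; rate is unidentified")
        lam = n_events / sample.lengths.sum()
    else:
        lam = 1.0 / sample.uncensored.mean()
    g = 100.0 * lam / (1.0 - m)
    return DateEstimate(float(g), "tract_mle",
                        details={"m": m, "n_tracts": len(sample.lengths),
                                 "n_uncensored": n_unc, "censoring": censoring})


def date_from_tract_tail(sample: TractLengthSample, m: float,
                         threshold_cM: float = 15.0) -> DateEstimate:
    """Date the most recent pulse from tracts longer than `threshold_cM`.

    By the memoryless property the excess length over the threshold of an
    exponential tail is exponential with the same rate, and tracts from a
    much older pulse are essentially absent above the threshold, so the
    censored-exponential MLE on the excesses isolates the recent pulse.
    """
    if not (0.0 < m < 1.0):
        raise ValueError("m must be in (0, 1)")
    tail = sample.lengths > threshold_cM
    if tail.sum() < 5:
        raise ValueError(f"fewer than 5 tracts exceed {threshold_cM} cM")
    excess = sample.lengths[tail] - threshold_cM
    n_events = int((~sample.right_censored[tail]).sum())
    if n_events == 0:
        raise ValueError("all tail tracts censored")
    lam = n_events / excess.sum()
    g = 100.0 * lam / (1.0 - m)
    return DateEstimate(float(g), "tract_tail",
                        details={"m": m, "threshold_cM": threshold_cM,
                                 "n_tail": int(tail.sum())})


# ---------------------------------------------------------------------------
# coancestry curve
# ---------------------------------------------------------------------------

def _indicator_sums(tracts: pd.DataFrame, gmap: GeneticMap, ancestry: str,
                    grid_cM: float, max_cM: float):
    """Per-individual lag sums of the ancestry indicator on a regular grid.

    Returns dict individual -> (lag_products, lag_counts, ones, total), where
    lag_products[k] sums I(x)·I(x + k·grid) over both haplotypes and all
    chromosomes.  FFT autocorrelation keeps this O(n log n).
    """
    n_lags = int(round(max_cM / grid_cM))
    per_ind: dict = {}
    for hap, grp in tracts.groupby("haplotype", sort=False):
        ind = hap.rsplit("_h", 1)[0]
        acc = per_ind.setdefault(
            ind, [np.zeros(n_lags + 1), np.zeros(n_lags + 1), 0.0, 0.0])
        for chrom, sub in grp.groupby("chrom", sort=False):
            lo = float(gmap.chrom_cM[chrom][0])
            hi = float(gmap.chrom_cM[chrom][-1])
            x = lo + (np.arange(int((hi - lo) / grid_cM)) + 0.5) * grid_cM
            sub = sub.sort_values("start_cM")
            ends = sub["end_cM"].to_numpy()
            anc = sub["ancestry"].to_numpy()
            k = np.minimum(np.searchsorted(ends, x, side="right"), len(ends) - 1)
            I = (anc[k] == ancestry).astype(float)
            full = fftconvolve(I, I[::-1])
            n = len(I)
            lags = np.arange(min(n_lags, n - 1) + 1)
            acc[0][lags] += full[n - 1 + lags]
            acc[1][lags] += n - lags
            acc[2] += I.sum()
            acc[3] += n
    return per_ind


def _fit_decay(d: np.ndarray, cov: np.ndarray, w: np.ndarray):
    """Weighted fit of cov(d) = A exp(-g d / 100) + C; returns (g, A, C, ok)."""
    pos = cov > 0
    if pos.sum() >= 3:
        slope = np.polyfit(d[pos], np.log(cov[pos]), 1, w=np.sqrt(w[pos]))[0]
        g0 = max(-slope * 100.0, 1.0)
    else:
        g0 = 10.0
    p0 = [max(cov[0], 1e-4), g0, 0.0]
    try:
        popt, _ = curve_fit(
            lambda x, A, g, C: A * np.exp(-g * x / 100.0) + C,
            d, cov, p0=p0, sigma=1.0 / np.sqrt(w),
            bounds=([0.0, 1e-3, -1.0], [1.0, 2000.0, 1.0]), maxfev=5000)
        A, g, C = popt
        ok = True
    except RuntimeError:
        A, g, C = p0[0], g0, 0.0
        ok = False
    return float(g), float(A), float(C), ok


@dataclass
class CoancestryResult:
    curve: pd.DataFrame           # distance bin (cM), covariance, weight
    estimate: DateEstimate
    per_individual: dict          # cached sums, reused by the bootstrap
    grid_cM: float
    bin_cM: float


def coancestry_curve(tracts: pd.DataFrame, gmap: GeneticMap, ancestry: str,
                     bin_cM: float = 0.5, max_cM: float = 30.0,
                     grid_cM: float = 0.25, min_cM: float = 0.5,
                     fit_max_cM: float = 10.0) -> CoancestryResult:
    """Ancestry-indicator autocovariance vs genetic distance, and its decay date.

    cov(d) = mean over haplotypes and position pairs at distance d of
    I(x)I(x+d), minus the squared mean ancestry fraction; a single pulse g
    generations ago gives cov(d) = m(1-m) e^{-g d/100}, so the fitted decay
    constant estimates g.  The curve is computed out to `max_cM` but fitted
    only on [`min_cM`, `fit_max_cM`]: below min_cM the indicator saturates
    within tracts, and far beyond the pulse decay length the covariance is
    dominated by slowly-decaying drift relatedness, which drags a
    single-exponential fit toward shallower decay.
    """
    inds = sorted({h.rsplit("_h", 1)[0] for h in tracts["haplotype"].unique()})
    if len(inds) < 2:
        raise ValueError("coancestry curve needs >=2 individuals")
    per_ind = _indicator_sums(tracts, gmap, ancestry, grid_cM, max_cM)
    curve, est = _curve_from_sums([per_ind[i] for i in inds],
                                  grid_cM, bin_cM, max_cM, min_cM, fit_max_cM)
    return CoancestryResult(curve, est, per_ind, grid_cM, bin_cM)


def _curve_from_sums(acc_list, grid_cM, bin_cM, max_cM, min_cM,
                     fit_max_cM=None):
    S = sum(a[0] for a in acc_list)
    n = sum(a[1] for a in acc_list)
    ones = sum(a[2] for a in acc_list)
    tot = sum(a[3] for a in acc_list)
    mbar = ones / tot
    d = np.arange(1, len(S)) * grid_cM
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = S[1:] / n[1:] - mbar ** 2
    # the fit uses the exact grid lags: averaging into wider bins and
    # assigning the bin centre flattens a steep decay (Jensen bias)
    if fit_max_cM is None:
        fit_max_cM = max_cM
    ok_lag = (n[1:] > 0) & (d >= min_cM) & (d <= fit_max_cM)
    g, A, C, converged = _fit_decay(d[ok_lag], cov[ok_lag], n[1:][ok_lag])
    # binned curve for reporting/plotting
    nbin = int(round(max_cM / bin_cM))
    bin_idx = np.minimum(((d - 1e-9) / bin_cM).astype(int), nbin - 1)
    rows = []
    for b in range(nbin):
        m = (bin_idx == b) & (n[1:] > 0)
        if not m.any():
            continue
        rows.append(((b + 0.5) * bin_cM,
                     np.average(cov[m], weights=n[1:][m]),
                     n[1:][m].sum()))
    curve = pd.DataFrame(rows, columns=["d_cM", "cov", "weight"])
    est = DateEstimate(g, "coancestry",
                       details={"A": A, "C": C, "converged": converged,
                                "m_bar": mbar})
    return curve, est


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_dates(tracts: pd.DataFrame, gmap: GeneticMap, ancestry: str,
                    method: str = "tract_mle", B: int = 1000, seed: int = 0,
                    censoring: bool = False, **kwargs) -> DateEstimate:
    """Resample individuals with replacement and re-estimate g each time.

    Returns the full-sample point estimate with `B` bootstrap draws and the
    2.5th/97.5th percentile interval; `DateEstimate.density()` gives the
    kernel-density summary of the draws.
    """
    if B < 50:
        warnings.warn("fewer than 50 bootstrap replicates gives unstable intervals")
    rng = np.random.default_rng(seed)
    inds = sorted({h.rsplit("_h", 1)[0] for h in tracts["haplotype"].unique()})
    if len(inds) < 3:
        raise ValueError("bootstrap needs >=3 individuals")

    if method == "tract_mle":
        sample = collect_tract_lengths(tracts, ancestry, gmap)
        per_len = {i: sample.subset_individuals([i]) for i in inds}
        frac = _per_individual_fractions(tracts, ancestry)

        def estimate(chosen):
            lens = np.concatenate([per_len[i].lengths for i in chosen])
            cens = np.concatenate([per_len[i].censored for i in chosen])
            rcens = np.concatenate([per_len[i].right_censored for i in chosen])
            m = np.mean([frac[i] for i in chosen])
            s = TractLengthSample(lens, cens, ancestry,
                                  np.repeat("boot", len(lens)), rcens)
            return date_from_tracts(s, m, censoring=censoring).g_hat

    elif method == "coancestry":
        res = coancestry_curve(tracts, gmap, ancestry, **kwargs)
        bin_cM, max_cM = res.bin_cM, res.curve["d_cM"].iloc[-1] + res.bin_cM / 2
        min_cM = kwargs.get("min_cM", 0.5)
        fit_max = kwargs.get("fit_max_cM", 10.0)

        def estimate(chosen):
            _, est = _curve_from_sums([res.per_individual[i] for i in chosen],
                                      res.grid_cM, bin_cM, max_cM, min_cM,
                                      fit_max)
            return est.g_hat

    else:
        raise ValueError(f"unknown method {method!r}")

    g_hat = estimate(inds)
    draws = np.array([estimate([inds[j] for j in
                                rng.integers(0, len(inds), len(inds))])
                      for _ in range(B)])
    ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
    return DateEstimate(float(g_hat), method, bootstrap_draws=draws, ci=ci,
                        details={"B": B, "seed": seed, "n_individuals": len(inds)})


def _per_individual_fractions(tracts: pd.DataFrame, ancestry: str) -> dict:
    from .sim import realized_fractions
    return realized_fractions(tracts, ancestry).to_dict()


# ---------------------------------------------------------------------------
# calendar conversion
# ---------------------------------------------------------------------------

_ORDINALS = [
    "first", "second", "third", "fourth", "fifth", "sixth", "seventh",
    "eighth", "ninth", "tenth", "eleventh", "twelfth", "thirteenth",
    "fourteenth", "fifteenth", "sixteenth", "seventeenth", "eighteenth",
    "nineteenth", "twentieth", "twenty-first", "twenty-second",
    "twenty-third", "twenty-fourth", "twenty-fifth",
]


def _ordinal(n: int) -> str:
    return _ORDINALS[n - 1] if 1 <= n <= len(_ORDINALS) else f"{n}th"


def generations_to_year(g: float, reference_year: int,
                        years_per_generation: float = 30.0) -> tuple[int, str]:
    """Convert generations before present to a calendar year and century label.

    Uses the demographic convention of 30 years per generation by default;
    e.g. g=16 anchored at 2000 gives (1520, "sixteenth century CE").
    """
    if g < 0:
        raise ValueError("g must be >= 0")
    year = int(round(reference_year - g * years_per_generation))
    if year >= 1:
        century = (year - 1) // 100 + 1
        label = f"{_ordinal(century)} century CE"
    else:
        century = (-year) // 100 + 1
        label = f"{_ordinal(century)} century BCE"
    return year, label
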