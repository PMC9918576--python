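# Methods

This note records the models behind each stage, the defaults and why they
were chosen, and the known limits of the approximations. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Forward simulation

**Model.** A Wright–Fisher population of constant diploid size N is founded
*g* generations before present by one or more admixture pulses between two
source populations and evolved to the present. Each generation every
gamete draws its parent uniformly with replacement (selfing allowed) and
receives Poisson(L/100) crossovers per chromosome of length L cM, placed
uniformly in genetic distance — no interference, no gene conversion, no
mutation, no selection. A later pulse at generation *g*′ replaces
round(*m*·N) randomly chosen individuals with fresh single-source founders.
Founding and pulse counts are deterministic (largest-remainder rounding),
so the founding proportions are exact and all residual spread in realized
ancestry is genuine drift.

**Ancestry bookkeeping.** Haplotypes are represented as tract lists
(segment end in cM, founder haplotype id), so the local ancestry of every
sampled haplotype is exact by construction; genotypes are materialized only
on demand by copying alleles from the founder panels at the recorded sites.
cM coordinates are authoritative; bp positions derive from the genetic map
(uniform 1 cM/Mb by default).

**Source panels.** Per site, an ancestral frequency p ~ U(0.05, 0.95) and
source frequencies from the Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F)
at a chosen FST; haplotype alleles i.i.d. Bernoulli. Panel sites carry no
linkage disequilibrium; founders copy whole panel haplotypes, so the
admixture-generated LD (ancestry mosaic) is the only LD in a simulated
cohort. This is deliberate: every downstream signal (tract lengths,
coancestry decay, IBD) is admixture LD, and background LD is a confounder
the synthetic data intentionally omit. Consequences: local-ancestry
inference is *harder* than on real data at equal marker density (no
haplotype structure to exploit), while IBD detection is *easier* (chance
identity runs are short); both directions are quantified in the tests.

**Scenario presets.** Five study conditions: one-wave 3:1 admixture at
g ∈ {25, 50, 100} with 126 haplotypes per source panel, and two-wave
histories adding a second minor-source pulse of 25% at generation 25 to
the two deeper settings, with 80 haplotypes per panel; N = 100, 40
individuals sampled, ~3,500 cM genome of 22 chromosomes with
human-autosome length proportions, source FST 0.15 (a French–Yoruba-scale
differentiation). Chromosome lengths are parameterized directly in cM so
that all dating theory stays in natural units.

**Drift at the study scale.** At N = 100 and g = 25 the realized cohort
minor-ancestry fraction has a standard deviation of ≈ 0.03 around the
founding 0.25 (measured over seeds; founding counts are deterministic, so
this is drift plus the 40/100 sampling). Single seeds can realize
major:minor ratios outside 2.4–3.8; only the across-seed mean is tightly
centred on 3.

## Quality control

Variant filters follow standard array practice: per-site missingness > 5%,
exact Hardy–Weinberg p < 1e-5 (conditional heterozygote-count distribution,
no mid-p), MAF < 5%, duplicate ids; then samples with > 10% missingness. A
removed site is attributed to the first rule it violates so per-rule counts
reconcile. Kinship uses the KING-robust within-pair estimator
φ = (N_het,het − 2·N_opposite-hom)/(N_het,i + N_het,j), which gives ≈ 0.5
for duplicates and ≈ 0.25 for first-degree pairs without needing allele
frequencies; pruning removes, greedily, the sample with the most pairs at
φ ≥ 0.0442 (the conventional third-degree cutoff), ties broken by sample
order. LD pruning slides 50 kb windows in 5-SNP steps and drops the later
site of any pair with r² > 0.5 (keep-earlier makes it deterministic).

## Local ancestry (two-state haplotype HMM)

Each phased haplotype is decoded independently. Emissions are the panel
allele frequencies clipped to [ε, 1−ε] (ε = 0.01 absorbs genotype error
and panel sampling noise); transitions over d cM are
(1−e^(−g·d/100))·π_k toward state k, the pulse-admixture switch process
scaled by prior ancestry fractions π. The prior starts at (0.5, 0.5) and
is re-estimated once from the mean posterior (one EM-style round), so no
external global-ancestry estimate is needed; g defaults to 25 and acts
only as a smoothing scale. Tracts are Viterbi runs with boundaries midway
between flanking sites; calls shorter than 0.5 cM are absorbed into the
higher-posterior neighbour to suppress switch noise. At FST 0.2 and ~10
markers/cM the per-site accuracy against truth tracts exceeds 90%; at
sparser marker density the HMM misses short minor tracts, which biases
inferred tract lengths long (and therefore inferred-tract dates low) —
the dating experiments run on truth tracts for exactly this reason, and
the pipeline's inferred-tract dating inherits the marker density of its
input.

## Ancestry-specific PCA

Masked haplotypes (alleles outside target-ancestry tracts set to missing)
are embedded with reference haplotypes by classical MDS (double centering,
top eigenpairs) of Euclidean distances on 0/1 alleles. Missing sites are
handled by rescaling: d(i,j) = sqrt(S·M/C) with S the squared-difference
sum over the C jointly observed sites and M the total site count — the
unbiased expected distance when masking is independent of the reference
contrast. Pairs with no joint sites are an error, except in the joint
sanity embedding of complementary maskings, where such distances are
imputed from the cohort-mean mismatch rate. Source attribution uses
per-query-haplotype mean embedding distances to each reference population
and a Welch two-sided t-test between the two candidate sources; the paired
structure of the arms informs only the reported direction. Two output
dimensions by default; sites are LD-pruned on the pooled references with
the QC parameters first.

## Admixture dating

*Tract MLE.* Minor-ancestry tract lengths under one pulse are
Exp(g(1−m)/100) per cM. Default estimator: drop chromosome-end tracts and
use ĝ = 100/(L̄(1−m̂)), with m̂ the realized cohort fraction from the same
tract set. Censoring-aware option: λ̂ = n_events/Σ lengths, where an event
is a tract whose *right* end is interior — left truncation is harmless by
memorylessness, so tracts touching the chromosome start still contribute
exposure and (if their right end is interior) an event.

*Coancestry curve.* The ancestry indicator is sampled on a 0.25 cM grid
per haplotype; lagged products are accumulated by FFT autocorrelation and
cov(d) = E[I(x)I(x+d)] − m̄² is fitted with A·e^(−g·d/100) + C by weighted
nonlinear least squares (log-linear initialisation) on the exact grid
lags. The fit uses distances in [0.5, 10] cM even though the curve is
reported out to 30 cM: below 0.5 cM the indicator saturates within
tracts, and beyond the pulse decay length the covariance is dominated by
drift-generated relatedness, which decays far more slowly than the pulse
signal and drags a single-exponential fit toward shallower decay (a
~20% downward date bias at g = 50 with a 30 cM window, measured on
simulated truth; the constant C absorbs only the flat part of it).

*Known bias.* Both estimators are mildly biased low on forward-simulated
cohorts at N = 100 (≈ 5–15%, growing with g): neighbouring tracts are
correlated through recent coalescence, so minor-ancestry runs merge
slightly more often than the binomial (1−m) theory assumes. The recovery
tests budget for this within their ±20% tolerance.

*Recent pulse of a two-wave history.* Tracts longer than 15 cM are
essentially absent from a g ≥ 50 pulse (P < e^(−4)), so the excess length
over that threshold is exponential with the recent pulse's rate; the
censored MLE on the excesses dates the recent pulse. The 15 cM default
balances contamination from the old pulse (< ~10% of tail tracts for the
study's settings) against tail sample size.

*Bootstrap.* Individuals are resampled with replacement; per-individual
tract lists and per-individual coancestry lag sums are precomputed so each
of the B = 1000 replicates is a cheap re-aggregation. Reported: point
estimate, 2.5/97.5 percentiles, and a kernel-density summary of the draws.
Calendar conversion uses 30 years per generation.

## One- vs two-wave discrimination

The bootstrap KS test reconstructs the pooled-resample null: both
resamples are drawn from the pooled data, p = (1 + #{D* ≥ D})/(1 + nboot),
which is tie-robust and never exactly zero. Comparisons run on the full
length distributions and on the ≤ 10 cM subset (where most segments lie);
scenarios are ranked by D, and with thousands of segments per side even
the best-fitting scenario can have p below α — the ranking, not the
p-value, identifies the best fit, while the p-values reject the deep
one-wave alternatives.

## IBD and ancestry-specific Ne

*Detection.* Maximal allele-identity runs between haplotypes of different
individuals, ≥ 2 cM by default (≥ 1 cM in the recovery experiments, where
marker density makes chance runs negligible: at ~50 markers/cM a 1 cM
chance run has probability ~3e-8 per start). Optionally, runs chain
across isolated mismatches up to a mismatch-per-cM budget. Gap merging
joins segments of a pair across gaps < 0.6 cM containing ≤ 1
IBD-inconsistent site; the operation is idempotent.

*Labeling.* Each segment gets an ancestry proportion = mean over its two
haplotypes of the target-ancestry fraction of its span, then a Bernoulli
label at that proportion from a dedicated seed stream — unbiased for
per-ancestry total IBD length, and ancestry-unaware results are untouched
by the labeling draw.

*Ne inversion.* A pair coalescing t generations ago yields
L·r·(e^(−ra)−e^(−rb)) expected segments with length in [a,b), r = 2t/100
per cM, and the per-generation coalescence probability under
piecewise-constant Ne is x_i = 1/(2Ne_i). Counts in 12 log-spaced length
bins are therefore linear in the x_i; the design matrix keeps every
cross-bin contribution (a length bin receives segments from all
coalescence times, which a bin-by-bin inversion ignores at large cost),
nuisance generation bins absorb coalescence more recent and older than the
reported 4–50 range, and the cohort's known founding depth truncates the
model. The system is solved by non-negative least squares with
Poisson (√count) weighting and a first-difference smoothing penalty on the
x_i — without smoothing the inversion is ill-conditioned because adjacent
generation bins have nearly collinear length profiles. Ancestry-specific
modes use the assigned segments with the pair count adjusted to
haplotype-equivalents n_eff = n_haplotypes × ancestry fraction,
pairs = n_eff(n_eff−1)/2. Intervals come from resampling chromosomes with
replacement (80 replicates, 2.5/97.5 percentiles).

*Validity regime.* Identity-run detection merges adjacent IBD segments
with different coalescence times into one run. This is negligible when
total pairwise IBD coverage is small, i.e. when the maximum generation of
interest t_max ≪ 2N. At N = 100 and t_max = 50, ~25% of a random pair's
genome is within-pedigree IBD and run merging destroys the count-length
relation for *any* count-based estimator on identity runs; the constant-N
recovery experiment therefore runs at N = 1000 diploids, founded 80
generations back, with 2,000-haplotype founder panels (collisions among
founders otherwise mimic extra ancient coalescence). Under those
conditions the recovered trajectory is flat at the simulated level. The
five-run cohort suite (ancestry-unaware, each ancestry, each ancestry
excluding individuals above 50% target ancestry) and the reference-only
run share this estimator.

## Numerical and engineering choices

- All randomness flows from integer seeds through `numpy.random.default_rng`;
  per-generation batching of Poisson/uniform draws keeps the simulator at
  ~10 µs per meiosis without changing the model.
- Tract and IBD tables are plain pandas DataFrames with cM floats; bp are
  1-based in VCF and 0-based half-open in TSVs (stated in file headers).
- VCF round-trips store per-site cM in an INFO string field to preserve
  precision; reading uses cyvcf2.
- Greedy tie-breaks (kinship pruning, LD keep-earlier), strict-vs-inclusive
  conventions (ancestry-threshold selection is ≥; merge gap is < 0.6), and
  the exact-HWE no-mid-p formulation are fixed and tested at their
  boundaries.
- Degenerate inputs fail loudly: zero-variance concordance, all-censored
  tract samples, pairs with no joint sites, empty KS samples, < 4
  haplotypes for Ne.

## Problem sizes used by the test suite

The recovery experiments run at the study conditions (3:1, N = 100, 40
individuals, 3,500 cM, ≥ 20 seeds) for the dating and fraction checks;
the two-wave KS experiment uses a 1,200 cM genome at the same sample
sizes (the comparison operates on thousands of segments either way); the
ASPCA and Ne experiments use 200 cM genomes at marker densities chosen so
that detection noise is negligible (10 and 50 markers/cM respectively).
The ASPCA attribution experiment runs a 1:1 founding mix at N = 500 so
the 50% selection threshold sits inside the bulk of the per-individual
proportion distribution in every seed — at N = 100 the cohort mean
drifts across the threshold and the selected set can be empty; the Ne
experiment runs at N = 1000 for the sparse-IBD reasons given above.
These sizes are the package's chosen verification scale; the code itself
is size-agnostic.

## Limitations

- Two ancestries only; no three-way or continuous admixture models.
- The HMM does not model background LD, so its accuracy on real dense
  panels is not predicted by the synthetic experiments (likely higher, as
  real haplotype structure adds information a forest/conditional-random-field
  method exploits).
- The Ne estimator is a transparent moment method, not a full
  segment-likelihood model; absolute levels outside its sparse-sharing
  regime (t_max approaching 2N) are unreliable, as documented above.
- Tract-based dating assumes pulse (instantaneous) admixture; continuous
  gene flow biases dates toward the midpoint of the flow period.
- Calendar anchoring requires a user-supplied reference year.
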