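# Methods

This note documents the models, the estimators, the synthetic-data
generator and the numerical choices made where the design was genuinely
open.  It states no empirical result that the test suite does not itself
compute.

## Model 1: histone dilution at the replication fork

The chromatin around a replication fork is a lattice of R loci
(rows) x N nucleosome sites (columns).  Every site carries a histone;
one locus R* carries tagged histones.  One cell cycle is:

1. **Transfer.** Columns are processed serially j = 1..N; transfers never
   cross columns.  This encodes the assumption that a dislodged histone
   finds its new site before the fork dislodges the next one —
   equivalently, histone diffusion is fast relative to fork progression.
   Every histone in the column samples a daughter lattice (probability
   1/2 each; diffusion is undirected, so deposition is symmetric) and a
   destination row from the kernel row

       K[i, i'] ∝ (4πDT)^(-1/2) · exp(-x_{i,i'}² / (4DT)),   x = |i-i'|.

2. **Refill.** Empty daughter sites receive new, untagged histones.
3. **Promotion.** One daughter becomes the next parent (probability 1/2).

The tagged fraction at R* is recorded each cycle; its decay rate is
controlled by D.

**Normalization.** The Gaussian is a continuous density; on a finite
lattice it is renormalized per source row so each row of K sums to 1 — a
histone must land somewhere.  A consequence worth noting: renormalization
breaks the symmetry of K (edge rows have less Gaussian mass, hence larger
normalizing factors), although the unnormalized weight matrix is exactly
symmetric.  Tests assert row-stochasticity of K and symmetry of the
weights.

**Identifiability.** Only the product D·T enters K.  T is fixed to 1 and
D is the single free parameter, in arbitrary lattice units; fitted values
are not physically interpretable (the lattice is 1D and distances are
dimensionless).

**Collision handling (open design point).** One histone per site.  Within
a column, histones are processed in a uniformly random order; each
samples (daughter, row) from the product measure; an occupied target
triggers resampling; after 100 rejections the histone is placed uniformly
on one of the remaining empty sites of the column.  With 2R sites for at
most R histones this always terminates, and the fallback bounds the
worst-case cost.  The processing order, the per-histone (rather than
per-column) daughter choice, and the rejection rule are explicit choices;
the underlying process description does not pin them down.  A brute-force
enumeration of the R=2 single-column instance is frozen in the tests and
matched by the simulator within Monte-Carlo error.

**Expectation oracle.** Ignoring site exclusion, the expected tagged-count
vector evolves as v_{g+1} = (1/2)·Kᵀ v_g (the transpose propagates counts
to destinations), giving a deterministic dilution curve f(g) with
f(0) = 1, non-increasing, and f(g) = 2⁻ᵍ for the identity kernel.
Exclusion makes the simulation decay slightly more slowly than the
oracle; at half occupancy (R histones into 2R sites) the tests bound the
discrepancy at 5% relative for the R = 9 reference case.

**Fitting.** `fit_diffusion_constant` minimizes the sum of squared
differences between the observed mean curve and the model mean curve at
the observed generations.  Search: a 25-point logarithmic grid on the
search interval, then bounded scalar minimization on log10(D) between the
bracketing grid cells (relative tolerance 1e-3).  The model mean is the
oracle by default — fast, deterministic, and accurate to a few percent —
with an option to use the stochastic simulator mean (fixed seed at every
candidate D so the objective stays smooth).  A flat objective across the
interval sets a warning flag instead of failing.  If the best grid point
is an edge, the edge is returned (e.g. an exact halving curve drives D to
the lower edge).

**Random numbers.** One root seed expands to per-replicate child streams
via `default_rng([seed, replicate])`, so changing the replicate count
never reshuffles earlier replicates.  All simulations are bit-reproducible
from their seed; the replication inner loop is numba-compiled with an
identical pure-Python fallback (same RNG call sequence).

## Model 2: emergence of mark-similarity patterns

Rows are split into Early (first R/2) and Late (last R/2) replication
compartments, proxies for eu- and heterochromatin.  States are: mark of
interest ("1"), other marks ("2"), empty.  Initialization draws the
per-row count of "1"s from an exponential distribution (mean 130 by
default, 200 columns), rounded and clipped to [0, N]; the rest are "2"s.
Defaults follow the headline simulation: R = 20, N = 200, D_EE = 1.2,
D_LL = 0.07, checkpoints {0, 2, 8, 50}, 100 repetitions.

Transfer mechanics are identical to Model 1 except:

- distances are compartment-scaled, x = s_c·|i-i'| with s_E = 2 > s_L = 1
  (early loci are less compact, so same-compartment early pairs sit
  further apart on average).  The exact distance-assignment rule is an
  open design point; simple compartment scaling satisfies the only stated
  constraint (mean EE distance > mean LL distance) and both factors are
  config-exposed.
- the kernel is block-diagonal: D_EE within Early, D_LL within Late, and
  no cross-compartment transfer (donor and acceptor must replicate at the
  same time; Early and Late do not).  A config switch can disable the
  D_EE > D_LL check for exploration, and `no_diffusion=True` replaces the
  kernel with the identity (the control in which no pattern may emerge).

**Mark copying.** After transfer, empty daughter sites repeatedly adopt
the mark of a uniformly chosen non-empty horizontal neighbour (same row,
adjacent column; boundary sites have one neighbour) in synchronous passes
until none remain.  A row that received no histones at all is filled with
"2"s — new histones with no parental mark to copy; the source process
does not cover this corner.  Mark copying prevents mark levels from
diluting to zero and is what stabilizes the emergent patterns; its
precise mechanism is irrelevant to the diffusion results.

**Signals and Q.** After each checkpointed cycle (on the promoted
daughter, after copying), signal_i = number of "1"s in row i, and
Q(i₁,i₂) = |log10(signal₁/signal₂)| for every within-compartment pair,
tagged with the scaled distance.  Distances are binned separately per
compartment class when slopes are estimated; the distance axis is
conventionally plotted negated so that "closer" lies to the right, as
with Hi-C proximity.

Three patterns emerge by ~50 cycles and are verified by the tests at the
full simulation scale: (1) median Q_EE < median Q_LL at every shared
distance bin; (2) median Q increases with distance in both compartments
(slope bootstrap over repeats, one-sided 95%); (3) the LL slope is
steeper.  Controls: at checkpoint 0 the classes are indistinguishable; the
mean Early-minus-Late signal stays centred on zero (diffusion is
undirected); the no-diffusion run shows none of the three patterns.

## The Q statistic and its summaries

Q is symmetric, non-negative, zero iff the signals are equal, and
invariant to common rescaling.  Pairs with a non-positive signal have no
defined Q; they are excluded and counted, never silently dropped and
never patched with a pseudocount (a pseudocount option exists but
defaults off).

- **Binned medians:** right-open bins [lo, hi), last bin closed; empty
  bins are flagged.  Equal-count (quantile) edges are used for continuous
  grouping variables such as Hi-C proximity; equal-width edges for
  lattice distances.  Bin edges always accompany results.
- **Slopes:** ordinary least squares of per-bin median on bin centre,
  with standard error.
- **Chance median:** the median Q of 10000 randomly drawn unordered pairs
  of distinct loci from one class (with replacement across draws) — the
  similarity expected from the class's signal distribution alone.
- **ΔΔ:** per bin, (MedianQ_LL − MedianQ_EE) − (chance_LL − chance_EE).
  Positive ΔΔ at low spatial proximity is the diffusion signature.

## The epigenome pipeline

Inputs: chrom.sizes, early/late Repli-seq bedGraphs, per-mark narrowPeak
files (signalValue is the peak height Hₚ; 5-column BED with a score
column is also accepted), and a dense tab-delimited Hi-C matrix with
`chrom:start-end` labels at the binning resolution.  Coordinates are
0-based half-open throughout.

1. **Binning:** fixed 1 Mb tiling, last bin truncated.
2. **Classification:** per-bin early and late scores are sums of
   value x overlap-bp (invariant to bedGraph fragmentation).  A bin is
   EARLY iff early − late > +cutoff, LATE iff < −cutoff, else
   UNCLASSIFIED; strict inequalities, default cutoff 1000.  Conclusions
   are insensitive to halving the cutoff (checked on the synthetic
   fixture).
3. **Peak aggregation:** a peak contributes Hₚ x (overlap width) to every
   bin it overlaps — total peak mass is conserved across bin boundaries
   (midpoint assignment would not be).
4. **Spatial proximity:** Pearson correlation between two bins' rows of
   the contact matrix, computed over all columns except the two bins' own
   (self-contact masked).  The matrix is expected to be normalized
   already; the pipeline does not re-implement matrix balancing.
   Alternative metrics: raw observed counts, and observed/expected
   enrichment where the expectation is the mean intra-chromosomal count
   at each separation (pooled across chromosomes) and the global
   inter-chromosomal mean.  All-zero rows are flagged and excluded.
   Row correlations are taken over the whole genome-wide matrix (not per
   chromosome pair).
5. **Pairs and summaries:** all unordered EE (both EARLY) and LL pairs,
   optionally restricted to intra- or inter-chromosomal scope;
   zero-signal pairs dropped and counted.  Proximity bins are equal-count
   edges computed on the *pooled* EE+LL proximity values so both classes
   (and hence ΔΔ) share edges; the default is 8 bins, fine enough that
   the top bin isolates genuinely proximal pairs.

**Pattern calls.** Pattern presence is a directional claim, so
`pattern_directions` combines the point-estimate direction with a
one-sided 95% bootstrap bound: (1) Q_EE < Q_LL in every shared bin and
the minimum per-bin gap's lower bound above 0; (2) both slope upper
bounds below 0; (3) |slope_LL| − |slope_EE| lower bound above 0.  The
bootstrap resamples *loci* (bins), not pairs: all pairs sharing a locus
are statistically dependent, and a pair-level bootstrap would be
anti-conservative.  `pattern_signs` exposes the bare directions for
robustness comparisons (e.g. across cutoffs).

## Synthetic data

The generator produces every input the pipeline needs, with known ground
truth.  It emulates the statistical structure the analysis relies on —
not read-level realism.

- **Genome:** 8 chromosomes x 60 Mb at 1 Mb bins (480 bins).
  Replication classes alternate in 6-bin blocks.  Per-bin timing-score
  differences are bimodal (modes ±3000, sd 800, aggregated-score units)
  so nearly every bin clears the ±1000 cutoff; each bin's bedGraph entry
  is split at a random interior point to exercise fragmentation
  invariance.
- **Latent geometry:** every bin gets a 1D "nuclear coordinate"
  u = chromosome offset + 0.5 x bin position, offsets drawn uniformly
  over seven chromosome spans so territories interleave.  Spatially
  close same-class pairs — on the same chromosome or not — both contact
  more often (Hi-C plaid) and carry more similar mark signals, which is
  exactly the coupling a diffusion process would create and the pipeline
  is designed to detect.  Making similarity decay with genomic
  separation instead would leave the dominant inter-chromosomal pair
  population uninformative.
- **Mark signals:** per class, log10 signals are a Gaussian field over u
  with triangular correlation corr = max(0, 1 − |du|/range) — the
  covariance of a moving average, giving strong local correlation with
  exact independence beyond the range (many independent field patches,
  hence stable binned medians at this genome size; an exponential tail
  would leave too few).  For a pair with correlation ρ the median Q is
  0.6745·σ·sqrt(2(1−ρ))/1, analytically controllable.  Defaults:
  - `planted` (DAD-structured): σ_E = 0.2 < σ_L = 0.8,
    range_E = 20 ≥ range_L = 12 — plants all three patterns;
  - `null`: equal σ, no spatial structure — plants none;
  - `constitutive_like` (an H3K9me3 analogue): σ_E = 0.45 > σ_L = 0.3,
    no spatial structure — LL pairs *more* similar, no distance
    dependence, the negative control.
- **Peaks:** each bin's target aggregate 10^(log signal) is split over
  1–10 peaks with random widths (200–2000 bp) and Dirichlet mass
  fractions; heights are set so Σ Hₚ·Wₚ equals the target exactly.
- **Hi-C:** intra-chromosomal base 15·(1+sep)^(−0.6), inter base 1,
  times (1 + 2·max(0, 1 − |du|/6)) for same-class pairs, times symmetric
  lognormal noise (sd 0.15).  The mild decay and visible plaid emulate a
  *normalized* contact matrix — on raw-count-like matrices Pearson row
  correlations between different chromosomes are near-degenerate, which
  is why proximity is defined on normalized matrices in the first place.
- **Dilution curves:** the deterministic oracle for a known D plus
  independent Gaussian noise, clipped to [0, 1], generation 0 pinned
  at 1.

What passing tests show — and what they do not: the pipeline provably
recovers planted covariance structure of this form and rejects nulls at
the stated rates; real ChIP-seq/Hi-C data have heavier tails, mappability
artefacts, copy-number effects and normalization quirks that the
generator does not emulate, so the tests validate the machinery, not any
claim about a particular organism or cell line.

## Problem sizes and tolerances

Test and acceptance runs use: dilution at R = 9, N = 50 with 500–2000
replicates; mark simulations at the full printed scale
(R = 20, N = 200, 100 repeats, 50 cycles); pipeline recovery over 20
seeded synthetic genomes of 480 bins, with 200 bootstrap resamples per
call.  Monte-Carlo comparisons use 3 standard errors; the
oracle-vs-simulation gap allows 5% relative (the measured exclusion bias
is 2–4%); parameter recovery allows 10% on oracle-generated curves and
25% on stochastic ones.  Kernel row sums are exact to 1e-12.

## Known limitations

- Diffusion is 1D on a dimensionless lattice; fitted D values have no
  physical units and cannot be compared to FRAP/FCS measurements.
- Lattice distance x and Hi-C spatial proximity are related only
  monotonically, so model-to-data comparisons are qualitative by design.
- The dense-matrix Hi-C reader targets desk-scale inputs (hundreds to a
  few thousand bins); genome-wide 1 Mb matrices fit, but no sparse or
  chunked path is provided.
- The Pearson proximity computation is O(n³); at a few thousand bins it
  is minutes, not seconds.
- The chance-median draw is with replacement across draws and excludes
  self-pairs; alternative conventions would shift the baseline by O(1/n).
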