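# Methods

This note documents the models, formulas, numerical choices and known
limitations behind `oritools`. It is written for users who need to know
exactly what each number means, in the spirit of the methods documentation
of packages like statsmodels or msprime.

## Sorted-population copy-number model

SortSeq infers per-locus S-phase copy number by sequencing flow-sorted
S-phase and G2-phase cell populations. A locus that replicates at the very
start of S-phase is present in two copies in essentially every sorted
S-phase cell (copy number 2); a locus that replicates at the very end is
present in one copy (copy number 1). Assuming uniform cell density across
S-phase within the sort gate, a locus replicated at time `t` in an S-phase
of length `T` has expected sorted-population copy number

    c(x) = 1 + max(0, (T - t(x)) / T),

bounded in [1, 2]. The uniform-density assumption is the simplest reading
consistent with a 1-to-2 scaled profile; it is isolated in the simulation
configuration so alternatives can be substituted.

### Firing model in the generator

Each origin fires independently (Bernoulli with per-origin efficiency) at a
fixed time; forks move at constant speed and replicate passively through
silent origins; forks do not cross chromosome boundaries. The replication
time of a position is the earliest fork arrival among origins that fired:
`t(x) = min_o (t_o + |x - pos_o| / v)`. The default truth track is the
*exact* expectation over firing configurations, computed by sorting per-
position arrival times and summing `r(a_k) e_k prod_{j<k} (1 - e_j)` over
"origin k's fork arrives first among those that fired". A Monte-Carlo mode
(`SimulationConfig.n_firing_draws > 0`) samples firing configurations
instead; the exact sum is what the sampling converges to, and the test
suite verifies both against brute-force enumeration of all `2^n` firing
states on small problems.

Sequencing counts are Poisson by default (negative binomial with a
dispersion parameter optionally), with expected S coverage
`read_depth * c(x)` and flat expected G2 coverage.

## Processing chain

Per sample: (1) coverage is normalized so the genome-wide per-bp mean is
exactly 1; (2) S and G2 are averaged in 1 kb bins (a partial terminal bin
averages only its own width) and divided, bins with zero G2 coverage
becoming undefined; (3) ratios beyond the Tukey fences `Q1 - 1.5 IQR` /
`Q3 + 1.5 IQR` (linear-interpolation quantiles, genome-wide, strict
inequalities) are removed; (4) surviving ratios are min-max scaled into
[1, 2]; (5) each chromosome is smoothed with a cubic smoothing spline.
Replicates are then summarized per bin by the mean and a t-based 95%
confidence half-width (`t_{0.975, n-1} * sd / sqrt(n)`); bins defined in a
single replicate keep their mean with an undefined interval. Confidence
intervals are computed on smoothed values, matching profiles that draw
shaded bands around smoothed replicate means.

### Smoothing spline

The smoother minimizes `sum_i (y_i - f(x_i))^2 + lambda * int f''(t)^2 dt`
over natural cubic splines, solved in the Reinsch / Green & Silverman
formulation: `(I + lambda K) g = y` with `K = Q R^{-1} Q^T` built from
knot spacings, followed by natural
cubic interpolation through the fitted knot values (which reproduces the
exact minimizer). `lambda` defaults to the minimizer of the generalized
cross-validation score `n * RSS / tr(I - A)^2`, evaluated cheaply through
one symmetric eigendecomposition of `K` per chromosome grid. x is measured
in bins, so quoted `lambda` values refer to that scale. Bins removed as
outliers are omitted from the fit; the fitted spline fills gaps of at most
10 bins, larger gaps stay undefined to avoid bridging filtered regions.
As `lambda -> infinity` the fit tends to the least-squares line; tests
exercise this limit at `lambda = 1e9` (beyond ~1e10 the dense solve loses
the identity block to conditioning, which bounds how literally the limit
can be checked numerically).

## Origin activity and classification

Each origin's S-phase statistic is the median of the ten 1 kb bin means in
a 10 kb window centered on the ORC-site start (the first nucleotide of the
T-rich strand, rel position 0). Because origins rarely sit on bin
boundaries, the window is realized as the block of 10 consecutive bins
minimizing the symmetric difference with the ideal centered window, ties
broken leftward. Only defined bins enter the median; records with fewer
than 10 defined bins or chromosome-end truncation are flagged, and records
with no defined bins are unevaluable.

The per-origin effect size is `log2(mutant / wild-type)` of these
statistics. Classification uses inclusive thresholds: `<= -0.1` positive
(the regulator promotes the origin), `>= +0.1` negative, otherwise
"other". Timing tertiles cut the 1/3 and 2/3 linear-interpolation
quantiles of either scaled copy number (higher = earlier) or Trep minutes
(lower = earlier), boundary ties going to the earlier tertile. Group
densities are Gaussian KDEs (Silverman bandwidth by default) on a shared
grid spanning the pooled range plus three bandwidths. Group overlap is
scored by the upper-tail hypergeometric probability
`P(X >= observed)` with population = universe, successes = |A|, draws =
|B|; the choice of the hypergeometric law for overlap significance is a
package assumption, labelled in output. Centromere association is
`orc_start` within `[cen_start - 10 kb, cen_end + 10 kb]`, inclusive.

## Motif architecture

The forkhead-site model is an input: an 8 bp log-odds matrix over a
background base distribution with a score threshold. Scanning scores every
window on both strands (windows containing N are skipped; other letters
are rejected); coordinates refer to the forward-strand leftmost base.
The stringent subset keeps the top quantile (default 25%) of matches by
rank, retaining ties at the cut score.

Matches are projected into ORC-site-relative coordinates: for minus-strand
origins positions are mirrored so the T-rich strand reads left-to-right,
and orientation is FKH-T when the match strand equals the origin's T-rich
strand, FKH-A otherwise. The three canonical regions are 5' FKH-T
(-150..-11), 3' FKH-A (+41..+150) and ORC-overlapping FKH-T (-10..+40);
region membership requires any overlap of the 8 bp footprint with the
(inclusive) interval. Note the ORC-overlapping interval follows the
figure-legend convention (-10..+40); the alternative -11..+41 phrasing
found elsewhere can be configured via `RegionSpec`. Enrichment against the
origin universe is hypergeometric in both tails, with significance tiers
0.05 / 0.001 / 0.0001.

Accumulation curves walk 5' (leftward from rel -1) or 3' (rightward from
the first position past the ORC site, +33 for the default 33 bp site) and
record, per distance d, the fraction of origins whose nearest correctly
oriented match footprint overlaps the walked interval; by construction
`curve(span)` equals the region fraction over the same interval, an
identity asserted in tests. The half point is the first distance at which
the curve reaches 0.5. 5' distances are measured from rel -1 (not from the
-11 region boundary), a convention choice.

## MNase footprints

The occupancy matrix counts, per fragment length (default rows 50..200 bp)
and origin-relative position, every position a fragment's footprint covers
inside a locus window (strand-mirrored; a midpoint-only mode exists).
Fragment-size classes: nucleosomal 142–162 bp and subnucleosomal
121–141 bp (digestion-stability classes), nucleosome-consistent
147 ± 10 bp and ORC/Cdc6-consistent 80 ± 10 bp (footprint classes), all
inclusive.

* `class_signal` — column sums over a class's rows.
* `stability_ratio` — per position,
  `[(nuc+psi)/(subnuc+psi)]_mutant / [(nuc+psi)/(subnuc+psi)]_wildtype`
  with pseudocount `psi = 1` count by default (configurable); positions
  with zero signal in both classes for either genotype are undefined.
* `scaled_fraction_signal` — the class share of the total signal at each
  position, min-max scaled to [0, 1] per curve (per-curve scaling matches
  independently scaled panels; a shared scale can be applied externally).

For localization claims (where the NDR bottoms out, where the ORC/Cdc6
footprint peaks) the scaled fraction signal is the right object: raw
column sums of an ~80 bp footprint class form a flat-topped plateau whose
argmax is decided by noise, while the class *share* peaks sharply inside
the nucleosome-depleted region.

ChIP-style tracks are normalized internally: IP and input are each divided
by their totals, the per-bp ratio taken (undefined where input is zero),
and defined ratios rescaled to mean 1. This concrete definition of
"internal normalization" is a package assumption recorded here.

## Fragment generator

Fragment lengths come from a Gaussian mixture (rounded, floor 1 bp).
Class counts follow the mixture weights exactly (largest-remainder
allocation, i.e. stratified sampling of the mixture): this keeps library
composition identical between independent draws so that between-sample
comparisons reflect positional sampling noise rather than compositional
drift, which a multinomial allocation would add. Anchors: nucleosome-class
midpoints sit on planted dyads (165 bp spacing, excluded within the NDR
half-width of every ORC-site start), ORC-class midpoints are drawn around
the ORC-site center (sd = site length / 6, clipped to the site),
background midpoints are uniform. Fragments are shifted to stay inside
their chromosome.

All generators derive independent substreams from one root seed via
`numpy.random.SeedSequence([seed, stream_id, extra])` with fixed stream
ids (S counts 0, G2 counts 1, firing draws 2, fragments 3, signal tracks
4), so identical seed + configuration reproduce outputs bit for bit.

## Canned validation scenarios and problem sizes

Two study designs ship with the package (`oritools.simulate`) and are used
by the tests and `scripts/acceptance.py` (`oritools.benchmarks`):

* **Replication recovery** — a 2 x 500 kb genome with 40 origins at 25 kb
  spacing, fork speed 1 kb/min, 60 min S-phase, Poisson 50x depth, 3
  wild-type + 2 mutant replicates. Twelve early origins (t = 10 min,
  efficiency 0.90) lose 25% of their efficiency in the mutant; twelve late
  origins (t = 42 min, 0.25) rise to 0.55; sixteen fillers/anchors are
  neutral. The geometry isolates each target from rescuing forks (a
  neighbor 25 kb away firing at 45 min cannot passively replicate it
  within S), so the planted efficiency changes translate into log2 effects
  of about -0.17 and +0.13 — detectable but not trivially large. Two very
  early anchors pin the genome-wide maximum in both genotypes so min-max
  scaling does not absorb the planted differences. Structurally, a couple
  of fillers with one-sided fork rescue sit near the -0.1 boundary; they
  account for the few-percent neutral misclassification rate the
  acceptance script reports.
* **Chromatin footprints** — 50 origins (alternating strands) whose
  ±500 bp windows tile a chromosome, dyads every 165 bp outside a ±80 bp
  NDR, and a G1-like mixture (55% nucleosome 150±8, 20% ORC-site 80±5,
  25% background); 200k fragments. For the identical-parameter stability
  comparison, 100 origins spaced 500 bp (overlapping windows double the
  per-column counts) with a two-band mixture (25% + 25% nucleosome
  152±6 / subnucleosome 131±6, 5% ORC, 45% background) keep per-position
  sampling noise comfortably inside the ±5% band; the background floor
  keeps NDR-adjacent columns countable.

These sizes run the whole validation in a few minutes on one CPU and were
chosen as the smallest designs in which the planted effects are
unambiguous.

## What the generator does and does not emulate

It reproduces the statistical structure the analyses assume: copy numbers
between 1 and 2 with peak/slope/valley geometry, replicate-to-replicate
counting noise, origin-anchored fragment-length mixtures with an NDR, and
Gaussian ChIP enrichment over flat input. It does not model read-level
artifacts (mappability, GC bias, duplicates), MNase sequence bias,
checkpoint feedback, variable fork speed, or correlated origin firing.
Passing recovery tests therefore demonstrates that the pipeline's
estimators are correct and well-calibrated under the stated model, not
that they are robust to every artifact of real libraries.

## Degenerate inputs and tie-breaks

All-zero coverage, empty origin groups, empty universes, non-positive
thresholds and negative pseudocounts raise errors; zero-G2 bins, filtered
bins and zero-input positions become NaN and propagate as "undefined"
rather than 0 or infinity. With IQR = 0 no bin is an outlier (strict
fences); with all timing values tied every origin is "early" (with a
warning); quantile ties at the motif-score cut retain all tied matches;
the window-bin choice breaks ties leftward; classification thresholds are
inclusive exactly as written.

## Known limitations

* The activity statistic conflates an origin's own firing with passive
  replication by neighbors; closely spaced origins shadow each other (the
  same limitation the windowed median has on real profiles).
* GCV can undersmooth short chromosomes with few defined bins.
* The hypergeometric overlap test treats origins as exchangeable; any
  spatial correlation between groups is ignored.
* Stability ratios at sparsely covered positions (NDR interiors) are
  noise-dominated at desk-scale fragment counts; the pseudocount bounds
  but does not remove this.
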