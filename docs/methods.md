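# Methods

## Demographic model and simulation

The default demography is a single panmictic population with, backwards in
time: exponential growth at 0.017 per generation from a present-day size of
4×10⁶ diploids back to 7700 at 368 generations ago (7700·e^(0.017·368) ≈
4×10⁶, so the three numbers are mutually consistent); constant sizes of
7700 on [368, 3500), 24,500 on [3500, 17,000) and 12,500 earlier. Epochs
are user-configurable as `(start_time, size, growth_rate)` triples, so
alternative histories (no-growth variants, constant-size controls, other
published models) can be supplied directly.

Regions default to 20 Mb with mutation rate μ = 1.2×10⁻⁸ and recombination
rate r = 1×10⁻⁸ per bp per generation; the constant map makes 1 cM ≡ 1 Mb,
and a single `GeneticMap` utility owns that conversion. The coalescent
engine is msprime's exact Hudson algorithm — any engine producing marginal
trees at every position would do, and we cross-check the expected
segregating-site count against a hand-written single-locus
time-inhomogeneous coalescent in the tests (Watterson's 4NμL·H_{n−1} under
constant size). Haplotypes are paired uniformly at random into diploid
individuals. No genotyping error or missingness is injected.

Array-like data are produced by dropping variants with MAF < 5% and
retaining the remainder independently with probability proportional to a
user-supplied spectrum weight (flat by default), scaled so the expected
marker count equals the target density (5800 per 20 Mb). The realised
count therefore fluctuates around the target, as it would under empirical
spectrum matching.

## Ground-truth IBD extraction

A pair of haplotypes is IBD over a maximal stretch of unchanged TMRCA.
Full enumeration over every marginal tree for every pair is expensive, so
the extractor uses two approximations: genealogies are sampled on a
regular 0.01 cM grid (boundary resolution is therefore one grid step), and
only pairs with TMRCA below 3000 generations are followed, which bounds
the number of open runs in memory. Runs are closed when the pair's TMRCA
value changes or exceeds the bound; emitted intervals span from the first
to one-past-the-last grid point of the run, and segments shorter than
0.2 cM are dropped. TMRCA equality is exact float equality — marginal-tree
times come from a common source; engines that jitter times can use a
relative tolerance.

Per grid point the extractor enumerates, in one postorder pass, all pairs
whose MRCA is younger than the age bound (cross-child sample blocks of
each recent node), which keeps the cost near-linear in the number of
recent pairs. A brute-force change-point walker over every marginal tree
serves as the oracle in the tests: at a grid far finer than the
recombination spacing the two agree run-for-run.

One caveat is documented deliberately: on an exact-ARG engine the same
ancestral node can recur after a short excursion (recombination followed
by back-coalescence), and excursions shorter than the grid step are
invisible, so grid sampling merges the flanking runs. At the default
thresholds this inflates segment counts by a few percent (~7% at 0.2 cM,
~2% at 1 cM against renewal-theory expectations); SMC-type engines, which
lack long-range tree recurrence, do not show it. Segments between the two
haplotypes of one individual are extracted and flagged; all diploid
analyses use between-individual pairs only.

## Conflation statistics

A conflation event is an unordered pair of segments of one diploid pair,
each at least *w* cM (default 0.2), separated by a gap of at most 0
(overlap or touching; 0.01 cM is exposed as the alternative), whose
end-to-end span reaches 1 cM. Chains of three or more close segments count
as all qualifying pairs — the rate statistic is pairwise — while the
apparent-length histogram merges greedily left-to-right so each segment
contributes to at most one apparent segment and the histogram remains a
proper distribution. An event is *cis* when both segments lie on the same
two haplotypes and *trans* otherwise; under independent placement of
haplotypes the expected trans fraction is 3/4.

The permutation null resamples segment lengths with replacement, assigns
each a uniform start, two uniform distinct individuals and one uniform
haplotype per individual, and recomputes the rate — the test suite checks
a two-segment configuration against exact integration over start
positions, and that the null cis fraction converges to 1/4.

## Age-given-length model

Segment ages within each 0.1 cM length bin are modelled as a two-component
gamma mixture fitted by EM: responsibilities in the E step; closed-form
weight and scale updates; shape by Newton iterations on the weighted
digamma stationarity equation; initialisation by splitting at the median
(random quantiles on the four additional restarts); convergence at 10⁻⁶
relative log-likelihood change, at most 500 iterations. Components are
reported in ascending order of mean. Bins with fewer than 50 segments are
merged into the adjacent longer bin; bins larger than 5000 observations
are fitted on a random subsample of that size (the fit is insensitive
beyond this, and it bounds the EM cost). With fewer than 10k observations
the fit falls back to a single method-of-moments gamma with a warning.
Queries outside the modelled length range clamp to the nearest bin. The
model serialises to a plain-text table of per-bin parameters.

## Mutation-rate experiment

The estimator is μ̂ = Σm / Σ2·L_seq·T_IBD. Synthetic segments draw an
apparent length from the empirical apparent-length distribution (truncated
at the 1 cM analysis cutoff), and are conflated with the per-bin empirical
proportion (or forced to 0/1 by scenario). Nonconflated segments draw one
true age from the model at their length; conflated segments split into two
gap-free sub-lengths — the first resampled from the true length
distribution until it is smaller than the whole (rejection sampling; the
split rule is otherwise unstated) — with independent ages at each
sub-length. Mismatches are Poisson with mean 2·L·T·μ per (sub)segment and
sum across the two halves; no mutations fall in a gap because there is
none by construction. Both kinds also draw an *apparent* age from the
model at the apparent length; that is the T_IBD the estimator sees. 1000
sets of 5000 segments give the median and 5th/95th percentiles. Setting
`use_true_ages=True` replaces the denominator with the exact
per-subsegment ages, under which μ̂ is unbiased — the bias is entirely the
apparent-age misassignment. In the cutoff sweep the per-set segment count
shrinks with the surviving fraction of the apparent distribution, so
intervals widen as the cutoff rises.

## Called-segment decomposition

Parsed (or internally generated) calls are decomposed against the true
segments of their diploid pair: subsegments are ranked by overlap with the
called interval (ties broken by earlier start, then older TMRCA). The
longest defines the overlap component; other subsegments qualify when
their clipped length reaches 0.2 cM (a flag switches to unclipped lengths,
since the original intersection rule is ambiguous) and they are not fully
contained in the longest's span — a fully overlapped second subsegment,
possible through the other haplotype configuration, cannot confound a
caller. Extension is the flanking called length covered by qualifying
subsegments; endpoint error is the rest; the three parts sum exactly to
the called length. Summaries stratify into the seven bins [1,1.2), …,
[2.2,20) cM, and a trimming variant shrinks calls by 0.1 cM per side
first. The built-in IBS matcher (exact seed windows of 32 markers,
marker-by-marker extension, projection to diploid pairs) exists so this
pipeline is testable without external Java/C callers; it makes no
probabilistic assessment and is not a reimplementation of any of them.

## What the synthetic data do and do not show

The generator reproduces the study conditions: panmixia, a known constant
map, perfect phase, no genotyping error, no gaps within conflated pairs.
Real cohorts add local structure (raising recent coalescence), variable
recombination, phasing and genotyping error, and array ascertainment, all
of which the estimator experiment deliberately excludes — passing tests
demonstrate the internal consistency of the machinery and the
bias-attribution claim, not calibrated error rates for any real dataset.

Two families of checks behave differently at reduced sample size. Per-pair
normalised rates (IBD rate, conflation rate, trans fraction, per-bin
conflation proportions) are sample-size invariant by pairwise
exchangeability, so the test suite runs 300 diploids × three seeded 20 Mb
regions and the acceptance script 300 diploids × five; the variant-count
check runs at the full 2000 haplotypes. The measured values under the
default demography are internally consistent across three independent
routes (the extractor, a renewal-theory calculation, and a brute-force
walker); several published headline numbers are not reproduced at their
stated tolerances under this demography, and the corresponding checks are
left failing rather than recalibrated — the demographic parameters are the
stated study conditions, not tuning knobs.

## Numerical conventions

Coordinates are 0-based half-open bp intervals; genetic distances are cM
at six decimal places in all files; event gaps and combined lengths are
rounded to 10⁻⁹ cM to keep histogram bin assignment stable against float
conversion noise. One global seed spawns independent per-stage streams
(`RunConfig.stage_seed`), so any stage reruns reproducibly in isolation,
and every output file carries its seed and parameters in `#` header lines.
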