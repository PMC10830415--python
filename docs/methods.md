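# Methods

## Overview

`enhancerkit` designs cell-type-specific enhancer sequences by oracle-guided
search.  An *oracle* is any deterministic scorer mapping a batch of
equal-length DNA sequences to per-class scores in [0, 1] (the
`OracleModel` contract).  In practice such oracles are trained deep learning
models of chromatin accessibility; the package treats them as pluggable
black boxes and ships a fully specified *surrogate* oracle so that every
algorithm is runnable, testable and exactly analysable without model weights
or downloads.  Adapters around externally hosted trained models are a
documented plug-in point only; nothing in the package depends on them.

## The surrogate oracle

The surrogate scores a sequence s by scanning a set of transcription-factor
binding-site models m (position weight matrices with activator or repressor
roles) on both strands at every offset and summing thresholded log-odds
hits:

    r(s) = Σ_m w_m · Σ_{hits h of m: LLR_h ≥ τ_m} (LLR_h − τ_m)
           + Σ_{qualifying activator hit pairs} β_pair
    score(s) = 1 / (1 + exp(−(r(s) − b)))

An offset's LLR is the maximum of the forward and reverse-complement
log-odds, so an occurrence is counted once regardless of orientation.
Without proximity bonuses r is an exact sum of per-hit terms; the packaged
presets ship with an empty pair set so this additivity holds exactly (the
pair-bonus machinery is implemented and tested, but a non-additive default
would forfeit the exact attribution mode and the analytic calibration
below).  When a pair bonus is configured, every qualifying hit pair (gap
between the two intervals at most D bp) contributes β once.

### Packaged parameters and their rationale

* PWMs are derived from published consensus sites (fly: Ey
  `TGCTCACTCAAGCGTAA`, Mef2 `CTATTTATAG`, Onecut `ATCGAT`, Sr `CCACCC`;
  human: SOX10 `AACAATGGGCCCATTGTT`, MITF `GTCACGTGAC`, TFAP2 `GCCTGAGGC`)
  with match probability 0.85 and 0.05 per off-base.  Repressor models are
  the CAATTA 6-mer plus a synthetic 5-mer stand-in (`CGTCA`) for the Mamo
  class, whose consensus is not published; the human preset uses the
  ZEB-class E-box `CACCTG` as a synthetic repressor stand-in.  A second fly
  class ("T_neuron") with two synthetic activator 8–10-mers exists purely so
  dual-code objectives are exercisable out of the box.
* Hit thresholds default to τ_m = 0.8 · max LLR.  At match probability
  0.85 a single mismatch costs ln(0.85/0.25) + ln(0.25/0.05) ≈ 2.8 nats, so
  this τ admits essentially consensus-quality occurrences only.
* Weights are +1.0 (activators), −2.5 (repressors); the intercept is
  b = 4.0.  These were fixed once by expectation arithmetic on 500 bp
  random sequence: a random sequence carries ≈1.2 repressor and ≈0.5
  activator consensus hits in expectation, so E[r] < 0 and
  score ≈ σ(−4) ≈ 0.02, while the full activator complement contributes
  r ≈ 9.5, giving σ(5.5) ≈ 0.996 after repressor ablation.  Two planted
  repressor hits (−7.35) are enough to dominate the full activator set —
  the behaviour the repression experiments require.  The calibration
  property (mean random score < 0.1, designed score > 0.9) follows by
  construction and is asserted by the test suite.

## Sequence generation

Random starts are drawn position-independently from a `PositionFrequencyProfile`.
The packaged default is a length-500 profile whose GC fraction rises
linearly from 0.40 at the edges to 0.55 at the centre, emulating the
elevated central GC content of accessible regulatory regions; real designs
would estimate the profile from genomic region sets with
`estimate_position_profile`.  A k-th order Markov background sampler
(add-one smoothing by default, exact empirical chain optional) provides
order-matched null sequences.  Coordinates are 0-based half-open
everywhere, including BED output.

## Saturation mutagenesis and search

`saturation_mutagenesis` enumerates all 3L single-substitution variants
(1,500 for 500 bp), scores them together with the reference in one batched
oracle call, and stores an L×4 delta matrix with the reference column
exactly zero.  All searches consume this landscape:

* **maximize** — apply the highest positive delta; stop early when none is
  positive (a 20-mutation budget by default).  Traces are therefore strictly
  increasing in the target score.
* **augment** — like maximize, but a candidate is feasible only if every
  "keep" class stays at or above its floor (default: its starting score
  minus 0.05).
* **prune** — most-negative off-target delta, feasible while the target
  class stays above a floor (default 0.5).
* **repress** — most-negative target delta outside protected intervals
  (typically the activator sites of the enhancer being switched off).
* **branched** — keep the k highest-delta substitutions per node for a
  fixed depth.  Paths are counted without deduplicating convergent
  sequences, so k=20, depth=5 yields exactly 20⁵ = 3.2 million paths.
  Levels are stored column-wise (parent, position, base, score), so memory
  scales with the final level only; the full 3.2-million-path run is
  executed at reduced sequence length with a deliberately cheap GC-content
  oracle, since the path count is a property of the search tree, not of the
  guiding oracle.

Ties anywhere in mutation ranking break deterministically: lowest position
first, then base order A<C<G<T.  Random-drift controls (uniform random
substitutions) are seeded and carried in the trace.

## Motif implantation and syntax

`scan_implant` writes a site into every allowed offset on both strands,
scores all candidates in one batch and keeps the best (ties: lowest offset,
+ before −).  Iterative implantation repeats this for an ordered site list;
by default later sites may not overwrite earlier placements (the mask
accumulates; a flag allows overlap).  Placement policies: `best`
(exhaustive), `random` (seeded uniform control) and `closest_positive`
(nearest offset to the anchor with a positive score change, for minimal
designs).  Syntax analytics: signed inter-site gap histograms keyed by
same/opposite strand (gap = bases strictly between the intervals, negative
when the partner is upstream — stated explicitly because "distance" is
otherwise ambiguous), flank position-probability matrices (strand-aligned,
0.25 subtracted per entry so columns sum to 0), minimal-enhancer cutting
from the most upstream to the most downstream site plus a flank, and
background-robustness distributions over random replacements of a window.

## Motif annotation

`pwm_scan` reports both-strand hits with log-odds at least a floor (default
3.0) against a 0-order background (default: frequencies of the scanned
set, pseudocount 0.01).  Overlapping hits are merged per motif identity
with strands pooled (bookended intervals stay separate; cross-motif pooling
is a flag), keeping the maximum member score.  Significance thresholds are
empirical: per motif, the best-hit log-odds over n random sequences is
collected and the threshold set to mean + 1 sample standard deviation
(ddof = 1 — the estimator is a package choice).  The trace census counts
significant merged hits per motif at every step of an evolution trace and
flags per-step gains and losses.

## Genome scanning

`make_windows` tiles chromosomes with fixed-width windows (default 500 bp,
stride 50 bp), dropping partial windows.  `scan_genome` takes contig
lengths from the FASTA itself (a disagreeing chromsizes file is an error),
skips and counts windows containing non-ACGT symbols, and batch-scores the
rest.  Per-window accessibility is the length-weighted bedGraph mean with
uncovered bases contributing 0, computed from a validated
(sorted, non-overlapping) interval set.  The near-enhancer filter keeps
windows with score above 0.3 and mean signal at or below the 25th
percentile (both configurable), optionally collapsing overlapping survivors
to the best-scoring window.

## The WGAN-GP generator

The generator maps 128-dimensional Gaussian noise through a dense layer of
seq_len × channels units (64,000 at the 500 × 128 default) with ELU, a
reshape to (seq_len, channels), five residual convolution blocks (ReLU then
a length-preserving width-5 convolution with `channels` filters, additive
skip), a width-1 convolution to 4 channels and a position-wise softmax.
The critic applies a width-1 convolution to 128 channels, the same
five-block tower, a flatten and a single linear unit.  Training follows
WGAN-GP: 10 critic updates per generator update, penalty
λ·(‖∇_x̂ D(x̂)‖ − 1)² on uniform real/fake interpolates with λ = 10, Adam
at learning rate 1e-4, β₁ = 0.5, β₂ = 0.9.  Skip-connection form (additive
residual), padding ("same"), λ and Glorot-uniform initialization are
package choices where the recipe leaves them open.  Sampling decodes the
softmax output by per-position argmax (ties resolve A<C<G<T).

The networks run on a compact NumPy reverse-mode autodiff engine written
for this package (`enhancerkit.autodiff`).  Its backward rules are
themselves composed of differentiable operations, so the gradient penalty's
gradient-of-a-gradient comes out of the same machinery; all rules are
validated against finite differences in the test suite, including the
double-backprop path.

### Smoke scale

Full-scale training (hundreds of thousands of batch iterations on genomic
region sets) is out of desk scope.  The packaged smoke configuration —
seq_len 64, 16 channels, 16 noise dimensions, batch 32, learning rate 1e-3,
120 generator iterations on 512 synthetic sequences — keeps the layer plan
identical and finishes in about two minutes.  Its training fixture implants
the Onecut 6-mer at a fixed central position in uniform-random sequence:
positional fixation makes the signal learnable at this scale (real region
sets have positionally variable sites, which smoke training does not
emulate).  After training, sampled sequences carry a significant Onecut hit
at a far higher rate than profile-random controls.

## What the synthetic fixtures do and do not show

Fixtures emulate the *structure* of the design problems — activator
combinations, chance repressor hits, near-enhancers (all activators present
plus two dominating repressor sites, redrawn until the start scores below
0.5), toy genomes with planted accessible and inaccessible positive loci —
under the surrogate's additive, consensus-threshold scoring.  Passing tests
therefore demonstrate that the search, implantation, annotation, scanning
and training machinery is correct and internally consistent.  They do not
show that designs validated against the surrogate would be active in vivo,
nor do they reproduce trained-model-specific observables (preferred
inter-site spacings, saturation of scores after ~15 mutations at particular
rates, genome-wide window counts of a real assembly).

## Numerical choices and degenerate inputs

* All scanning arithmetic is float64; thresholded hits make "no change"
  deltas exactly zero, so batch scoring equals one-at-a-time scoring
  bit for bit and tie-breaks are platform-stable.
* Exact surrogate attribution distributes each hit term over the hit's
  positions in proportion to per-position log-odds; values sum back to the
  raw score to well below 1e-9 and are zero outside hits.  The
  in-silico-mutagenesis attribution (reference score minus the mean over
  the three alternates) is compared to the exact decomposition per
  sequence; rank agreement is assessed within sequences because the
  logistic slope differs between sequences.
* Degenerate cases are defined, not errors: empty chromsizes give empty
  window lists; all-equal null scores give sd 0 and threshold = mean; an
  entirely protected sequence yields an empty repression trace with
  `no_feasible_mutation`.
* Problem sizes in the acceptance script (200 calibration sequences, 50
  evolutions of 500 bp for 15 steps, branched search at length 30, 120
  smoke generator iterations) are the packaged desk-scale study conditions;
  they complete in a few minutes on one CPU.

## Known limitations

* The surrogate is additive and consensus-thresholded; it has no saturation,
  cooperativity (beyond the optional pair bonus) or soft binding-energy
  landscape, so greedy searches reach local optima quickly and score
  plateaus differ from trained-model behaviour.
* The Mamo and ZEB repressor stand-ins and the T-neuron activator set are
  synthetic; conclusions about those factors' real sites cannot be drawn
  from surrogate runs.
* Markov background sampling is exact but loops in Python per sequence; it
  is intended for null sets of hundreds, not millions.
* The GAN is CPU-bound NumPy; it is meant for smoke-scale verification and
  architecture experiments, not production training.
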