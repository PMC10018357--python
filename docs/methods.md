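# Methods

## The generative model for single-molecule traces

A surface-tethered DNA pair is modelled as a two-state continuous-time
process: a synaptic state with FRET efficiency `e_high` (default 0.78) and
mean lifetime `tau_high` (default 20 s), and a dissociated state with
`e_low` (default 0) and `tau_low` (default 77 s).  Dwells are exponential;
the initial state is drawn from the stationary distribution
`P(high) = tau_high/(tau_high+tau_low)`.  The defaults are the intact
(non-damaged) substrate conditions; the rare-transition regime (e.g. an
abasic site in the microhomology centre) is the same model with
`tau_low = 7.3e4 s` and a short synaptic lifetime (5 s is used in the
validation suites — short relative to the 300-s observation window while
still spanning ~50 frames, so state assignment is unambiguous).

Each 100-ms camera frame integrates the ideal emission by fractional
occupancy: the state path is sampled in continuous time and each frame's
donor/acceptor values weight the per-state emission by the exact fraction of
the frame spent in each state.  Sampling the state per frame instead would
bias dwell statistics once lifetimes approach the frame interval; the
integration approach has no such bias and frames that straddle a transition
get the physically correct intermediate intensity.

Emission while both dyes are alive:

    donor    = I·(1 − E(t))
    acceptor = I·E(t) + β·donor + dx

with total intensity `I` (default 1000 a.u./frame), bleed-through fraction
`β` (default 0.09) and a constant direct-excitation offset `dx` (default
30 a.u.).  Additive Gaussian noise (default σ = 50 a.u., i.e. 5% of `I`) is
applied per channel per frame.  The camera model of the real instrument is
not specified anywhere, so additive Gaussian noise is the deliberate,
simplest choice; shot noise appears only in the movie renderer, which draws
Poisson counts per pixel.

Photobleaching is single-step with independent exponential waiting times per
dye (default mean 30 s donor, 60 s acceptor).  After donor bleaching the
donor channel is noise-only and the acceptor retains only `dx`; if the
acceptor bleaches first the donor recovers its full unquenched intensity and
the acceptor channel drops to noise.  These are the standard signatures used
to identify single pairs.

Donor-only molecules (the β-calibration population) emit `β·donor` in the
acceptor channel — no FRET, no `dx`, no acceptor bleach event.

### What the generator does not emulate

No EMCCD gain/excess-noise statistics, no multi-step or reversible
(blinking) photobleaching, no stage drift, no baseline drift, no
detection-efficiency (γ) asymmetry between channels.  Passing tests
therefore demonstrate correctness of the estimators under clean two-state
photophysics with realistic signal-to-noise — they do not demonstrate
robustness to camera artefacts or non-ideal dye behaviour, which real data
would add.

## Trace quality control

**Bleach-step detection** is recursive two-segment splitting: within a
segment, the split maximising the reduction in residual variance is accepted
when the mean change exceeds `k`·(robust noise), `k = 4` by default, with
robust noise `1.4826·median|Δx|/√2`.  Only downward steps are reported,
ranked by magnitude.

**Selection** accepts a trace as a single pair when the summed intensity
shows exactly one sustained large drop (the donor bleach; "sustained" means
the smoothed signal never recovers past 60% of the step), the donor tail
after it sits at baseline, the pre-bleach summed intensity lies within
single-emitter bounds (400–1800 a.u. against the nominal 1000), and there
are ≥ 25 frames before and ≥ 10 frames after the bleach.  Aggregate traces
(two emitters) fail on the step count or the intensity bound.  On mixed
synthetic sets the selector's sensitivity and specificity are both ≥ 0.9
against generator truth.

**Direct excitation** is the mean acceptor intensity over at most 50 frames
just after the donor bleach (minimum 10).  Capping the window keeps a later
acceptor bleach from diluting the estimate; a detectable acceptor step
inside the window truncates it.

**FRET window.**  Efficiency is computed over the pre-donor-bleach frames;
if a sustained drop of the acceptor channel to baseline is detected before
the donor bleach (acceptor photobleached first), the window ends there —
after that point the acceptor carries no FRET information and the frames
would otherwise pile up at E ≈ −β.

**β calibration** finds the β whose corrected donor-only block-FRET
distribution has its kernel-density mode at zero, by bisection over
[0, 0.5].  The histogram convention is 25-frame non-overlapping block
averages aligned to the window start, trailing remainder dropped, bin width
0.02 over [−0.2, 1.2] (values outside are clipped into the edge bins so
counts are conserved).  Peak positions come from a Gaussian-mixture
least-squares fit to the binned counts, initialised at the largest local
maxima of the smoothed histogram.

A systematic note on peak positions: the apparent-FRET formula
`E = (I_A − β·I_D)/(I_D + I_A)` removes bleed-through from the numerator but
keeps the raw acceptor (which contains it) in the denominator, so a state
with generator efficiency `e` reads `e/(1 + β(1−e))` after correction —
0.765 for 0.78 and 0.149 for 0.16 at β = 0.09.  This compression is a
property of the conventional formula itself, is well inside the ±0.02
acceptance bands used throughout, and is left uncorrected because the
formula is the field's standard definition of apparent efficiency.

## Dwell-time estimation

Binarization assigns a sample to the synaptic state when its FRET value is
≥ 0.4 (the boundary value counts as high — one documented tie rule).  For
kinetics the pipeline thresholds **per frame**, not on 25-frame blocks:
block averaging cannot represent dwells shorter than the block, and at
`tau_high = 20 s` the ~14% of synaptic dwells shorter than ~3 s would vanish,
merging their flanking dissociated dwells and inflating `tau_low` by tens of
percent (measured ~77 → ~117 s).  Per-frame thresholding is reliable here
because per-frame FRET noise (~0.05–0.07 s.d.) leaves more than 5σ between
either state and the cutoff; with noisier data a small block size (3–5
frames) would be the appropriate compromise, and `binarize` accepts any
pre-averaged series.

**Concatenation.**  Dwells longer than a trace are censored at both ends;
naive averaging of censored dwells saturates near the trace duration.  The
concatenation estimator draws `n_copies = 10000` traces with replacement in
random order under the handshake constraint (the next trace must start in
the state the chain ends in).  At each junction the censored final dwell and
the censored leading dwell — both truncated observations of an ongoing dwell
— merge into a single dwell, so junctions add no transitions; the chain's
own first and last dwells are censored and are never counted ("end
removal").  Traces ending in a state that no trace starts in can never be
followed and are pruned from the draw before it begins (an error is raised
only if nothing remains).  The estimator is consistent: total time in a
state divided by the number of completed dwells converges to the true mean
lifetime.

**Replicates and SEM.**  `dwell_stats` builds three concatenated traces.  By
default the trace pool is first split into three disjoint random groups, one
concatenation per group, so the scatter between the three means reflects
genuine sampling variability (as replicate measurements would); three
permutations of one shared pool would agree to a fraction of a percent while
sharing the pool's finite-sample skew, making the SEM uninformative.
`split=False` selects the shared-pool variant, which is the right choice
when the dataset holds very few transition events: in the rare-transition
regime (~8 synapsis events across 2000 traces of 300 s) thirds of the pool
hold ~3 events each and the reciprocal of such small counts is badly skewed,
so the validation suites use the full-pool estimate there and its intrinsic
uncertainty is the Poisson noise of the event count (~±35%), matching the
large uncertainties such experiments report.

## Gel quantification

Band densities are indexed by product position: 0 = unreacted primer,
1–7 intermediates, 8 = full length, >8 = further-extended products (detached
full-length strands that self-anneal and extend again); the further-extended
bands count toward both total and ≥full metrics.  All four metrics divide by
the whole-lane signal Σ(≥N0): the quantification recipe is stated once with
Σ(≥N0) and once with the N0 band alone for the ≥full metric, and the
whole-lane denominator is used for all metrics for internal consistency
(`denominator="n0"` selects the alternative).  Metrics are scale-invariant
and bounded: bypass ≤ total, efficiency ∈ [0, 1].  The densitometry helper
subtracts a rolling-minimum background and integrates a fixed window around
the local maximum nearest each expected migration position.

## Survival and group statistics

Surviving fraction is `(colonies/cells)/PE` with plating efficiency `PE`
taken from the unirradiated wells.  The linear-quadratic fit is non-negative
least squares of `−ln SF` on `(D, D²)`; SF = 0 wells are excluded from the
log-space fit and flagged.  D10 solves `αD + β_LQ·D² = ln 10` via the
cancellation-free root `2·ln10/(α + √(α² + 4β_LQ·ln10))` (the textbook
quadratic formula loses all precision when the fitted β_LQ is ~10⁻¹⁷);
log-linear interpolation between bracketing doses is available as an
alternative and agrees with the fit to within 5% on dense data.
RBE_D10 is the plain ratio of reference to test D10.  Group comparisons use
Student's equal-variance unpaired t-test by default (the convention matching
the era's "unpaired t-test"), Welch's on request; fold change is the ratio
of group means.

## Problem sizes and tolerances in the validation suites

The suites size their simulations for tight statistical checks: 5000-trace
pipelines for the FRET peaks (recovered within ±0.02), 500 donor-only traces
for β (±0.01), 400 × 60-s traces for the 77-s lifetime (checked within
3 SEM, pooling three replicate datasets so the SEM has eight degrees of
freedom rather than two), and 3 × 2000 × 300-s traces for the rare regime
(harmonic-mean pooled, checked within a factor of 2 against ground truth
while naive censored averaging is wrong by more than two orders of
magnitude).  All generators are bitwise-reproducible under a fixed seed, and
every randomised pipeline routes its randomness through one seeded
generator per run.

## Known limitations

* Thresholding kinetics (no hidden-Markov idealization): states closer than
  a few noise σ to the 0.4 cutoff, or lifetimes of a frame or less, are out
  of scope by design.
* The β calibration assumes a homogeneous donor-only population; per-movie
  calibration is supported simply by passing per-movie trace subsets.
* The concatenation estimator assumes trace windows interrupt the process at
  state-independent times (true for photobleaching); selection rules that
  correlate with state would bias it.
* Gel analysis starts from 1-D profiles or band tables; 2-D gel image
  segmentation is out of scope.
* Survival fits assume independent Poisson counts per well; overdispersion
  between biological replicates is not modelled beyond the replicate
  structure itself.
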