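# synapsefret

Quantitative analysis pipelines for studying how DNA polymerase θ (POLQ)
repairs complex DNA double-strand breaks — the kind produced by high-LET
radiation such as carbon ions, which carry abasic sites and thymine glycol
close to the break ends.  The package covers the three quantitative layers of
such a study:

1. **Single-molecule FRET synapsis/extension analysis.**  POLQ pairs two
   resected single-stranded DNA tails via microhomology ("synapsis", a
   high-FRET state at *E* ≈ 0.78) and extends them into a rigid duplex (a low
   FRET state at *E* ≈ 0.16).  The pipeline selects single donor/acceptor
   pairs by photobleaching-step analysis, applies bleed-through and
   direct-excitation corrections, computes apparent FRET efficiency

       E = (I_A − β·I_D) / (I_D + I_A)

   per 100-ms frame, histograms 25-frame block averages, and fits Gaussian
   peaks.  β (donor bleed-through, ≈ 0.09) is calibrated by forcing the
   donor-only population's FRET peak to zero.

2. **Censored dwell-time kinetics.**  Synaptic and dissociated lifetimes are
   estimated from traces binarized at *E* = 0.4.  Lifetimes far longer than a
   single trace (up to ~10⁵ s against 60–300 s traces) are recovered by
   serialized handshaking repeated permutation with end removal: traces are
   concatenated in random order such that each appended trace starts in the
   state the chain ends in, censored end dwells merge across junctions, and
   the chain's own censored ends are discarded.  Mean ± SEM come from three
   independently built concatenated traces.

3. **Gel quantification and survival statistics.**  Primer-extension gels are
   scored by cumulative band densities (total product, ≥full-length product,
   lesion bypass product and bypass efficiency = bypass/total); clonogenic
   survival follows the linear-quadratic model SF(D) = exp(−αD − β_LQ·D²),
   with D10 (dose at 10% survival) and RBE_D10 = D10(X-ray)/D10(carbon ion);
   group comparisons (micronuclei, chromatid breaks) use fold changes with
   the unpaired two-sample t-test.

No raw experimental data are deposited for this kind of study, so the package
ships seeded synthetic-data generators with complete ground truth (two-state
kinetics with photophysics, extension staircases, donor-only traces,
two-channel movies, gel lanes, Poisson colony counts).  Every estimator is
validated by parameter recovery against what the generator injected.

## Worked example

```python
import numpy as np
from synapsefret import synth, fret, kinetics
from synapsefret.models import KineticModel
from synapsefret.survival import rbe_d10, group_compare

model = KineticModel()   # synaptic E 0.78, dissociated E 0, tau 20 s / 77 s,
                         # beta 0.09, direct excitation 30 a.u., 100-ms frames

# calibrate bleed-through from donor-only molecules
donor_only = synth.simulate_trace_set(model, 200, 60.0, seed=2, kind="donor_only")
beta = fret.estimate_beta(donor_only)

# trace QC -> corrections -> histogram -> peaks
traces = synth.simulate_trace_set(model, 1000, 60.0, seed=1)
series, report = fret.analyze_traces(traces, beta)
hist = fret.build_histogram(series, block_size=25)
peaks = fret.fit_peaks(hist, n_peaks=2)

# dwell times by binarization + handshaking concatenation
kin = KineticModel(bleach_rate_donor=0, bleach_rate_acceptor=0, direct_excitation=0)
ktr = synth.simulate_trace_set(kin, 400, 60.0, seed=4)
bins = [kinetics.binarize(fret.compute_fret(t.donor, t.acceptor, beta,
                                            frame_interval=0.1), cutoff=0.4)
        for t in ktr]
stats = kinetics.dwell_stats(bins, n_concat=3, n_copies=10000, seed=5)

print(rbe_d10(2.97, 2.26).rbe_d10_display)        # X-ray vs carbon-ion D10
print(group_compare([12.8], [21.7, 22.3]).fold_change)
```

Output (exact numbers are seed-reproducible):

```
beta = 0.087
accepted 779 of 1000 traces; rejections: {'no_donor_bleach': 133,
  'short_post_window': 4, 'short_pre_window': 82,
  'donor_not_at_baseline': 1, 'intensity_out_of_bounds': 1}
peak positions: [0.006 0.768]   weights: [0.79 0.21]
dissociated lifetime 77 +/- 7 s; synaptic 22.3 +/- 0.4 s
RBE_D10 = 1.31
fold change = 1.72
```

The two histogram peaks are the dissociated (≈0) and synaptic populations;
the synaptic peak sits at 0.768 rather than 0.78 because the apparent-FRET
formula keeps raw intensities in its denominator while the numerator removes
bleed-through (see `docs/methods.md`).  The dwell analysis recovers the
injected 77-s dissociated lifetime; 2.97/2.26 = 1.31 is the relative
biological effectiveness of carbon ions for the wild-type line, and the
knockout clones show a 1.7-fold increase in carbon-ion-induced chromatid
breaks.

## Command line

Every stage is exposed as a subcommand of `synapsefret`:

```bash
synapsefret simulate --kind two_state --n-traces 500 --seed 1 --out traces.csv
synapsefret fret traces.csv --donor-only donors.csv --out fret.json
synapsefret dwell traces.csv --cutoff 0.4 --n-copies 10000 --n-concat 3 \
    --seed 1 --out dwell.json
synapsefret gel lane.csv --lesion-position 3
synapsefret rbe xray.csv carbon.csv
synapsefret stats --group-a 12.8 --group-b 21.7,22.3
synapsefret demo --seed 7 --out demo_run   # seeded end-to-end run + manifest
```

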