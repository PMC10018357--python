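"""Trace QC, corrections, bleed-through calibration, histograms, peaks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synapsefret import fret, synth
from synapsefret.fret import (
    SelectionConfig,
    analyze_traces,
    block_averages,
    build_histogram,
    classify_fraction,
    compute_fret,
    correct_direct_excitation,
    detect_bleach_steps,
    estimate_beta,
    fit_peaks,
    relative_population,
    select_traces,
)
from synapsefret.models import KineticModel, RawTrace


def _make_trace(donor, acceptor=None, dt=0.1):
    donor = np.asarray(donor, float)
    if acceptor is None:
        acceptor = np.zeros_like(donor)
    return RawTrace(donor, np.asarray(acceptor, float), dt)


class TestDetectBleachSteps:
    def test_clean_step_found_exactly(self):
        x = np.concatenate([np.full(50, 1000.0), np.full(50, 100.0)])
        steps = detect_bleach_steps(x)
        assert steps[0][0] == 50
        assert np.isclose(steps[0][1], 900.0)

    def test_constant_trace_no_steps(self):
        assert detect_bleach_steps(np.full(100, 500.0)) == []

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            detect_bleach_steps(np.full(5, 1.0))

    def test_noisy_step_within_two_frames(self, rng):
        """Known bleach frame recovered within +/-2 frames in >=95% of trials."""
        hits = 0
        n_trials = 200
        for _ in range(n_trials):
            f = int(rng.integers(30, 170))
            x = np.concatenate([np.full(f, 1000.0), np.full(200 - f, 0.0)])
            x = x + rng.normal(0, 50.0, 200)
            steps = detect_bleach_steps(x)
            if steps and abs(steps[0][0] - f) <= 2:
                hits += 1
        assert hits / n_trials >= 0.95

    def test_agrees_with_exhaustive_split_oracle(self, rng):
        """Largest step matches a brute-force single-split SSE minimiser."""
        for _ in range(20):
            f = int(rng.integers(20, 80))
            x = np.concatenate([np.full(f, 800.0), np.full(100 - f, 50.0)])
            x = x + rng.normal(0, 40.0, 100)
            # oracle: minimise total SSE over all splits
            best, best_sse = None, np.inf
            for i in range(5, 96):
                sse = ((x[:i] - x[:i].mean()) ** 2).sum() + ((x[i:] - x[i:].mean()) ** 2).sum()
                if sse < best_sse:
                    best, best_sse = i, sse
            steps = detect_bleach_steps(x)
            assert steps and steps[0][0] == best


class TestSelectTraces:
    def test_single_pair_trace_accepted(self, default_model):
        traces = synth.simulate_trace_set(default_model, 30, 60.0, 5)
        report = select_traces(traces)
        good = [
            t for t in traces
            if t.truth.donor_bleach_frame is not None
            and 25 <= t.truth.donor_bleach_frame <= len(t) - 10
        ]
        assert report.n_accepted() >= max(1, int(0.7 * len(good)))

    def test_double_emitter_rejected(self, default_model):
        rng = np.random.default_rng(0)
        doubles = []
        for _ in range(20):
            a = synth.simulate_two_state_trace(default_model, 60.0, rng)
            b = synth.simulate_two_state_trace(default_model, 60.0, rng)
            doubles.append(_make_trace(a.donor + b.donor, a.acceptor + b.acceptor))
        report = select_traces(doubles)
        assert report.n_accepted() <= 4
        assert set(report.rejected) <= {
            "multiple_donor_steps", "intensity_out_of_bounds",
            "no_donor_bleach", "short_pre_window", "short_post_window",
            "donor_not_at_baseline",
        }
        assert report.rejected.get("multiple_donor_steps", 0) >= 1

    def test_sensitivity_and_specificity_on_mixed_set(self, default_model):
        """Confusion matrix against generator truth on a mixed population."""
        rng = np.random.default_rng(77)
        cfg = SelectionConfig()
        singles = synth.simulate_trace_set(default_model, 300, 60.0, 8)
        doubles = []
        for _ in range(100):
            a = synth.simulate_two_state_trace(default_model, 60.0, rng)
            b = synth.simulate_two_state_trace(default_model, 60.0, rng)
            doubles.append(_make_trace(a.donor + b.donor, a.acceptor + b.acceptor))
        labels, keep, traces = [], [], []
        for t in singles:
            f = t.truth.donor_bleach_frame
            labels.append(
                f is not None and cfg.min_pre_frames <= f <= len(t) - cfg.min_post_frames
            )
            # frames within a few frames of the window bounds are genuinely
            # ambiguous (detection is only frame-accurate); leave them out of
            # the confusion matrix
            borderline = f is not None and (
                abs(f - cfg.min_pre_frames) <= 3
                or abs(f - (len(t) - cfg.min_post_frames)) <= 3
            )
            keep.append(not borderline)
            traces.append(t)
        labels += [False] * len(doubles)
        keep += [True] * len(doubles)
        traces += doubles
        report = select_traces(traces, cfg)
        accepted = np.array([r == "" for r in report.reasons])
        labels, keep = np.array(labels), np.array(keep)
        accepted, labels = accepted[keep], labels[keep]
        sensitivity = accepted[labels].mean()
        specificity = (~accepted[~labels]).mean()
        assert sensitivity >= 0.9
        assert specificity >= 0.9


class TestDirectExcitation:
    def test_zero_offset_recovered(self):
        m = KineticModel(direct_excitation=0.0, noise_sigma=0.0,
                         bleach_rate_donor=1 / 10.0, bleach_rate_acceptor=0.0)
        tr = synth.simulate_two_state_trace(m, 120.0, 1)
        f = tr.truth.donor_bleach_frame
        _, offset = correct_direct_excitation(tr, f)
        assert abs(offset) < 1e-9

    def test_noiseless_offset_exact(self):
        m = KineticModel(direct_excitation=30.0, noise_sigma=0.0,
                         bleach_rate_donor=1 / 10.0, bleach_rate_acceptor=0.0)
        tr = synth.simulate_two_state_trace(m, 120.0, 1)
        f = tr.truth.donor_bleach_frame
        corrected, offset = correct_direct_excitation(tr, f)
        assert np.isclose(offset, 30.0, atol=1e-9)
        assert np.allclose(corrected[f + 2 :], 0.0, atol=1e-9)

    def test_noisy_offset_within_standard_error(self):
        m = KineticModel(direct_excitation=30.0, noise_sigma=50.0,
                         bleach_rate_donor=1 / 10.0, bleach_rate_acceptor=0.0)
        errs = []
        for seed in range(50):
            tr = synth.simulate_two_state_trace(m, 120.0, seed)
            f = tr.truth.donor_bleach_frame
            if f is None or len(tr) - f < 11:
                continue
            n_window = min(50, len(tr) - f - 1)
            _, offset = correct_direct_excitation(tr, f)
            errs.append((offset - 30.0) * np.sqrt(n_window))
        errs = np.asarray(errs)
        # per-trace error scaled by sqrt(window) should look like N(0, sigma)
        assert np.abs(errs).mean() < 3 * 50.0

    def test_insufficient_window_rejected(self):
        tr = _make_trace(np.full(30, 1000.0), np.full(30, 100.0))
        with pytest.raises(ValueError):
            correct_direct_excitation(tr, 25)


class TestComputeFret:
    @pytest.mark.parametrize(
        "d, a, beta, expected",
        [
            (100.0, 9.0, 0.09, 0.0),
            (0.0, 100.0, 0.25, 1.0),
            (50.0, 54.5, 0.09, 0.478),
        ],
    )
    def test_printed_formula_arithmetic(self, d, a, beta, expected):
        s = compute_fret(np.full(5, d), np.full(5, a), beta)
        assert np.allclose(np.round(s.efret, 3), expected)

    def test_zero_denominator_flagged_invalid(self):
        s = compute_fret(np.array([100.0, 0.0]), np.array([100.0, 0.0]), 0.1)
        assert np.isfinite(s.efret[0])
        assert np.isnan(s.efret[1])

    @given(
        c=st.floats(min_value=1e-3, max_value=1e3),
        d=st.floats(min_value=1.0, max_value=1e4),
        a=st.floats(min_value=0.0, max_value=1e4),
        beta=st.floats(min_value=0.0, max_value=0.5),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_invariance(self, c, d, a, beta):
        e1 = compute_fret(np.array([d]), np.array([a]), beta).efret[0]
        e2 = compute_fret(np.array([c * d]), np.array([c * a]), beta).efret[0]
        assert np.isclose(e1, e2, rtol=1e-9, atol=1e-9)

    def test_invalid_beta_raises(self):
        with pytest.raises(ValueError):
            compute_fret(np.ones(3), np.ones(3), 0.7)


class TestEstimateBeta:
    def test_recovers_stated_bleedthrough(self, default_model):
        traces = synth.simulate_trace_set(default_model, 120, 60.0, 21, kind="donor_only")
        beta = estimate_beta(traces)
        assert abs(beta - 0.09) <= 0.01

    def test_zero_bleedthrough_near_zero(self):
        m = KineticModel(beta_true=0.0)
        traces = synth.simulate_trace_set(m, 120, 60.0, 22, kind="donor_only")
        assert estimate_beta(traces) <= 0.005

    def test_monotone_in_true_bleedthrough(self):
        estimates = []
        for i, b in enumerate([0.03, 0.09, 0.15]):
            m = KineticModel(beta_true=b)
            traces = synth.simulate_trace_set(m, 100, 60.0, 30 + i, kind="donor_only")
            estimates.append(estimate_beta(traces))
        assert estimates[0] < estimates[1] < estimates[2]

    def test_corrected_donor_only_histogram_peaks_at_zero(self, default_model):
        traces = synth.simulate_trace_set(default_model, 120, 60.0, 23, kind="donor_only")
        beta = estimate_beta(traces)
        series = [
            compute_fret(t.donor, t.acceptor, beta, frame_interval=t.frame_interval)
            for t in traces
        ]
        hist = build_histogram(series)
        mode = hist.bin_centers[np.argmax(hist.counts)]
        assert abs(mode) < 0.02

    def test_too_few_traces_raise(self, default_model):
        traces = synth.simulate_trace_set(default_model, 5, 60.0, 0, kind="donor_only")
        with pytest.raises(ValueError):
            estimate_beta(traces)


class TestHistogram:
    def test_fifty_frames_two_blocks(self):
        s = compute_fret(np.full(50, 220.0), np.full(50, 780.0), 0.0)
        hist = build_histogram([s], block_size=25)
        assert hist.n_blocks == 2

    def test_constant_series_single_bin_at_value(self):
        s = compute_fret(np.full(100, 220.0), np.full(100, 780.0), 0.0)
        hist = build_histogram([s])
        occupied = np.nonzero(hist.counts)[0]
        assert occupied.size == 1
        lo, hi = hist.bin_edges[occupied[0]], hist.bin_edges[occupied[0] + 1]
        assert lo <= 0.78 < hi

    def test_count_conservation(self, rng):
        series = []
        expected = 0
        for _ in range(20):
            n = int(rng.integers(10, 200))
            vals = rng.uniform(0, 1, n)
            series.append(compute_fret(1000 * (1 - vals), 1000 * vals, 0.0))
            expected += n // 25
        hist = build_histogram(series)
        assert hist.counts.sum() == expected

    def test_empty_input_empty_histogram(self):
        hist = build_histogram([])
        assert hist.counts.sum() == 0


class TestFitPeaks:
    def test_single_population_peak_recovered(self, rng):
        vals = rng.normal(0.78, 0.03, 4000)
        series = [compute_fret(1000 * (1 - vals), 1000 * vals, 0.0)]
        hist = build_histogram(series, block_size=1)
        pk = fit_peaks(hist, 1)
        assert abs(pk.means[0] - 0.78) < 0.02

    def test_symmetric_mixture_equal_weights(self, rng):
        vals = np.concatenate([rng.normal(0.2, 0.03, 3000), rng.normal(0.8, 0.03, 3000)])
        series = [compute_fret(1000 * (1 - vals), 1000 * vals, 0.0)]
        pk = fit_peaks(build_histogram(series, block_size=1), 2)
        se = np.sqrt(0.5 * 0.5 / 6000)
        assert abs(pk.weights[0] - 0.5) < max(3 * se, 0.03)

    def test_well_separated_peaks_within_bin_width(self, rng):
        for mu1, mu2 in [(0.1, 0.5), (0.2, 0.8), (0.3, 0.7)]:
            vals = np.concatenate([rng.normal(mu1, 0.03, 2000), rng.normal(mu2, 0.03, 3000)])
            series = [compute_fret(1000 * (1 - vals), 1000 * vals, 0.0)]
            pk = fit_peaks(build_histogram(series, block_size=1), 2)
            assert abs(pk.means[0] - mu1) < 0.02
            assert abs(pk.means[1] - mu2) < 0.02

    def test_fewer_modes_than_requested_warns(self, rng):
        vals = rng.normal(0.5, 0.02, 2000)
        pk = fit_peaks(build_histogram(
            [compute_fret(1000 * (1 - vals), 1000 * vals, 0.0)], block_size=1), 3)
        assert pk.warning


class TestRelativePopulation:
    def test_identical_condition_is_one(self):
        res = relative_population([0.4, 0.5, 0.45], [0.4, 0.5, 0.45])
        assert np.isclose(res.relative_population, 1.0)

    def test_zero_condition_is_zero(self):
        res = relative_population([0.0, 0.0], [0.5, 0.6])
        assert res.relative_population == 0.0

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            relative_population([0.3], [0.0, 0.0])

    def test_simulated_lesion_ratio_recovered(self, default_model):
        """A condition with ~30% of the reference synapsis rate reads ~0.3."""
        rng = np.random.default_rng(9)
        ref_fracs, cond_fracs = [], []
        for rep in range(3):
            n = 120
            ref_syn = int(0.5 * n)
            cond_syn = rng.binomial(n, 0.15)
            ref_fracs.append(ref_syn / n)
            cond_fracs.append(cond_syn / n)
        res = relative_population(cond_fracs, ref_fracs)
        se = np.sqrt(0.15 * 0.85 / (3 * 120)) / 0.5
        assert abs(res.relative_population - 0.30) < 4 * se

    def test_classify_fraction_on_two_state_data(self, default_model):
        traces = synth.simulate_trace_set(default_model, 80, 60.0, 13)
        series, _ = analyze_traces(traces, 0.09)
        frac = classify_fraction(series, band=(0.4, np.inf))
        # tau_high=20 vs tau_low=77: most molecules' modal state is dissociated
        assert 0.0 <= frac <= 0.5


class TestEndToEndHistogram:
    def test_pipeline_recovers_high_fret_peak(self, default_model):
        traces = synth.simulate_trace_set(default_model, 600, 60.0, 99)
        series, report = analyze_traces(traces, 0.09)
        assert len(series) > 200
        pk = fit_peaks(build_histogram(series), 2)
        # apparent high-state efficiency under the printed formula
        expected = 0.78 / (1 + 0.09 * (1 - 0.78))
        assert abs(pk.means[-1] - expected) < 0.015

    def test_no_fret_values_escape_physical_band(self, default_model):
        traces = synth.simulate_trace_set(default_model, 100, 60.0, 55)
        series, _ = analyze_traces(traces, 0.09)
        blocks = np.concatenate([block_averages(s) for s in series if s.efret.size >= 25])
        assert np.all(blocks > -0.5) and np.all(blocks < 1.5)
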