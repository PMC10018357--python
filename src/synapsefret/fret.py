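"""Single-pair FRET trace selection, corrections and population analysis.

The stage mirrors standard practice for surface-immobilised smFRET data:

1. photobleaching steps are located in each trace; molecules are kept only
   if they behave like a single donor/acceptor pair (one donor bleach step,
   sane intensity, enough frames on both sides of the bleach);
2. the acceptor channel is corrected for direct excitation by subtracting
   the mean acceptor intensity in a window just after donor photobleaching;
3. apparent FRET efficiency is computed per frame as
   ``E = (I_A - beta*I_D) / (I_D + I_A)``, where ``beta`` is the donor
   bleed-through fraction calibrated by forcing the donor-only FRET peak
   to zero;
4. efficiencies averaged over 25-frame blocks are histogrammed and state
   populations are quantified by Gaussian peak fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .models import FretHistogram, FretSeries, PopulationResult, RawTrace

__all__ = [
    "detect_bleach_steps",
    "select_traces",
    "SelectionConfig",
    "correct_direct_excitation",
    "compute_fret",
    "estimate_beta",
    "block_averages",
    "build_histogram",
    "fit_peaks",
    "classify_fraction",
    "relative_population",
    "analyze_traces",
]


# ---------------------------------------------------------------------------
# step detection
# ---------------------------------------------------------------------------

def _robust_noise(x: np.ndarray) -> float:
    """Noise s.d. from the median absolute first difference."""
    d = np.abs(np.diff(x))
    return 1.4826 * float(np.median(d)) / math.sqrt(2.0)


def _best_split(x: np.ndarray, min_size: int) -> tuple[int, float] | None:
    """Index and variance-reduction gain of the best two-segment mean split."""
    n = x.size
    if n < 2 * min_size:
        return None
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    i = np.arange(min_size, n - min_size + 1)  # split before index i
    s1, s2 = c1[i - 1], c2[i - 1]
    sse_l = s2 - s1**2 / i
    nr = n - i
    sse_r = (c2[-1] - s2) - (c1[-1] - s1) ** 2 / nr
    sse_tot = c2[-1] - c1[-1] ** 2 / n
    gain = sse_tot - (sse_l + sse_r)
    k = int(np.argmax(gain))
    return int(i[k]), float(gain[k])


def detect_bleach_steps(
    trace: RawTrace | np.ndarray,
    channel: str = "donor",
    min_size: int = 5,
    k_sigma: float = 4.0,
) -> list[tuple[int, float]]:
    """Candidate downward intensity steps, largest first.

    Recursive two-segment mean splitting: each segment is split at the point
    that maximises the reduction in residual variance, and a split is kept
    when the mean change exceeds ``k_sigma`` times the robust noise level.
    Only downward steps (bleaching candidates) are returned, as
    ``(frame, magnitude)`` pairs where ``frame`` is the first frame after the
    drop.  Deterministic for fixed input.
    """
    if isinstance(trace, RawTrace):
        x = {"donor": trace.donor, "acceptor": trace.acceptor, "total": trace.total}[channel]
    else:
        x = np.asarray(trace, dtype=float)
    if x.size < 10:
        raise ValueError("trace too short for step detection (need >= 10 frames)")

    sigma = _robust_noise(x)
    scale = float(np.max(np.abs(x))) if x.size else 1.0
    thresh = max(k_sigma * sigma, 1e-9 * max(scale, 1.0))

    steps: list[tuple[int, float]] = []

    def recurse(lo: int, hi: int) -> None:
        res = _best_split(x[lo:hi], min_size)
        if res is None:
            return
        i, _gain = res
        left = x[lo : lo + i]
        right = x[lo + i : hi]
        delta = float(left.mean() - right.mean())
        if abs(delta) <= thresh:
            return
        if delta > 0:
            steps.append((lo + i, delta))
        recurse(lo, lo + i)
        recurse(lo + i, hi)

    recurse(0, x.size)
    steps.sort(key=lambda s: -s[1])
    return steps


def _sustained_steps(
    x: np.ndarray, min_size: int = 5, k_sigma: float = 4.0, recover_frac: float = 0.6
) -> list[tuple[int, float]]:
    """Downward steps after which the (smoothed) signal never recovers.

    State transitions of a FRET pair recover; photobleaching does not, so
    sustained steps in the summed intensity count bleach events.
    """
    steps = detect_bleach_steps(x, min_size=min_size, k_sigma=k_sigma)
    sm = uniform_filter1d(x, 5) if x.size >= 5 else x
    out = []
    for i, mag in steps:
        pre = float(np.mean(x[max(0, i - 20) : i]))
        if float(np.max(sm[min(i + 2, x.size - 1):])) < pre - recover_frac * mag:
            out.append((i, mag))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# trace selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionConfig:
    """Acceptance rules for single-pair traces.

    Intensity bounds refer to the mean summed intensity before the donor
    bleach; defaults bracket a single emitter at the generator's nominal
    signal level and reject aggregates at roughly twice that.
    """

    min_pre_frames: int = 25
    min_post_frames: int = 10
    min_total: float = 400.0
    max_total: float = 1800.0
    dx_window: int = 50  # frames used for the direct-excitation estimate
    donor_baseline_frac: float = 0.25  # donor tail must fall below this x pre level
    step_k_sigma: float = 4.0


@dataclass
class SelectionReport:
    accepted: list[RawTrace] = field(default_factory=list)
    donor_bleach_frames: list[int] = field(default_factory=list)
    rejected: dict[str, int] = field(default_factory=dict)
    reasons: list[str] = field(default_factory=list)  # per input trace

    def n_accepted(self) -> int:
        return len(self.accepted)


def _find_bleach_structure(
    trace: RawTrace, config: SelectionConfig
) -> tuple[int | None, str]:
    """Locate the donor bleach step; classify failures."""
    total = trace.total
    steps = _sustained_steps(total, k_sigma=config.step_k_sigma)
    big = [s for s in steps if s[1] > 0.45 * (np.percentile(total, 95) - np.min(total))]
    if len(big) == 0:
        return None, "no_donor_bleach"
    if len(big) > 1:
        return None, "multiple_donor_steps"
    frame = big[0][0]
    pre_total = float(np.mean(total[:frame]))
    donor_tail = float(np.mean(trace.donor[frame:]))
    if donor_tail > config.donor_baseline_frac * pre_total:
        return None, "donor_not_at_baseline"
    return frame, ""


def select_traces(
    traces: list[RawTrace], config: SelectionConfig | None = None
) -> SelectionReport:
    """Keep traces consistent with a single donor/acceptor pair.

    Acceptance requires exactly one donor photobleaching step, a pre-bleach
    summed intensity within the configured single-emitter bounds, and enough
    frames before the bleach (for FRET) and after it (for the
    direct-excitation estimate).  Every rejection carries a reason.
    """
    config = config or SelectionConfig()
    report = SelectionReport()
    for trace in traces:
        if len(trace) < 10:
            reason = "too_short"
        else:
            frame, reason = _find_bleach_structure(trace, config)
            if not reason:
                pre_total = float(np.mean(trace.total[:frame]))
                if not (config.min_total <= pre_total <= config.max_total):
                    reason = "intensity_out_of_bounds"
                elif frame < config.min_pre_frames:
                    reason = "short_pre_window"
                elif len(trace) - frame < config.min_post_frames:
                    reason = "short_post_window"
        if reason:
            report.rejected[reason] = report.rejected.get(reason, 0) + 1
            report.reasons.append(reason)
        else:
            report.accepted.append(trace)
            report.donor_bleach_frames.append(int(frame))
            report.reasons.append("")
    return report


# ---------------------------------------------------------------------------
# corrections and FRET computation
# ---------------------------------------------------------------------------

def correct_direct_excitation(
    trace: RawTrace,
    donor_bleach_frame: int,
    dx_window: int = 50,
    min_window: int = 10,
) -> tuple[np.ndarray, float]:
    """Subtract the direct-excitation offset from the acceptor channel.

    The offset is the mean acceptor intensity in a window just after donor
    photobleaching (capped at ``dx_window`` frames so a later acceptor bleach
    barely dilutes it), where the acceptor signal can only come from direct
    excitation by the donor-excitation laser.
    """
    post = trace.acceptor[donor_bleach_frame + 1 :]
    if post.size < min_window:
        raise ValueError("insufficient post-bleach window for direct excitation")
    window = post[:dx_window]
    # trim at a detectable acceptor bleach inside the window
    if window.size >= 10:
        steps = detect_bleach_steps(window, min_size=5, k_sigma=4.0)
        if steps:
            i = steps[0][0]
            if i >= min_window:
                window = window[:i]
    offset = float(np.mean(window))
    return trace.acceptor - offset, offset


def compute_fret(
    donor: np.ndarray,
    acceptor: np.ndarray,
    beta: float,
    valid_range: tuple[int, int] | None = None,
    frame_interval: float = 0.1,
    trace_id: str = "",
) -> FretSeries:
    """Apparent FRET efficiency ``(I_A - beta*I_D) / (I_D + I_A)`` per frame.

    ``acceptor`` must already be direct-excitation corrected.  Frames where
    the denominator is not positive are flagged invalid (NaN) and excluded
    from histograms downstream.
    """
    if not (0.0 <= beta <= 0.5):
        raise ValueError("beta must lie in [0, 0.5]")
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if valid_range is None:
        valid_range = (0, donor.size)
    start, stop = valid_range
    d = donor[start:stop]
    a = acceptor[start:stop]
    denom = d + a
    with np.errstate(divide="ignore", invalid="ignore"):
        e = (a - beta * d) / denom
    e = np.where(denom > 0, e, np.nan)
    return FretSeries(
        efret=e, valid_range=(start, stop), trace_id=trace_id,
        frame_interval=frame_interval,
    )


# ---------------------------------------------------------------------------
# bleed-through calibration
# ---------------------------------------------------------------------------

def estimate_beta(
    donor_only_traces: list[RawTrace],
    block_size: int = 25,
    bracket: tuple[float, float] = (0.0, 0.5),
    tol: float = 1e-4,
) -> float:
    """Bleed-through fraction that zeroes the donor-only FRET peak.

    For donor-only molecules the acceptor channel contains bleed-through
    only, so the block-averaged FRET histogram must peak at zero once the
    correct ``beta`` is applied.  The mode is located by kernel density
    estimation and ``beta`` found by bisection over the bracket.
    """
    if len(donor_only_traces) < 30:
        raise ValueError("need at least 30 donor-only traces to calibrate beta")

    u_blocks: list[np.ndarray] = []
    v_blocks: list[np.ndarray] = []
    for trace in donor_only_traces:
        end = len(trace)
        steps = _sustained_steps(trace.donor)
        if steps:
            end = steps[0][0]
        if end < block_size:
            continue
        d = trace.donor[:end]
        a = trace.acceptor[:end]
        denom = d + a
        ok = denom > 0
        u = np.where(ok, a / denom, np.nan)
        v = np.where(ok, d / denom, np.nan)
        n_blocks = end // block_size
        u_blocks.append(u[: n_blocks * block_size].reshape(n_blocks, block_size).mean(axis=1))
        v_blocks.append(v[: n_blocks * block_size].reshape(n_blocks, block_size).mean(axis=1))
    if not u_blocks:
        raise ValueError("no usable donor-only blocks")
    U = np.concatenate(u_blocks)
    V = np.concatenate(v_blocks)
    keep = np.isfinite(U) & np.isfinite(V)
    U, V = U[keep], V[keep]

    grid = np.linspace(-0.4, 0.6, 2001)

    def mode_at(beta: float) -> float:
        vals = U - beta * V
        kde = stats.gaussian_kde(vals)
        return float(grid[np.argmax(kde(grid))])

    lo, hi = bracket
    m_lo, m_hi = mode_at(lo), mode_at(hi)
    if m_lo < 0:
        if abs(m_lo) < 0.01:
            return lo
        raise ValueError("no zero crossing of the donor-only mode in the bracket")
    if m_hi > 0:
        raise ValueError("no zero crossing of the donor-only mode in the bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mode_at(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# histograms and peak fitting
# ---------------------------------------------------------------------------

def block_averages(series: FretSeries | np.ndarray, block_size: int = 25) -> np.ndarray:
    """Means of non-overlapping ``block_size``-frame blocks.

    Blocks are aligned to the start of the valid window; the trailing
    partial block is discarded; blocks containing invalid (NaN) frames are
    dropped.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    e = series.efret if isinstance(series, FretSeries) else np.asarray(series, float)
    n_blocks = e.size // block_size
    if n_blocks == 0:
        return np.array([])
    b = e[: n_blocks * block_size].reshape(n_blocks, block_size).mean(axis=1)
    return b[np.isfinite(b)]


def build_histogram(
    fret_series: list[FretSeries],
    block_size: int = 25,
    bin_width: float = 0.02,
    hist_range: tuple[float, float] = (-0.2, 1.2),
) -> FretHistogram:
    """Histogram of 25-frame block-averaged FRET values.

    Each complete block contributes exactly one count; values outside the
    histogram range are clipped into the edge bins so counts are conserved.
    """
    edges = np.arange(hist_range[0], hist_range[1] + 0.5 * bin_width, bin_width)
    all_blocks = [block_averages(s, block_size) for s in fret_series]
    values = np.concatenate(all_blocks) if all_blocks else np.array([])
    if values.size:
        clipped = np.clip(values, edges[0], np.nextafter(edges[-1], -np.inf))
        counts, _ = np.histogram(clipped, bins=edges)
    else:
        counts = np.zeros(edges.size - 1, dtype=int)
    return FretHistogram(
        bin_edges=edges,
        counts=counts,
        n_traces=len(fret_series),
        n_blocks=int(counts.sum()),
        block_size=block_size,
    )


@dataclass
class PeakFit:
    means: np.ndarray
    sigmas: np.ndarray
    weights: np.ndarray  # fraction of histogram mass per peak
    n_requested: int
    warning: str = ""


def _gauss_sum(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x)
    for j in range(0, len(params), 3):
        amp, mu, sig = params[j : j + 3]
        y = y + amp * np.exp(-((x - mu) ** 2) / (2 * sig**2))
    return y


def fit_peaks(histogram: FretHistogram, n_peaks: int = 2) -> PeakFit:
    """Gaussian-mixture fit to the FRET histogram.

    Initialised at the ``n_peaks`` largest local maxima of the smoothed
    counts; if fewer maxima exist the fit proceeds with those found and a
    warning flag is set.  Peaks are returned sorted by position.
    """
    if histogram.n_blocks == 0:
        raise ValueError("cannot fit peaks of an empty histogram")
    x = histogram.bin_centers
    y = histogram.counts.astype(float)
    sm = gaussian_filter1d(y, 1.0)
    interior = (sm[1:-1] >= sm[:-2]) & (sm[1:-1] >= sm[2:]) & (sm[1:-1] > 0)
    maxima = np.nonzero(interior)[0] + 1
    maxima = maxima[np.argsort(sm[maxima])[::-1]]
    warning = ""
    if maxima.size < n_peaks:
        warning = f"only {maxima.size} local maxima for {n_peaks} requested peaks"
    use = maxima[:n_peaks]
    if use.size == 0:
        use = np.array([int(np.argmax(y))])

    bw = float(x[1] - x[0])
    p0, lb, ub = [], [], []
    for idx in use:
        p0 += [max(y[idx], 1.0), float(x[idx]), 2 * bw]
        lb += [0.0, float(x[0]), bw / 2]
        ub += [np.inf, float(x[-1]), 0.5]
    try:
        popt, _ = optimize.curve_fit(
            _gauss_sum, x, y, p0=p0, bounds=(lb, ub), maxfev=20000
        )
    except RuntimeError:
        popt = np.asarray(p0)
        warning = (warning + "; " if warning else "") + "fit did not converge, returning init"
    amps = popt[0::3]
    mus = popt[1::3]
    sigs = popt[2::3]
    mass = amps * sigs
    order = np.argsort(mus)
    weights = mass[order] / mass.sum() if mass.sum() > 0 else np.full(mus.size, np.nan)
    return PeakFit(
        means=mus[order], sigmas=sigs[order], weights=weights,
        n_requested=n_peaks, warning=warning,
    )


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

def classify_fraction(
    fret_series: list[FretSeries],
    band: tuple[float, float] = (0.4, np.inf),
    block_size: int = 25,
) -> float:
    """Fraction of molecules whose modal block-averaged FRET lies in ``band``.

    The synaptic class uses ``(0.4, inf)`` (the binarization cutoff); the
    extended class uses a band such as ``(0.1, 0.4)``, configurable because
    extended-duplex FRET shifts upward for damaged substrates.
    """
    if not fret_series:
        return 0.0
    n_in = 0
    n_tot = 0
    for s in fret_series:
        blocks = block_averages(s, block_size)
        if blocks.size == 0:
            continue
        counts, edges = np.histogram(blocks, bins=np.arange(-0.3, 1.3, 0.02))
        mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        n_tot += 1
        if band[0] <= mode < band[1]:
            n_in += 1
    return n_in / n_tot if n_tot else 0.0


def relative_population(
    condition_fractions: list[float] | np.ndarray,
    reference_fractions: list[float] | np.ndarray,
    condition: str = "",
) -> PopulationResult:
    """Population of a molecular class relative to a reference condition.

    Inputs are per-replicate class fractions (typically triplicates).  The
    ratio of mean fractions is reported with its SEM propagated from the
    replicate scatter.
    """
    c = np.asarray(condition_fractions, dtype=float)
    r = np.asarray(reference_fractions, dtype=float)
    if c.size == 0 or r.size == 0:
        raise ValueError("need at least one replicate per condition")
    mc, mr = float(np.mean(c)), float(np.mean(r))
    if mr <= 0:
        raise ValueError("reference fraction is zero; relative population undefined")
    rel = mc / mr
    sem_c = float(np.std(c, ddof=1) / math.sqrt(c.size)) if c.size > 1 else 0.0
    sem_r = float(np.std(r, ddof=1) / math.sqrt(r.size)) if r.size > 1 else 0.0
    if mc > 0:
        sem = rel * math.sqrt((sem_c / mc) ** 2 + (sem_r / mr) ** 2)
    else:
        sem = sem_c / mr
    return PopulationResult(
        condition=condition,
        fraction=mc,
        reference_fraction=mr,
        relative_population=rel,
        sem=sem,
    )


# ---------------------------------------------------------------------------
# pipeline wrapper
# ---------------------------------------------------------------------------

def _acceptor_bleach_before(trace: RawTrace, donor_bleach_frame: int) -> int:
    """End of the usable FRET window: an acceptor bleach preceding the donor
    bleach truncates it (after that the acceptor channel carries no FRET).

    The acceptor-first bleach is a sustained drop of the acceptor signal to
    baseline; it can be small (bleed-through + direct excitation only when
    the molecule sits in the low-FRET state), so a permissive threshold is
    used and the candidate closest to the donor bleach wins.
    """
    a = trace.acceptor[:donor_bleach_frame]
    if a.size < 20:
        return donor_bleach_frame
    try:
        steps = detect_bleach_steps(a, min_size=5, k_sigma=2.0)
    except ValueError:
        return donor_bleach_frame
    sigma = _robust_noise(a)
    for i, mag in sorted(steps, reverse=True):
        if a.size - i < 5:
            continue
        pre = float(np.mean(a[max(0, i - 20) : i]))
        tail_mean = float(np.mean(a[i:]))
        # a dead acceptor sits at baseline: near zero in absolute terms and
        # well below the pre-step level (which still carried bleed-through)
        if tail_mean < min(0.35 * max(pre, 1.0), 2.0 * max(sigma, 1e-9)):
            return i
    return donor_bleach_frame

def analyze_traces(
    traces: list[RawTrace],
    beta: float,
    config: SelectionConfig | None = None,
) -> tuple[list[FretSeries], SelectionReport]:
    """Full per-trace stage: selection, corrections, FRET series.

    Returns corrected FRET series (over the pre-donor-bleach window of each
    accepted trace) together with the selection report.
    """
    config = config or SelectionConfig()
    report = select_traces(traces, config)
    series: list[FretSeries] = []
    kept_traces, kept_frames = [], []
    for trace, frame in zip(report.accepted, report.donor_bleach_frames):
        fret_end = _acceptor_bleach_before(trace, frame)
        try:
            acc_corr, offset = correct_direct_excitation(
                trace, frame, dx_window=config.dx_window,
                min_window=config.min_post_frames,
            )
        except ValueError:
            report.rejected["unusable_dx_window"] = (
                report.rejected.get("unusable_dx_window", 0) + 1
            )
            continue
        s = compute_fret(
            trace.donor, acc_corr, beta, valid_range=(0, fret_end),
            frame_interval=trace.frame_interval, trace_id=trace.trace_id,
        )
        s.direct_excitation_offset = offset
        s.truth = trace.truth
        series.append(s)
        kept_traces.append(trace)
        kept_frames.append(frame)
    report.accepted = kept_traces
    report.donor_bleach_frames = kept_frames
    return series, report
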