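"""Matplotlib figures for the standard outputs.

Small, deliberately plain helpers: a FRET histogram with fitted peaks, a
representative trace panel, and a semi-log survival curve with its
linear-quadratic fit.
"""

from __future__ import annotations

import numpy as np

from .models import FretHistogram, RawTrace, SurvivalCurve


def plot_fret_histogram(histogram: FretHistogram, peaks=None, ax=None):
    """Bar histogram of block-averaged FRET with optional peak overlays."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    width = histogram.bin_edges[1] - histogram.bin_edges[0]
    ax.bar(histogram.bin_centers, histogram.counts, width=width,
           color="0.6", edgecolor="none")
    if peaks is not None:
        x = np.linspace(histogram.bin_edges[0], histogram.bin_edges[-1], 400)
        for mu, sig, w in zip(peaks.means, peaks.sigmas, peaks.weights):
            amp = w * histogram.n_blocks * width / (sig * np.sqrt(2 * np.pi))
            ax.plot(x, amp * np.exp(-((x - mu) ** 2) / (2 * sig**2)), lw=1.5)
            ax.axvline(mu, color="k", ls=":", lw=0.8)
            ax.annotate(f"{mu:.2f}", (mu, ax.get_ylim()[1] * 0.9), ha="center")
    ax.set_xlabel("FRET efficiency")
    ax.set_ylabel(f"count / {histogram.block_size}-frame block")
    return ax


def plot_trace(trace: RawTrace, efret=None, ax=None):
    """Donor/acceptor intensities and, optionally, the FRET series below."""
    import matplotlib.pyplot as plt

    if ax is None:
        n_rows = 2 if efret is not None else 1
        _, axes = plt.subplots(n_rows, 1, sharex=True, figsize=(6, 2.2 * n_rows))
        axes = np.atleast_1d(axes)
    else:
        axes = np.atleast_1d(ax)
    t = np.arange(len(trace)) * trace.frame_interval
    axes[0].plot(t, trace.donor, color="green", lw=0.7, label="donor")
    axes[0].plot(t, trace.acceptor, color="magenta", lw=0.7, label="acceptor")
    axes[0].set_ylabel("intensity (a.u.)")
    axes[0].legend(frameon=False, fontsize=8)
    if efret is not None and len(axes) > 1:
        te = np.arange(len(efret)) * trace.frame_interval
        axes[1].plot(te, efret, color="navy", lw=0.7)
        axes[1].set_ylim(-0.2, 1.1)
        axes[1].set_ylabel("FRET")
    axes[-1].set_xlabel("time (s)")
    return axes


def plot_survival_curve(curve: SurvivalCurve, label: str = "", ax=None):
    """Semi-log dose-survival points with the linear-quadratic fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.4))
    ax.semilogy(curve.doses, curve.surviving_fraction, "o", ms=4, label=label or None)
    if curve.alpha is not None:
        d = np.linspace(0, curve.doses.max(), 200)
        ax.semilogy(d, np.exp(-curve.alpha * d - curve.beta_lq * d**2), "-", lw=1)
    if curve.d10 is not None:
        ax.axhline(0.1, color="0.7", ls=":", lw=0.8)
        ax.axvline(curve.d10, color="0.7", ls=":", lw=0.8)
    ax.set_xlabel("dose (Gy)")
    ax.set_ylabel("surviving fraction")
    if label:
        ax.legend(frameon=False, fontsize=8)
    return ax
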