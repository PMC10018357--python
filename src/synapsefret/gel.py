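"""Primer-extension gel quantification.

Band densities are indexed by product length: position 0 is the unreacted
primer (N0), positions 1..7 are intermediate extension products, 8 is the
full-length product (N8), and higher positions are further-extended products
(full-length strands that detach, self-anneal and extend again).  The four
lane metrics are cumulative-density ratios:

* total product    = sum(>=N1) / sum(>=N0)  (as %)
* >=Full product   = sum(>=N8) / sum(>=N0)  (as %; includes >N8)
* bypass product   = sum(>=N+1) / sum(>=N0) for a lesion templating at N
* bypass efficiency = bypass product / total product (fraction)

The common denominator is the whole lane signal sum(>=N0); all metrics are
invariant to a common rescaling of the densities.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d

from .models import BypassMetrics, GelLane

__all__ = ["quantify_lane", "lane_profile_to_bands", "FULL_LENGTH_POSITION"]

FULL_LENGTH_POSITION = 8


def _cumulative_from(lane: GelLane, position: int) -> float:
    """Summed density of all bands at or beyond ``position``."""
    return float(lane.densities[lane.positions >= position].sum())


def quantify_lane(
    lane: GelLane,
    full_position: int = FULL_LENGTH_POSITION,
    denominator: str = "whole_lane",
) -> BypassMetrics:
    """Product percentages and lesion bypass efficiency for one lane.

    ``denominator`` selects the normalisation: ``"whole_lane"`` divides
    every metric by sum(>=N0) (the default, internally consistent);
    ``"n0"`` divides the >=Full metric by the N0 band alone, an alternative
    reading of the quantification recipe.
    """
    total_signal = _cumulative_from(lane, lane.positions.min())
    if total_signal <= 0:
        raise ValueError("all-zero lane cannot be quantified")
    if lane.lesion_position is not None:
        # absent bands simply have zero density, so the lesion only needs to
        # lie within the plausible product range of the assay
        hi = max(int(lane.positions.max()), full_position)
        if not (int(lane.positions.min()) <= lane.lesion_position <= hi):
            raise ValueError("lesion position outside the lane's position range")

    if denominator not in ("whole_lane", "n0"):
        raise ValueError("denominator must be 'whole_lane' or 'n0'")
    denom_full = lane.density_at(0) if denominator == "n0" else total_signal
    total_pct = 100.0 * _cumulative_from(lane, 1) / total_signal
    full_pct = 100.0 * _cumulative_from(lane, full_position) / denom_full if denom_full > 0 else 0.0

    bypass_pct: float | None = None
    efficiency: float | None = None
    undefined = False
    if lane.lesion_position is not None:
        bypass_pct = 100.0 * _cumulative_from(lane, lane.lesion_position + 1) / total_signal
        if total_pct > 0:
            efficiency = bypass_pct / total_pct
        else:
            efficiency = 0.0
            undefined = True
    return BypassMetrics(
        total_product_pct=total_pct,
        full_product_pct=min(full_pct, 100.0),
        bypass_product_pct=bypass_pct,
        bypass_efficiency=efficiency,
        undefined=undefined or total_pct == 0,
    )


def lane_profile_to_bands(
    profile: np.ndarray,
    expected_positions: dict[int, int],
    search_radius: int = 6,
    integration_halfwidth: int = 8,
    background_window: int = 51,
    lesion_position: int | None = None,
) -> GelLane:
    """Call bands from a 1-D densitometry profile.

    ``expected_positions`` maps product position index to the expected pixel
    of the band centre.  A rolling-minimum background is subtracted, each
    band centre is refined to the local maximum within ``search_radius``
    pixels of its expected location, and the density is the integral over a
    fixed window around the refined centre.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1:
        raise ValueError("profile must be 1-D")
    if np.any(profile < 0):
        raise ValueError("profile must be non-negative")

    background = uniform_filter1d(
        minimum_filter1d(profile, background_window), background_window
    )
    signal = np.clip(profile - background, 0.0, None)

    positions, densities = [], []
    for pos in sorted(expected_positions):
        px = int(expected_positions[pos])
        lo = max(px - search_radius, 0)
        hi = min(px + search_radius + 1, signal.size)
        if hi <= lo:
            continue
        centre = lo + int(np.argmax(signal[lo:hi]))
        a = max(centre - integration_halfwidth, 0)
        b = min(centre + integration_halfwidth + 1, signal.size)
        positions.append(pos)
        densities.append(float(signal[a:b].sum()))
    lane = GelLane(
        positions=np.asarray(positions, dtype=int),
        densities=np.asarray(densities, dtype=float),
        lesion_position=lesion_position,
    )
    if lane.densities.sum() <= 0:
        raise ValueError("no bands detected in the profile")
    return lane
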