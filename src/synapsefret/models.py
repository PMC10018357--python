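"""Domain containers shared across the pipeline stages.

The containers are thin dataclasses: per-molecule fluorescence traces and their
derived FRET series, binarized state traces with dwell segments, gel-lane band
densities, and clonogenic-survival curves.  Ground-truth annotations produced
by the simulators travel alongside the data so every downstream estimator can
be checked against the values that generated its input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "KineticModel",
    "RawTrace",
    "MovieStack",
    "FretSeries",
    "FretHistogram",
    "PopulationResult",
    "BinaryTrace",
    "DwellStats",
    "GelLane",
    "BypassMetrics",
    "SurvivalDataset",
    "SurvivalCurve",
    "RBEResult",
]


@dataclass
class KineticModel:
    """Ground-truth parameters of the two-state synapsis/dissociation process.

    The molecule alternates between a high-FRET synaptic state (paired
    single-stranded tails) and a low-FRET dissociated state, with
    exponentially distributed dwell times.  Emission follows the standard
    donor/acceptor photophysics: donor bleed-through into the acceptor
    channel (``beta_true``), direct excitation of the acceptor by the donor
    laser (``direct_excitation``), single-step photobleaching of each dye,
    and additive Gaussian camera noise.

    Parameters
    ----------
    tau_high, tau_low
        Mean dwell times (s) of the synaptic (high-FRET) and dissociated
        (low-FRET) states.
    e_high, e_low, e_extended
        FRET efficiency of the synaptic state, the dissociated state, and the
        fully extended duplex.
    total_intensity
        Mean summed dye signal per frame (a.u.).
    beta_true
        Fraction of donor emission detected in the acceptor channel.
    direct_excitation
        Acceptor signal under donor excitation that is independent of FRET
        (a.u./frame).
    bleach_rate_donor, bleach_rate_acceptor
        Per-second photobleaching hazards (0 disables bleaching).
    noise_sigma
        Additive per-channel Gaussian noise s.d. (a.u.).
    frame_interval
        Camera integration time per frame (s); 0.1 s matches the recording
        rate used for the experiments this package models.
    """

    tau_high: float = 20.0
    tau_low: float = 77.0
    e_high: float = 0.78
    e_low: float = 0.0
    e_extended: float = 0.16
    total_intensity: float = 1000.0
    beta_true: float = 0.09
    direct_excitation: float = 30.0
    bleach_rate_donor: float = 1.0 / 30.0
    bleach_rate_acceptor: float = 1.0 / 60.0
    noise_sigma: float = 50.0
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        if self.tau_high <= 0 or self.tau_low <= 0:
            raise ValueError("state lifetimes must be positive")
        if not (0.0 <= self.e_low < self.e_high <= 1.0):
            raise ValueError("require 0 <= e_low < e_high <= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be positive")
        if not (0.0 <= self.beta_true <= 0.5):
            raise ValueError("beta_true outside the plausible [0, 0.5] range")
        if self.bleach_rate_donor < 0 or self.bleach_rate_acceptor < 0:
            raise ValueError("bleach rates must be non-negative")


@dataclass
class TraceTruth:
    """Latent generator state attached to a simulated :class:`RawTrace`."""

    state_labels: np.ndarray | None = None  # per-frame majority state (1=high)
    high_fraction: np.ndarray | None = None  # per-frame fractional occupancy
    donor_bleach_frame: int | None = None  # first frame fully after donor bleach
    acceptor_bleach_frame: int | None = None
    donor_bleach_time: float | None = None
    acceptor_bleach_time: float | None = None
    dwells_high: np.ndarray | None = None  # continuous-time dwells (s)
    dwells_low: np.ndarray | None = None
    model: KineticModel | None = None
    n_emitters: int = 1
    kind: str = "two_state"


@dataclass
class RawTrace:
    """Per-frame donor and acceptor intensities for one molecule."""

    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval: float
    trace_id: str = ""
    truth: TraceTruth | None = None

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape or self.donor.ndim != 1:
            raise ValueError("donor and acceptor must be 1-D and equal length")
        if self.donor.size < 1:
            raise ValueError("trace must contain at least one frame")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return int(self.donor.size)

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor


@dataclass
class MovieStack:
    """Two-channel synthetic movie with ground-truth emitter positions."""

    frames: np.ndarray  # (n_frames, 2, height, width); channel 0=donor
    spot_truth: list[tuple[float, float, str]]
    psf_sigma: float
    frame_interval: float = 0.1
    background: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[1] != 2:
            raise ValueError("frames must have shape (n_frames, 2, h, w)")
        if np.any(self.frames < 0):
            raise ValueError("pixel values must be non-negative")
        h, w = self.frames.shape[2:]
        for x, y, _ in self.spot_truth:
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError("spot position outside image bounds")


@dataclass
class FretSeries:
    """Corrected FRET-efficiency time series over the usable frame window."""

    efret: np.ndarray  # invalid frames are NaN
    valid_range: tuple[int, int]  # [start, stop) frames of the source trace
    trace_id: str = ""
    frame_interval: float = 0.1
    direct_excitation_offset: float = 0.0
    truth: TraceTruth | None = None

    def __post_init__(self) -> None:
        self.efret = np.asarray(self.efret, dtype=float)
        start, stop = self.valid_range
        if not (0 <= start <= stop):
            raise ValueError("invalid frame window")
        if self.efret.size != stop - start:
            raise ValueError("efret length must match the frame window")


@dataclass
class FretHistogram:
    """Histogram of block-averaged FRET values.

    Each contribution is the mean efficiency over ``block_size`` consecutive
    frames, so ``counts.sum()`` equals the number of complete blocks.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_traces: int
    n_blocks: int
    block_size: int = 25

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("counts/bin_edges size mismatch")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PopulationResult:
    """Relative population of a molecular class versus a reference condition."""

    condition: str
    fraction: float
    reference_fraction: float
    relative_population: float
    sem: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0 and 0.0 <= self.reference_fraction <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.relative_population < 0:
            raise ValueError("relative population must be non-negative")


@dataclass
class BinaryTrace:
    """Thresholded two-state trace stored as alternating dwell segments.

    Segments tile the trace; ``dt`` converts segment lengths (samples) into
    seconds.  The first and last segments are censored: the molecule was
    already in that state when observation started/stopped, so their true
    durations are unknown.  Long concatenated traces are stored as segments
    only; the per-sample label vector is materialised on demand.
    """

    seg_states: np.ndarray  # 1=high, 0=low, alternating
    seg_lengths: np.ndarray  # samples, > 0
    dt: float  # seconds per sample
    censored_first: bool = True
    censored_last: bool = True
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.seg_states = np.asarray(self.seg_states, dtype=np.int8)
        self.seg_lengths = np.asarray(self.seg_lengths, dtype=np.int64)
        if self.seg_states.size != self.seg_lengths.size:
            raise ValueError("segment arrays must have equal length")
        if self.seg_states.size == 0:
            raise ValueError("binary trace must contain at least one segment")
        if np.any(self.seg_lengths <= 0):
            raise ValueError("segment lengths must be positive")
        if np.any(self.seg_states[1:] == self.seg_states[:-1]):
            raise ValueError("segments must alternate states")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.seg_lengths.sum())

    @property
    def duration(self) -> float:
        return float(self.n_samples * self.dt)

    @property
    def states(self) -> np.ndarray:
        """Per-sample state labels (1=high). Materialised on demand."""
        return np.repeat(self.seg_states, self.seg_lengths)

    @property
    def start_state(self) -> int:
        return int(self.seg_states[0])

    @property
    def end_state(self) -> int:
        return int(self.seg_states[-1])


@dataclass
class DwellStats:
    """Mean/SEM dwell times from several independently concatenated traces."""

    mean_high: float
    sem_high: float
    mean_low: float
    sem_low: float
    n_dwells_high: int
    n_dwells_low: int
    n_concatenated: int
    per_concat_mean_high: np.ndarray = field(default_factory=lambda: np.array([]))
    per_concat_mean_low: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class GelLane:
    """Band densities of one primer-extension gel lane.

    Positions are integer product lengths: 0 is the unreacted primer (N0),
    1..7 intermediate extension positions, 8 the full-length product (N8) and
    anything >8 the further-extended products that re-anneal and extend past
    full length.
    """

    positions: np.ndarray  # strictly increasing ints
    densities: np.ndarray  # a.u., >= 0
    lesion_position: int | None = None
    truth_fractions: dict[int, float] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.positions.shape != self.densities.shape or self.positions.ndim != 1:
            raise ValueError("positions/densities must be matching 1-D arrays")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.densities < 0):
            raise ValueError("band densities must be non-negative")

    def density_at(self, position: int) -> float:
        idx = np.nonzero(self.positions == position)[0]
        return float(self.densities[idx[0]]) if idx.size else 0.0


@dataclass
class BypassMetrics:
    """Lane-level product percentages and lesion bypass efficiency."""

    total_product_pct: float
    full_product_pct: float
    bypass_product_pct: float | None
    bypass_efficiency: float | None
    undefined: bool = False  # True when total product is zero

    def __post_init__(self) -> None:
        for v in (self.total_product_pct, self.full_product_pct):
            if not (0.0 <= v <= 100.0):
                raise ValueError("percentages must lie in [0, 100]")
        if self.bypass_product_pct is not None and not (
            0.0 <= self.bypass_product_pct <= 100.0
        ):
            raise ValueError("percentages must lie in [0, 100]")
        if self.bypass_efficiency is not None and not (
            0.0 <= self.bypass_efficiency <= 1.0
        ):
            raise ValueError("bypass efficiency must lie in [0, 1]")


@dataclass
class SurvivalDataset:
    """Raw colony counts from a simulated clonogenic survival experiment."""

    doses: np.ndarray  # Gy, one entry per well
    cells_plated: np.ndarray
    colonies: np.ndarray
    replicate: np.ndarray
    truth: dict[str, Any] | None = None


@dataclass
class SurvivalCurve:
    """Dose-survival points with an optional linear-quadratic fit."""

    doses: np.ndarray
    surviving_fraction: np.ndarray
    replicate: np.ndarray
    plating_efficiency: float
    alpha: float | None = None  # Gy^-1
    beta_lq: float | None = None  # Gy^-2
    d10: float | None = None
    excluded: np.ndarray | None = None  # mask of SF=0 points left out of fits


@dataclass
class RBEResult:
    """Relative biological effectiveness at 10% survival."""

    d10_reference: float  # X-ray, Gy
    d10_test: float  # carbon ion, Gy
    rbe_d10: float
    rbe_d10_display: float  # rounded to 2 d.p. for reporting

    def __post_init__(self) -> None:
        if self.d10_reference <= 0 or self.d10_test <= 0:
            raise ValueError("D10 values must be positive")
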