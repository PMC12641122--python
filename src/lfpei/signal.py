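"""Recording data model, zero-phase band filtering, Hilbert envelopes and
vigilance-aware interval concatenation.

All downstream stages (DFA, fE/I, PAC, event detection) consume the
primitives defined here.  Filtering is zero-phase FIR (``filtfilt``) with an
order covering at least three cycles of the band's low edge, which preserves
phase for phase-amplitude coupling and keeps narrow low-frequency bands
stable.  Hilbert-transform edge artifacts are removed by trimming two
low-edge cycles (``ceil(2 / lo)`` seconds) from each side of every
independently filtered interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, firwin, hilbert

from .bands import Band

EPOCH_S = 5.0  # vigilance scoring epoch length (s)

VIGILANCE_STATES = ("active_wake", "quiet_wake", "sleep")

REGIONS = ("PFC", "PTC", "HC")
HC_LAYERS = ("supra_pyramidal", "pyramidal", "infra_pyramidal")


class SegmentTooShortError(ValueError):
    """Segment shorter than the filter warm-up."""


class AlignmentError(ValueError):
    """Vigilance annotation not aligned with the recording."""


@dataclass(frozen=True)
class ChannelMeta:
    name: str
    region: str
    hc_layer: str | None = None
    hemisphere: str = "unknown"

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.region == "HC":
            if self.hc_layer not in HC_LAYERS:
                raise ValueError("HC channels require an hc_layer")
        elif self.hc_layer is not None:
            raise ValueError("hc_layer is only meaningful for HC channels")


@dataclass
class Recording:
    """Multichannel LFP voltage traces (µV) with channel metadata."""

    data: np.ndarray  # (n_channels, n_samples) float
    fs: float
    channels: list[ChannelMeta]
    subject_id: str = ""
    age_week: int | None = None
    age_month: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel metadata does not match data rows")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None

    def get(self, name: str) -> np.ndarray:
        return self.data[self.channel_index(name)]


@dataclass(frozen=True)
class IntervalSet:
    """Sorted, non-overlapping half-open intervals [start_s, end_s)."""

    intervals: tuple[tuple[float, float], ...]
    state: str = ""

    def __post_init__(self):
        prev_end = -math.inf
        for s, e in self.intervals:
            if not e > s:
                raise ValueError("intervals must have end > start")
            if s < prev_end:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_end = e

    @property
    def total_s(self) -> float:
        return sum(e - s for s, e in self.intervals)


@dataclass
class Envelope:
    """Amplitude envelope of one band of one channel."""

    values: np.ndarray
    fs: float
    band: Band
    source_channel: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("envelope values must be nonnegative")


@dataclass
class VigilanceTrack:
    """Per-epoch vigilance labels plus the features used to score them."""

    labels: list[str]
    epoch_s: float = EPOCH_S
    delta_theta: np.ndarray | None = None
    velocity: np.ndarray | None = None

    def __post_init__(self):
        bad = set(self.labels) - set(VIGILANCE_STATES)
        if bad:
            raise ValueError(f"unknown vigilance labels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def intervals(self, state: str) -> IntervalSet:
        """Merge consecutive epochs of ``state`` into half-open intervals.

        Epoch ``i`` covers ``[epoch_s * i, epoch_s * (i + 1))`` seconds.
        """
        ivals: list[tuple[float, float]] = []
        start = None
        for i, lab in enumerate(self.labels):
            if lab == state and start is None:
                start = i
            elif lab != state and start is not None:
                ivals.append((start * self.epoch_s, i * self.epoch_s))
                start = None
        if start is not None:
            ivals.append((start * self.epoch_s, len(self.labels) * self.epoch_s))
        return IntervalSet(tuple(ivals), state=state)


def design_bandpass(band: Band, fs: float, min_cycles: float = 3.0) -> np.ndarray:
    """FIR band-pass taps for ``band``.

    The order covers at least ``min_cycles`` cycles of the band's low edge
    (keeps narrow low-frequency bands stable) and is additionally long
    enough that the transition width does not exceed the bandwidth — the
    binding constraint for narrow constant-bandwidth grids such as the PAC
    comodulogram bands, where a 3-cycle filter would be nearly all skirt.
    """
    if band.hi >= fs / 2:
        raise ValueError(f"band {band.label} exceeds the Nyquist frequency {fs / 2}")
    numtaps = int(math.ceil(fs * max(min_cycles / band.lo,
                                     3.3 / (band.hi - band.lo))))
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay
    # widen the cutoffs by a fraction of the transition width so the
    # equivalent noise bandwidth matches the nominal band (firwin places
    # half-amplitude points at the cutoffs, which would otherwise shave
    # ~20 % off in-band power)
    tw = 3.3 * fs / numtaps
    lo = max(band.lo - 0.12 * tw, 0.5 * band.lo, 0.01)
    hi = min(band.hi + 0.12 * tw, 0.499 * fs)
    return firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)


def bandpass(x: np.ndarray, fs: float, band: Band, min_cycles: float = 3.0) -> np.ndarray:
    """Zero-phase FIR band-pass of ``x``; output has the same length.

    The FIR is symmetric (linear phase), so centred convolution compensates
    the group delay exactly — zero phase in a single pass.  The first and
    last half-kernel of samples carry edge taper; callers trim envelope
    edges anyway (see :func:`edge_trim_s`).
    """
    x = np.asarray(x, dtype=float)
    taps = design_bandpass(band, fs, min_cycles)
    if x.size <= len(taps):
        raise SegmentTooShortError(
            f"segment of {x.size} samples shorter than filter order {len(taps)}"
        )
    return fftconvolve(x, taps, mode="same")


def envelope(filtered: np.ndarray, fs: float, band: Band, source_channel: str = "") -> Envelope:
    """Amplitude envelope: magnitude of the analytic (Hilbert) signal."""
    filtered = np.asarray(filtered, dtype=float)
    if not np.all(np.isfinite(filtered)):
        raise ValueError("non-finite input")
    return Envelope(np.abs(hilbert(filtered)), fs, band, source_channel)


def edge_trim_s(band: Band) -> float:
    """Seconds trimmed from each side of a filtered interval (2 low-edge cycles)."""
    return math.ceil(2.0 / band.lo)


def band_envelope_segments(
    x: np.ndarray,
    fs: float,
    band: Band,
    intervals: IntervalSet | None = None,
    trim_s: float | None = None,
) -> tuple[list[np.ndarray], list[tuple[float, float]]]:
    """Filter + envelope each interval independently, trimming edges.

    Filtering precedes concatenation, so no window downstream ever straddles
    an interval seam.  Intervals too short to filter or fully consumed by the
    edge trim are dropped.  Returns (envelope segments, kept raw intervals).
    """
    if intervals is None:
        intervals = IntervalSet(((0.0, len(x) / fs),))
    if trim_s is None:
        trim_s = edge_trim_s(band)
    trim = int(round(trim_s * fs))
    segs: list[np.ndarray] = []
    kept: list[tuple[float, float]] = []
    for s, e in intervals.intervals:
        seg = x[int(round(s * fs)) : int(round(e * fs))]
        try:
            filt = bandpass(seg, fs, band)
        except SegmentTooShortError:
            continue
        env = np.abs(hilbert(filt))
        if trim > 0:
            env = env[trim:-trim] if env.size > 2 * trim else env[:0]
        if env.size:
            segs.append(env)
            kept.append((s, e))
    return segs, kept


@dataclass
class Concatenation:
    """Per-channel concatenated state intervals with provenance."""

    segments: dict[str, list[np.ndarray]]  # channel -> list of raw segments
    intervals: IntervalSet
    state: str
    total_s: float
    included: bool
    reason: str = ""


def concatenate_state(
    recording: Recording,
    annotation: VigilanceTrack,
    state: str,
    min_total_s: float = 120.0,
) -> Concatenation:
    """Collect all intervals of ``state``; excluded if they total < ``min_total_s``.

    The annotation must tile the recording in 5-s epochs (the last partial
    epoch of the recording may be unannotated).
    """
    n_epochs = len(annotation)
    if n_epochs * annotation.epoch_s > recording.duration_s + annotation.epoch_s:
        raise AlignmentError(
            f"{n_epochs} epochs of {annotation.epoch_s}s exceed the "
            f"{recording.duration_s:.1f}s recording"
        )
    ivals = annotation.intervals(state)
    total = ivals.total_s
    if total < min_total_s:
        return Concatenation({}, ivals, state, total, included=False,
                             reason=f"only {total:.0f}s of {state} (< {min_total_s:.0f}s)")
    segs = {
        meta.name: [
            recording.data[i, int(round(s * recording.fs)) : int(round(e * recording.fs))]
            for s, e in ivals.intervals
        ]
        for i, meta in enumerate(recording.channels)
    }
    return Concatenation(segs, ivals, state, total, included=True)
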