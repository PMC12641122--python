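"""Theta-gamma phase-amplitude coupling via the KL modulation index.

The modulation index (MI) compares the distribution of fast-oscillation
amplitude across slow-oscillation phase bins with the uniform distribution:
18 bins of 20 degrees, P_j = mean amplitude in bin j normalized to sum 1,
KL = log(N) + sum_j P_j log P_j (natural log), MI = KL / log(N), so
MI is 0 for phase-independent amplitude and 1 when all amplitude mass falls
in a single bin.  Comodulograms scan a grid of phase and amplitude bands;
printed grid frequencies are band *centers* and bands span center +- bw/2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .bands import Band
from .signal import (
    IntervalSet,
    Recording,
    VigilanceTrack,
    bandpass,
    SegmentTooShortError,
)

log = logging.getLogger(__name__)

N_PHASE_BINS = 18
THETA_RANGE = (4.0, 10.0)
LOW_GAMMA_RANGE = (40.0, 90.0)
HIGH_GAMMA_RANGE = (90.0, 160.0)
TOTAL_GAMMA_RANGE = (40.0, 300.0)


class InsufficientDataError(ValueError):
    """An empty phase bin: duration too short for the phase frequency."""


@dataclass
class Comodulogram:
    phase_centers: np.ndarray
    amp_centers: np.ndarray
    mi: np.ndarray  # (n_phase, n_amp)
    channel: str = ""
    state: str = ""
    minutes_used: float = 0.0

    def __post_init__(self):
        assert self.mi.shape == (len(self.phase_centers), len(self.amp_centers))


@dataclass
class PACSummary:
    theta_low_gamma: float
    theta_high_gamma: float
    theta_total_gamma: float | None = None  # hippocampal channels only


def modulation_index(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = N_PHASE_BINS
) -> float:
    """KL modulation index of ``amplitude`` over ``phase`` bins.

    Phase bins are half-open, starting at -pi.  Raises
    :class:`InsufficientDataError` if any bin receives no samples.
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    if np.any(amplitude < 0):
        raise ValueError("amplitude must be nonnegative")
    idx = np.floor((phase + np.pi) / (2 * np.pi / n_bins)).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # phase == +pi lands in the last bin
    counts = np.bincount(idx, minlength=n_bins)
    if np.any(counts == 0):
        raise InsufficientDataError(
            "empty phase bin: record longer relative to the phase frequency"
        )
    mean_amp = np.bincount(idx, weights=amplitude, minlength=n_bins) / counts
    total = mean_amp.sum()
    if total == 0:
        return 0.0
    p = mean_amp / total
    nz = p > 0
    kl = np.log(n_bins) + float(np.sum(p[nz] * np.log(p[nz])))
    # KL >= 0 analytically; rounding can leave a ~1e-16 negative residue
    return min(max(kl / np.log(n_bins), 0.0), 1.0)


def phase_grid_bands(
    lo_c: float = 2.0, hi_c: float = 14.0, step: float = 1.0, bw: float = 2.0
) -> list[Band]:
    """Phase-frequency bands: centers ``lo_c..hi_c`` in steps of ``step``."""
    centers = np.arange(lo_c, hi_c + step / 2, step)
    return [Band(c - bw / 2, c + bw / 2, label=f"{c:g} Hz") for c in centers]


def amp_grid_bands(
    region: str = "PTC",
    fs: float | None = None,
    lo_c: float | None = None,
    hi_c: float | None = None,
    step: float | None = None,
    bw: float | None = None,
) -> list[Band]:
    """Amplitude-frequency bands; defaults depend on the brain region.

    Cortical channels: centers 40-200 Hz, 2 Hz bandwidth, 1 Hz steps.
    Hippocampal channels: centers 40-300 Hz, 4 Hz bandwidth, 2 Hz steps.
    Bands whose upper edge would reach the Nyquist frequency are dropped
    with a warning (truncated grid) rather than erroring.
    """
    if region == "HC":
        lo_c = 40.0 if lo_c is None else lo_c
        hi_c = 300.0 if hi_c is None else hi_c
        step = 2.0 if step is None else step
        bw = 4.0 if bw is None else bw
    else:
        lo_c = 40.0 if lo_c is None else lo_c
        hi_c = 200.0 if hi_c is None else hi_c
        step = 1.0 if step is None else step
        bw = 2.0 if bw is None else bw
    centers = np.arange(lo_c, hi_c + step / 2, step)
    bands = []
    n_dropped = 0
    for c in centers:
        if fs is not None and c + bw / 2 >= fs / 2:
            n_dropped += 1
            continue
        bands.append(Band(c - bw / 2, c + bw / 2, label=f"{c:g} Hz"))
    if n_dropped:
        log.warning(
            "amplitude grid truncated: %d bands above Nyquist (fs=%s) dropped",
            n_dropped, fs,
        )
    return bands


def _pooled_analytic(
    segments: list[np.ndarray], fs: float, band: Band, trim: int, kind: str
) -> np.ndarray | None:
    """Filter each segment in ``band``, take Hilbert phase or magnitude,
    trim ``trim`` samples per side, pool across segments."""
    outs = []
    for seg in segments:
        try:
            filt = bandpass(seg, fs, band)
        except SegmentTooShortError:
            continue
        a = hilbert(filt)
        v = np.angle(a) if kind == "phase" else np.abs(a)
        if trim > 0:
            v = v[trim:-trim] if v.size > 2 * trim else v[:0]
        if v.size:
            outs.append(v)
    if not outs:
        return None
    return np.concatenate(outs)


def comodulogram(
    segments: np.ndarray | list[np.ndarray],
    fs: float,
    phase_bands: list[Band] | None = None,
    amp_bands: list[Band] | None = None,
    region: str = "PTC",
    n_bins: int = N_PHASE_BINS,
    channel: str = "",
    state: str = "",
) -> Comodulogram:
    """MI over every (phase band, amplitude band) pair.

    Each unique band is filtered once per segment; phase/amplitude samples
    are pooled across segments (seam-respecting) and share one common edge
    trim — two cycles of the slowest phase band — so every series stays
    sample-aligned.
    """
    if isinstance(segments, np.ndarray):
        segments = [segments]
    segments = [np.asarray(s, dtype=float) for s in segments]
    if phase_bands is None:
        phase_bands = phase_grid_bands()
    if amp_bands is None:
        amp_bands = amp_grid_bands(region, fs=fs)
    min_lo = min(b.lo for b in phase_bands)
    trim = int(round(np.ceil(2.0 / min_lo) * fs))
    phases = [_pooled_analytic(segments, fs, b, trim, "phase") for b in phase_bands]
    amps = [_pooled_analytic(segments, fs, b, trim, "amplitude") for b in amp_bands]
    n_used = sum(s.size for s in segments)
    mi = np.full((len(phase_bands), len(amp_bands)), np.nan)
    for i, ph in enumerate(phases):
        if ph is None:
            continue
        idx = np.floor((ph + np.pi) / (2 * np.pi / n_bins)).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        if np.any(counts == 0):
            continue
        for j, am in enumerate(amps):
            if am is None:
                continue
            mean_amp = np.bincount(idx, weights=am, minlength=n_bins) / counts
            total = mean_amp.sum()
            if total == 0:
                mi[i, j] = 0.0
                continue
            p = mean_amp / total
            nz = p > 0
            kl = np.log(n_bins) + float(np.sum(p[nz] * np.log(p[nz])))
            mi[i, j] = min(max(kl / np.log(n_bins), 0.0), 1.0)
    return Comodulogram(
        phase_centers=np.array([b.center for b in phase_bands]),
        amp_centers=np.array([b.center for b in amp_bands]),
        mi=mi,
        channel=channel,
        state=state,
        minutes_used=n_used / fs / 60.0,
    )


def band_average(
    com: Comodulogram,
    phase_range: tuple[float, float],
    amp_range: tuple[float, float],
) -> float:
    """Mean MI over cells with phase center and amp center inside the ranges
    (inclusive bounds)."""
    pm = (com.phase_centers >= phase_range[0]) & (com.phase_centers <= phase_range[1])
    am = (com.amp_centers >= amp_range[0]) & (com.amp_centers <= amp_range[1])
    if not pm.any() or not am.any():
        raise ValueError(f"empty selection {phase_range} x {amp_range}")
    cells = com.mi[np.ix_(pm, am)]
    return float(np.nanmean(cells))


def summarize(com: Comodulogram, region: str) -> PACSummary:
    """Theta x gamma band-averaged MI; total-gamma only for HC channels.

    A summary whose gamma range has no grid cells (e.g. a high-gamma range
    on a truncated or coarse grid) is reported as NaN rather than erroring.
    """
    def _avg(amp_range):
        try:
            return band_average(com, THETA_RANGE, amp_range)
        except ValueError:
            return float("nan")

    low = _avg(LOW_GAMMA_RANGE)
    high = _avg(HIGH_GAMMA_RANGE)
    total = _avg(TOTAL_GAMMA_RANGE) if region == "HC" else None
    return PACSummary(low, high, total)


@dataclass
class MonthlyPAC:
    comodulogram: Comodulogram
    summary: PACSummary
    minutes_used: float
    shortfall: bool
    excluded: bool = False
    reason: str = ""


def monthly_pac(
    weekly: list[tuple[Recording, VigilanceTrack]],
    channel: str,
    region: str,
    target_minutes: float = 10.0,
    state: str = "active_wake",
    phase_bands: list[Band] | None = None,
    amp_bands: list[Band] | None = None,
) -> MonthlyPAC:
    """Monthly PAC: concatenate a month's active-wake intervals across its
    weekly recordings in chronological order, truncate to ``target_minutes``,
    and compute one comodulogram + summary.

    ``minutes_used`` may fall short of the target; the result is then
    flagged rather than dropped.
    """
    target_n = None
    segs: list[np.ndarray] = []
    fs = None
    for rec, ann in weekly:
        fs = rec.fs
        if target_n is None:
            target_n = int(round(target_minutes * 60 * fs))
        x = rec.get(channel)
        for s, e in ann.intervals(state).intervals:
            seg = x[int(round(s * fs)) : int(round(e * fs))]
            have = sum(v.size for v in segs)
            if have >= target_n:
                break
            if have + seg.size > target_n:
                seg = seg[: target_n - have]
            if seg.size:
                segs.append(seg)
    if not segs or fs is None:
        empty = Comodulogram(np.empty(0), np.empty(0), np.empty((0, 0)), channel, state, 0.0)
        return MonthlyPAC(empty, PACSummary(np.nan, np.nan), 0.0, True,
                          excluded=True, reason="no active-wake data")
    com = comodulogram(
        segs, fs, phase_bands=phase_bands, amp_bands=amp_bands,
        region=region, channel=channel, state=state,
    )
    minutes = sum(s.size for s in segs) / fs / 60.0
    return MonthlyPAC(com, summarize(com, region), minutes, shortfall=minutes < target_minutes - 1e-9)
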