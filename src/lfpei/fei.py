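"""Functional excitation-inhibition ratio (fE/I).

fE/I is computed from a band-limited amplitude envelope: the envelope's
signal profile is divided into 5-s windows with 80 % overlap; each window's
profile segment is normalized by the window's mean envelope amplitude and
linearly detrended, and the residual RMS is the normalized fluctuation
nF(t).  fE/I = 1 - Pearson(w_amp, nF).  Values near 1 indicate balanced
excitation/inhibition, > 1 excitation dominance, < 1 inhibition dominance.
fE/I is only defined when the envelope shows long-range temporal
correlations, so it is gated on the DFA exponent (missing when beta < 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .bands import Band
from .dfa import DFAEstimationError, DFAResult, dfa, detrended_window_rms, signal_profile
from .signal import (
    Concatenation,
    Envelope,
    Recording,
    VigilanceTrack,
    band_envelope_segments,
    concatenate_state,
)

DEFAULT_WINDOW_S = 5.0
DEFAULT_OVERLAP = 0.8
DEFAULT_BETA_THRESHOLD = 0.6
DEFAULT_MIN_WINDOWS = 40  # ~ the window count implied by the 2-min minimum
DEFAULT_MIN_TOTAL_S = 120.0


class MissingReason(str, Enum):
    none = "none"
    low_dfa = "low_dfa"
    too_short = "too_short"
    degenerate = "degenerate"
    excluded = "excluded"


@dataclass
class FEIWindowSet:
    starts_s: np.ndarray
    w_amp: np.ndarray
    nF: np.ndarray
    window_s: float
    overlap_frac: float


@dataclass
class FEIResult:
    fei: float | None
    missing_reason: MissingReason
    r: float | None
    dfa_beta: float | None
    n_windows: int
    band: Band | None = None
    channel: str = ""

    @property
    def is_missing(self) -> bool:
        return self.missing_reason is not MissingReason.none


def fei_windows(
    envelope_segments: Envelope | np.ndarray | list[np.ndarray],
    fs: float | None = None,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_frac: float = DEFAULT_OVERLAP,
    segment_offsets_s: list[float] | None = None,
) -> FEIWindowSet:
    """Windowed amplitude and normalized fluctuation of an envelope.

    Multi-segment input is seam-respecting: the signal profile is built per
    segment (centered on the pooled envelope mean) and windows are laid out
    within segments only, then pooled.  A 120-s single segment with 5-s
    windows at 80 % overlap yields floor((120-5)/1)+1 = 116 windows.
    """
    if isinstance(envelope_segments, Envelope):
        fs = envelope_segments.fs
        segs = [envelope_segments.values]
    elif isinstance(envelope_segments, np.ndarray):
        segs = [np.asarray(envelope_segments, dtype=float)]
    else:
        segs = [np.asarray(s, dtype=float) for s in envelope_segments]
    if fs is None:
        raise ValueError("fs is required for array input")
    segs = [s for s in segs if s.size >= 2]
    win = int(round(window_s * fs))
    step = max(1, int(round(window_s * (1 - overlap_frac) * fs)))
    n_total = sum(s.size for s in segs)
    if n_total == 0:
        return FEIWindowSet(np.empty(0), np.empty(0), np.empty(0), window_s, overlap_frac)
    gmean = float(sum(s.sum() for s in segs) / n_total)

    starts_all, amp_all, nf_all = [], [], []
    if segment_offsets_s is None:
        segment_offsets_s = list(np.cumsum([0.0] + [s.size / fs for s in segs[:-1]]))
    for seg, off in zip(segs, segment_offsets_s):
        if seg.size < win:
            continue
        profile = signal_profile(seg, global_mean=gmean)
        # nF of (window / w_amp) equals the window's detrended RMS / w_amp:
        # the per-window scaling commutes with detrending
        rms, starts = detrended_window_rms(profile, win, step)
        csum = np.concatenate([[0.0], np.cumsum(seg)])
        amp = (csum[starts + win] - csum[starts]) / win
        nf = rms / amp
        starts_all.append(off + starts / fs)
        amp_all.append(amp)
        nf_all.append(nf)
    if not starts_all:
        return FEIWindowSet(np.empty(0), np.empty(0), np.empty(0), window_s, overlap_frac)
    return FEIWindowSet(
        np.concatenate(starts_all),
        np.concatenate(amp_all),
        np.concatenate(nf_all),
        window_s,
        overlap_frac,
    )


def compute_fei(
    envelope_segments: Envelope | np.ndarray | list[np.ndarray],
    dfa_result: DFAResult | None = None,
    fs: float | None = None,
    beta_threshold: float = DEFAULT_BETA_THRESHOLD,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_frac: float = DEFAULT_OVERLAP,
    min_windows: int = DEFAULT_MIN_WINDOWS,
    band: Band | None = None,
    channel: str = "",
) -> FEIResult:
    """fE/I of one envelope, gated on DFA.

    All failure paths are typed (:class:`MissingReason`), never silent NaN:
    ``low_dfa`` when beta < ``beta_threshold``, ``too_short`` when fewer
    than ``min_windows`` windows fit, ``degenerate`` when w_amp or nF has
    zero variance.
    """
    if isinstance(envelope_segments, Envelope):
        fs = envelope_segments.fs
    if dfa_result is None:
        try:
            dfa_result = dfa(envelope_segments, fs=fs)
        except DFAEstimationError:
            return FEIResult(None, MissingReason.too_short, None, None, 0, band, channel)
    beta = dfa_result.beta
    ws = fei_windows(envelope_segments, fs=fs, window_s=window_s, overlap_frac=overlap_frac)
    n = len(ws.w_amp)
    if beta < beta_threshold:
        return FEIResult(None, MissingReason.low_dfa, None, beta, n, band, channel)
    if n < min_windows:
        return FEIResult(None, MissingReason.too_short, None, beta, n, band, channel)
    if np.ptp(ws.w_amp) == 0 or np.ptp(ws.nF) == 0:
        return FEIResult(None, MissingReason.degenerate, None, beta, n, band, channel)
    r = float(np.corrcoef(ws.w_amp, ws.nF)[0, 1])
    return FEIResult(1.0 - r, MissingReason.none, r, beta, n, band, channel)


def fei_spectrum(
    recording: Recording,
    channel: str,
    band_grid: list[Band],
    annotation: VigilanceTrack,
    state: str = "quiet_wake",
    min_total_s: float = DEFAULT_MIN_TOTAL_S,
    beta_threshold: float = DEFAULT_BETA_THRESHOLD,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_frac: float = DEFAULT_OVERLAP,
    min_windows: int = DEFAULT_MIN_WINDOWS,
    concat: Concatenation | None = None,
) -> list[FEIResult]:
    """Per-band fE/I for one channel, restricted to ``state`` intervals.

    The whole recording is excluded (every band reported as ``excluded``)
    when the state's intervals total less than ``min_total_s`` seconds.
    """
    if concat is None:
        concat = concatenate_state(recording, annotation, state, min_total_s)
    if not concat.included:
        return [
            FEIResult(None, MissingReason.excluded, None, None, 0, b, channel)
            for b in band_grid
        ]
    x = recording.get(channel)
    results = []
    for b in band_grid:
        segs, _ = band_envelope_segments(x, recording.fs, b, concat.intervals)
        res = compute_fei(
            segs,
            fs=recording.fs,
            beta_threshold=beta_threshold,
            window_s=window_s,
            overlap_frac=overlap_frac,
            min_windows=min_windows,
            band=b,
            channel=channel,
        )
        results.append(res)
    return results
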