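"""Rule-based epileptiform event detection.

Candidate transients are found with the nonlinear energy operator (NEO),
psi[n] = x[n]^2 - x[n-1] x[n+1], smoothed and thresholded at a multiple of
its mean.  Candidates are then classified:

* giant spikes — simultaneous candidates on every channel, amplitude beyond
  +-10 robust SD on at least one hippocampal channel, followed by a positive
  deflection ("after-hyperpolarization") lasting > 200 ms on all channels;
* isolated hippocampal / cortical spikes — brief (< 100 ms) negative-going
  single spikes with no contralateral partner within +-100 ms;
* spike-wave discharges (SWDs, prefrontal channels) — >= 3 spike-wave
  cycles at >= 6 Hz, >= 1 s long, peak-to-peak > 2x background, episodes
  closer than 1 s merged.

Detection is vigilance-agnostic; rates are events per second of recording.
All thresholds are relative (SD or mean multiples), so detection is
invariant to rescaling the voltage trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .bands import Band
from .signal import ChannelMeta, Recording, bandpass

log = logging.getLogger(__name__)

# NEO weights energy by frequency squared, so the candidate band stops at
# 80 Hz: sub-100-ms spike transients carry their energy below ~50 Hz, while
# noise above 80 Hz would dominate psi and bury them
SPIKE_BAND = Band(5.0, 80.0, "spike detection band")
SWD_BAND = Band(1.0, 80.0, "SWD detection band")
DEFAULT_K_THRESH = 12.0
NEO_SMOOTH_MS = 8.0
REFRACTORY_MS = 30.0
GIANT_TOL_MS = 10.0
GIANT_SD = 10.0
AHP_MS = 200.0
ISOLATED_MAX_WIDTH_MS = 100.0
CONTRA_WINDOW_MS = 100.0
SWD_MIN_CYCLES = 3
SWD_MIN_RATE_HZ = 6.0
SWD_MIN_DURATION_S = 1.0
SWD_MIN_P2P_RATIO = 2.0
SWD_MERGE_GAP_S = 1.0


class EventType(str, Enum):
    candidate = "candidate"
    isolated_hc = "isolated_hc"
    isolated_ctx = "isolated_ctx"
    giant = "giant"              # one representative event per giant spike
    giant_member = "giant_member"  # the same giant seen on the other channels
    swd_member = "swd_member"
    discarded = "discarded"


@dataclass
class SpikeEvent:
    time_s: float
    channel: str
    polarity: str  # "negative" | "positive"
    width_ms: float
    amplitude_sd: float  # signed, in robust-SD units of the filtered baseline
    type: EventType = EventType.candidate


@dataclass
class SWDEpisode:
    start_s: float
    end_s: float
    n_cycles: int
    rate_hz: float
    peak_to_peak_ratio: float
    channel: str = ""

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EventCatalog:
    events: list[SpikeEvent]
    episodes: list[SWDEpisode]
    recording_duration_s: float

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e.time_s)

    def of_type(self, t: EventType) -> list[SpikeEvent]:
        return [e for e in self.events if e.type == t]

    def rate(self, t: EventType | str) -> float:
        return event_rate(self, t)


@dataclass
class ISIHistogram:
    bin_edges_s: np.ndarray
    counts: np.ndarray


def neo(x: np.ndarray) -> np.ndarray:
    """Nonlinear energy operator, zero-padded at both ends."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("NEO requires at least 3 samples")
    psi = np.zeros_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    return psi


def smoothed_neo(x: np.ndarray, fs: float, smooth_ms: float = NEO_SMOOTH_MS) -> np.ndarray:
    """NEO convolved with a unit-area Bartlett window (classic practice)."""
    psi = neo(x)
    w = max(3, int(round(smooth_ms * fs / 1000.0)))
    win = np.bartlett(w)
    win /= win.sum()
    return np.convolve(psi, win, mode="same")


def robust_sd(x: np.ndarray) -> float:
    """1.4826 * median absolute deviation."""
    x = np.asarray(x, dtype=float)
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _measure_candidate(
    filt: np.ndarray, fs: float, peak_idx: int, sd: float
) -> tuple[str, float, float]:
    """Polarity, width (FWHM of |x|, ms) and signed amplitude (SD units)."""
    # locate the extreme of the filtered trace near the energy peak
    half_win = int(round(0.05 * fs))
    lo = max(0, peak_idx - half_win)
    hi = min(filt.size, peak_idx + half_win + 1)
    seg = filt[lo:hi]
    k = lo + int(np.argmax(np.abs(seg)))
    amp = filt[k]
    polarity = "negative" if amp < 0 else "positive"
    half = abs(amp) / 2.0
    left = k
    while left > 0 and abs(filt[left - 1]) > half and np.sign(filt[left - 1]) == np.sign(amp):
        left -= 1
    right = k
    while right < filt.size - 1 and abs(filt[right + 1]) > half and np.sign(filt[right + 1]) == np.sign(amp):
        right += 1
    width_ms = (right - left + 1) / fs * 1000.0
    return polarity, width_ms, amp / sd if sd > 0 else np.inf


def neo_detect(
    x: np.ndarray,
    fs: float,
    k_thresh: float = DEFAULT_K_THRESH,
    band: Band = SPIKE_BAND,
    channel: str = "",
    refractory_ms: float = REFRACTORY_MS,
) -> list[SpikeEvent]:
    """NEO candidate spikes on one channel.

    Threshold = ``k_thresh`` x mean(smoothed psi) of the band-passed trace;
    supra-threshold runs closer than ``refractory_ms`` merge into one
    candidate timed at the energy peak.  Amplitude is reported in units of
    a robust baseline SD computed with candidate windows excised.
    """
    x = np.asarray(x, dtype=float)
    if not np.any(x):
        return []
    eff_band = band
    if band.hi >= fs / 2:
        eff_band = Band(band.lo, 0.95 * fs / 2, band.label)
    filt = bandpass(x, fs, eff_band)
    psi = smoothed_neo(filt, fs)
    thresh = k_thresh * float(psi.mean())
    above = psi > thresh
    if not above.any():
        return []
    # group supra-threshold samples into runs, merging across short gaps
    idx = np.flatnonzero(above)
    gap = int(round(refractory_ms * fs / 1000.0))
    breaks = np.flatnonzero(np.diff(idx) > gap)
    run_bounds = zip(np.r_[0, breaks + 1], np.r_[breaks, idx.size - 1])
    peaks = []
    for a, b in run_bounds:
        lo, hi = idx[a], idx[b] + 1
        peaks.append(lo + int(np.argmax(psi[lo:hi])))
    # baseline SD excluding +-50 ms around each candidate
    mask = np.ones(filt.size, dtype=bool)
    guard = int(round(0.05 * fs))
    for p in peaks:
        mask[max(0, p - guard) : p + guard] = False
    sd = robust_sd(filt[mask]) if mask.any() else robust_sd(filt)
    events = []
    for p in peaks:
        polarity, width_ms, amp_sd = _measure_candidate(filt, fs, p, sd)
        events.append(SpikeEvent(p / fs, channel, polarity, width_ms, amp_sd))
    return events


def _background_p2p(filt: np.ndarray, fs: float, t_s: float, event_mask: np.ndarray) -> float:
    """Median peak-to-peak of 1-s windows in the surrounding 60 s,
    excluding samples flagged as detected events."""
    half = int(round(30.0 * fs))
    c = int(round(t_s * fs))
    lo = max(0, c - half)
    hi = min(filt.size, c + half)
    win = int(round(fs))
    p2ps = []
    for s in range(lo, hi - win + 1, win):
        if event_mask[s : s + win].any():
            continue
        seg = filt[s : s + win]
        p2ps.append(float(np.ptp(seg)))
    if not p2ps:
        return float(np.ptp(filt)) or 1.0
    return float(np.median(p2ps))


def detect_swd(
    x: np.ndarray,
    fs: float,
    k_thresh: float = DEFAULT_K_THRESH,
    channel: str = "",
) -> list[SWDEpisode]:
    """Spike-wave discharge episodes on a prefrontal channel."""
    filt = bandpass(np.asarray(x, dtype=float), fs, SWD_BAND) if np.any(x) else np.zeros_like(x)
    cands = neo_detect(x, fs, k_thresh=k_thresh, band=SWD_BAND, channel=channel)
    if not cands:
        return []
    times = np.array([c.time_s for c in cands])
    max_gap = 1.0 / SWD_MIN_RATE_HZ
    runs: list[list[float]] = [[times[0]]]
    for t in times[1:]:
        if t - runs[-1][-1] <= max_gap:
            runs[-1].append(t)
        else:
            runs.append([t])
    event_mask = np.zeros(filt.size, dtype=bool)
    guard = int(round(0.1 * fs))
    for t in times:
        c = int(round(t * fs))
        event_mask[max(0, c - guard) : c + guard] = True
    episodes = []
    for run in runs:
        n = len(run)
        if n < 2:
            continue
        span = run[-1] - run[0]
        rate_est = (n - 1) / span if span > 0 else np.inf
        half_period = 0.5 / rate_est if np.isfinite(rate_est) else 0.0
        start, end = run[0] - half_period, run[-1] + half_period
        lo = max(0, int(round(start * fs)))
        hi = min(filt.size, int(round(end * fs)))
        p2p = float(np.ptp(filt[lo:hi]))
        bg = _background_p2p(filt, fs, (start + end) / 2, event_mask)
        episodes.append(
            SWDEpisode(start, end, n, n / (end - start), p2p / bg if bg > 0 else np.inf, channel)
        )
    # merge episodes separated by < 1 s
    episodes.sort(key=lambda e: e.start_s)
    merged: list[SWDEpisode] = []
    for ep in episodes:
        if merged and ep.start_s - merged[-1].end_s < SWD_MERGE_GAP_S:
            prev = merged[-1]
            n = prev.n_cycles + ep.n_cycles
            start, end = prev.start_s, ep.end_s
            merged[-1] = SWDEpisode(
                start, end, n, n / (end - start),
                max(prev.peak_to_peak_ratio, ep.peak_to_peak_ratio), channel,
            )
        else:
            merged.append(ep)
    return [
        ep
        for ep in merged
        if ep.n_cycles >= SWD_MIN_CYCLES
        and ep.rate_hz >= SWD_MIN_RATE_HZ
        and ep.duration_s >= SWD_MIN_DURATION_S
        and ep.peak_to_peak_ratio > SWD_MIN_P2P_RATIO
    ]


def classify_giant(
    candidates: dict[str, list[SpikeEvent]],
    recording: Recording,
    tol_ms: float = GIANT_TOL_MS,
) -> list[SpikeEvent]:
    """Giant spikes: simultaneous on all channels, > 10 SD on >= 1 HC
    channel, positive mean over (t, t + 200 ms] on all channels."""
    hc_names = [c.name for c in recording.channels if c.region == "HC"]
    if len(recording.channels) < 2 or not hc_names:
        return []
    tol = tol_ms / 1000.0
    names = recording.channel_names
    giants: list[SpikeEvent] = []
    seeds = sorted((e for n in hc_names for e in candidates.get(n, [])), key=lambda e: e.time_s)
    fs = recording.fs
    n_ahp = int(round(AHP_MS / 1000.0 * fs))
    claimed: set[tuple[str, float]] = set()
    for seed in seeds:
        if (seed.channel, seed.time_s) in claimed:
            continue
        group = {}
        for name in names:
            match = next(
                (e for e in candidates.get(name, []) if abs(e.time_s - seed.time_s) <= tol),
                None,
            )
            if match is None:
                break
            group[name] = match
        if len(group) != len(names):
            continue
        if not any(abs(group[n].amplitude_sd) > GIANT_SD for n in hc_names):
            continue
        # after-hyperpolarization: positive mean over (t, t+200 ms] on the
        # raw trace relative to the preceding 1-s baseline level
        k0 = int(round(seed.time_s * fs)) + int(round(0.03 * fs))
        n_base = int(round(fs))
        ok = True
        for name in names:
            raw = recording.get(name)
            if k0 + 1 + n_ahp > raw.size:
                ok = False
                break
            base = np.median(raw[max(0, k0 - n_base) : max(1, k0 - int(0.05 * fs))])
            if np.mean(raw[k0 + 1 : k0 + 1 + n_ahp]) - base <= 0:
                ok = False
                break
        if not ok:
            continue
        rep = max(group.values(), key=lambda e: abs(e.amplitude_sd))
        for n, e in group.items():
            claimed.add((n, e.time_s))
            e.type = EventType.giant if e is rep else EventType.giant_member
        giants.append(rep)
    return giants


def classify_isolated(
    candidates: dict[str, list[SpikeEvent]],
    channel_meta: dict[str, ChannelMeta],
) -> list[SpikeEvent]:
    """Isolated HC/cortical spikes among the remaining candidates.

    A candidate qualifies when it is brief (< 100 ms), negative-going, and
    has no candidate on a contralateral channel of the same region within
    +-100 ms.  Without a contralateral channel the pairing rule passes
    vacuously (logged caveat).
    """
    out: list[SpikeEvent] = []
    window = CONTRA_WINDOW_MS / 1000.0
    for name, evs in candidates.items():
        meta = channel_meta.get(name)
        if meta is None or meta.region == "PFC":
            continue
        target = EventType.isolated_hc if meta.region == "HC" else EventType.isolated_ctx
        contra = [
            n for n, m in channel_meta.items()
            if m.region == meta.region and n != name
            and m.hemisphere != meta.hemisphere
            and "unknown" not in (m.hemisphere, meta.hemisphere)
        ]
        if not contra:
            log.warning("no contralateral %s channel for %s: pairing rule passes vacuously",
                        meta.region, name)
        contra_times = np.sort(np.array(
            [e.time_s for n in contra for e in candidates.get(n, [])]
        ))
        for e in evs:
            if e.type is not EventType.candidate:
                continue
            if e.polarity != "negative" or e.width_ms >= ISOLATED_MAX_WIDTH_MS:
                continue
            if contra_times.size:
                j = np.searchsorted(contra_times, e.time_s)
                near = []
                if j > 0:
                    near.append(contra_times[j - 1])
                if j < contra_times.size:
                    near.append(contra_times[j])
                if any(abs(t - e.time_s) <= window for t in near):
                    continue
            e.type = target
            out.append(e)
    return out


def build_catalog(
    recording: Recording,
    k_thresh: float = DEFAULT_K_THRESH,
) -> EventCatalog:
    """Full detection pass over one recording (all vigilance states).

    PFC channels contribute SWD episodes; PTC and HC channels contribute
    NEO candidates which are classified into giant and isolated spikes.
    Unclassified candidates are kept as ``discarded`` so the type partition
    is complete.
    """
    meta = {c.name: c for c in recording.channels}
    candidates: dict[str, list[SpikeEvent]] = {}
    for c in recording.channels:
        # PFC candidates participate only in the giant-spike simultaneity
        # check; isolated-spike classification is limited to PTC/HC
        candidates[c.name] = neo_detect(
            recording.get(c.name), recording.fs, k_thresh=k_thresh, channel=c.name
        )
    classify_giant(candidates, recording)   # relabels members in place
    classify_isolated(candidates, meta)
    episodes: list[SWDEpisode] = []
    for c in recording.channels:
        if c.region == "PFC":
            episodes.extend(
                detect_swd(recording.get(c.name), recording.fs, k_thresh=k_thresh, channel=c.name)
            )
    all_events: list[SpikeEvent] = []
    for evs in candidates.values():
        for e in evs:
            if e.type is EventType.candidate:
                e.type = EventType.discarded
            all_events.append(e)
    return EventCatalog(all_events, episodes, recording.duration_s)


def event_rate(catalog: EventCatalog, event_type: EventType | str) -> float:
    """Events of ``event_type`` per second of recording."""
    if catalog.recording_duration_s <= 0:
        raise ValueError("recording duration must be positive")
    t = EventType(event_type)
    if t is EventType.swd_member:
        n = len(catalog.episodes)
    else:
        n = sum(1 for e in catalog.events if e.type is t)
    return n / catalog.recording_duration_s


def isi_histogram(
    times_s: np.ndarray,
    n_bins: int = 24,
    range_s: tuple[float, float] = (0.05, 200.0),
) -> ISIHistogram:
    """Log-binned inter-spike-interval histogram.

    Intervals outside ``range_s`` are clamped into the end bins (logged),
    so the counts always sum to ``n_events - 1``.
    """
    times_s = np.sort(np.asarray(times_s, dtype=float))
    edges = np.geomspace(range_s[0], range_s[1], n_bins + 1)
    if times_s.size < 2:
        return ISIHistogram(edges, np.zeros(n_bins, dtype=int))
    isis = np.diff(times_s)
    n_out = int(np.sum((isis < range_s[0]) | (isis > range_s[1])))
    if n_out:
        log.info("%d ISIs outside %s clamped to end bins", n_out, range_s)
    idx = np.clip(np.searchsorted(edges, isis, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return ISIHistogram(edges, counts)
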