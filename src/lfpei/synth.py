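"""Synthetic LFP with known ground truth.

Every analysis stage in this package can be validated against signals whose
statistical structure is known exactly:

* fractional Gaussian noise (fGn) with prescribed Hurst exponent H via the
  Davies-Harte circulant embedding — the substrate for envelopes with a
  known DFA exponent;
* narrowband oscillations whose amplitude envelope is a geometric
  (exponentiated) transform of fGn, so the envelope stays positive and its
  long-range temporal correlations survive;
* theta-phase-modulated gamma with a closed-form modulation depth chi;
* parameterized epileptiform templates (biphasic spikes, spike-wave cycles,
  giant spikes with after-hyperpolarization) injected at known times;
* nested longitudinal cohorts (genotype -> mouse -> channel -> week) with
  genotype-by-age effects on envelope criticality, coupling depth,
  excitation bias and spike rate.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .bands import Band
from .events import EventCatalog, EventType, SpikeEvent, SWDEpisode, robust_sd
from .signal import (
    EPOCH_S,
    ChannelMeta,
    Recording,
    VigilanceTrack,
    bandpass,
)

DEFAULT_FS = 1000.0


# ---------------------------------------------------------------------------
# fractional Gaussian noise
# ---------------------------------------------------------------------------

def fgn_autocov(H: float, lags: np.ndarray) -> np.ndarray:
    """Analytic autocovariance of unit-variance fGn at integer lags."""
    k = np.abs(np.asarray(lags, dtype=float))
    return 0.5 * (np.abs(k - 1) ** (2 * H) - 2 * k ** (2 * H) + (k + 1) ** (2 * H))


def gen_fgn(H: float, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Exact fGn sample path by Davies-Harte circulant embedding.

    Returns a zero-mean unit-variance Gaussian series whose autocovariance
    is that of fGn with Hurst exponent ``H``.  Raises if the circulant
    embedding is not positive semi-definite (can occur for extreme H with
    small n).
    """
    if not (0 < H < 1):
        raise ValueError("H must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = 2 * n
    r = fgn_autocov(H, np.arange(n + 1))
    c = np.concatenate([r, r[-2:0:-1]])  # circulant first row, length 2n
    lam = np.fft.fft(c).real
    if lam.min() < -1e-8 * lam.max():
        raise ValueError(f"circulant embedding not PSD for H={H}, n={n}")
    lam = np.clip(lam, 0.0, None)
    # Hermitian-symmetric spectral amplitudes from 2n real normals
    z1 = rng.standard_normal(n + 1)
    z2 = rng.standard_normal(n - 1)
    w = np.empty(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * z1[0]
    w[n] = np.sqrt(lam[n] / m) * z1[n]
    k = np.arange(1, n)
    amp = np.sqrt(lam[k] / (2 * m))
    w[k] = amp * (z1[k] + 1j * z2)
    w[m - k] = np.conj(w[k])
    x = np.fft.fft(w).real[:n]
    return x


# ---------------------------------------------------------------------------
# LRTC oscillation
# ---------------------------------------------------------------------------

@dataclass
class SynthSpec:
    """Parameters of one synthetic narrowband LRTC oscillation."""

    duration_s: float = 200.0
    fs: float = DEFAULT_FS
    carrier_band: Band = field(default_factory=lambda: Band(35.0, 45.0))
    envelope_H: float = 0.8
    envelope_depth: float = 0.3     # log-envelope SD (geometric envelope)
    envelope_fs: float = 20.0       # rate of the slow envelope process, Hz
    excitation_bias: float = 0.0    # couples amplitude to fluctuation; >0 -> fE/I > 1
    fast_frac: float = 0.12         # fast (1-8 Hz) envelope fluctuation fraction
    amplitude: float = 10.0         # carrier scale, µV
    noise_sd: float = 0.0           # additive white noise, µV
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.envelope_H < 1):
            raise ValueError("envelope_H must be in (0, 1)")
        if self.carrier_band.hi >= self.fs / 2:
            raise ValueError("carrier band must lie below Nyquist")


def _fast_fluctuation(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited (1-8 Hz) noise for short-scale envelope
    fluctuations."""
    w = rng.standard_normal(n)
    f = bandpass(w, fs, Band(1.0, min(8.0, 0.45 * fs)))
    sd = f.std()
    return f / sd if sd > 0 else f


def slow_fgn_process(H: float, duration_s: float, fs: float, slow_fs: float,
                     rng: np.random.Generator,
                     excitation_bias: float = 0.0) -> np.ndarray:
    """fGn(H) generated at ``slow_fs`` and linearly interpolated to ``fs``.

    Neural amplitude-envelope fluctuations live below ~10 Hz; generating
    the process at a low rate puts all its variance below the narrowband
    filter's half-bandwidth, so the prescribed scaling survives the
    analysis path (fGn at the full rate is nearly white and would be
    destroyed by band filtering).

    A nonzero ``excitation_bias`` splits z into a very-slow level component
    (~10 s moving average) and a mid-frequency remainder and scales the
    remainder by exp(-bias * level / sd(level)): stretches of high level
    then carry relatively less fluctuation (bias > 0) or more (bias < 0).
    """
    n = int(round(duration_s * fs))
    n_slow = max(8, int(round(duration_s * slow_fs)) + 1)
    z = gen_fgn(H, n_slow, rng)
    if excitation_bias != 0.0:
        w = min(n_slow, max(3, int(round(10.0 * slow_fs)) | 1))
        kernel = np.ones(w) / w
        z_level = np.convolve(z, kernel, mode="same")
        z_mid = z - z_level
        sd = z_level.std() or 1.0
        z = z_level + np.exp(-excitation_bias * z_level / sd) * z_mid
    t_slow = np.arange(n_slow) / slow_fs
    t = np.arange(n) / fs
    return np.interp(t, t_slow, z)


def gen_lrtc_envelope(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Positive envelope with DFA exponent ~ envelope_H.

    The envelope is exp(c * z) with z an fGn(H) process — exponentiation
    keeps it positive without the clipping that would destroy LRTC.

    The optional excitation bias splits z into a very-slow level component
    (moving average over ~10 s, which sets the windowed amplitude) and a
    mid-frequency fluctuation component, and scales the latter by
    exp(-bias * level / sd): with positive bias, high-amplitude stretches
    carry relatively *less* amplitude-normalized fluctuation, producing the
    negative amplitude-vs-nF correlation that reads out as fE/I > 1.
    With bias = 0 the envelope is the plain geometric fGn envelope.
    """
    n = int(round(spec.duration_s * spec.fs))
    z = slow_fgn_process(spec.envelope_H, spec.duration_s, spec.fs, spec.envelope_fs,
                         rng, excitation_bias=spec.excitation_bias)
    m = np.exp(spec.envelope_depth * z)
    fast = _fast_fluctuation(n, spec.fs, rng)
    env = m * np.clip(1.0 + spec.fast_frac * fast, 0.05, None)
    return env


def gen_lrtc_oscillation(spec: SynthSpec, rng: np.random.Generator | None = None
                         ) -> tuple[np.ndarray, dict]:
    """Carrier at the band center multiplied by the LRTC envelope, plus
    optional white noise.  Returns (signal, ground truth dict)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    env = gen_lrtc_envelope(spec, rng)
    f0 = spec.carrier_band.center
    t = np.arange(n) / spec.fs
    phi0 = rng.uniform(0, 2 * np.pi)
    x = spec.amplitude * env * np.sin(2 * np.pi * f0 * t + phi0)
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * rng.standard_normal(n)
    truth = {
        "true_H": spec.envelope_H,
        "excitation_bias": spec.excitation_bias,
        "envelope": spec.amplitude * env,
        "carrier_hz": f0,
    }
    return x, truth


# ---------------------------------------------------------------------------
# phase-amplitude coupled signal
# ---------------------------------------------------------------------------

def pac_modulator(phase: np.ndarray, chi: float) -> np.ndarray:
    """Amplitude factor a(phi) = 1 - chi + chi * (1 + cos phi) / 2.

    chi = 0 gives a constant (no coupling); chi = 1 gives full-depth
    modulation with zero amplitude at phase pi.
    """
    return 1.0 - chi + chi * (1.0 + np.cos(phase)) / 2.0


def gen_pac_signal(
    f_phase: float,
    f_amp: float,
    chi: float,
    duration_s: float,
    fs: float = DEFAULT_FS,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    amp_phase: float = 1.0,
    amp_fast: float = 1.0,
) -> tuple[np.ndarray, dict]:
    """Slow oscillation plus a fast oscillation whose amplitude follows the
    slow phase with depth ``chi``; returns (signal, ground truth)."""
    if not (0 <= chi <= 1):
        raise ValueError("chi must be in [0, 1]")
    if not (0 < f_phase < f_amp < fs / 2):
        raise ValueError("require 0 < f_phase < f_amp < fs/2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase = 2 * np.pi * f_phase * t
    a = pac_modulator(phase, chi)
    x = amp_phase * np.sin(phase) + amp_fast * a * np.sin(2 * np.pi * f_amp * t)
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
    wrapped = np.angle(np.exp(1j * phase))
    return x, {"true_chi": chi, "phase": wrapped, "modulator": a * amp_fast}


# ---------------------------------------------------------------------------
# epileptiform event templates and injection
# ---------------------------------------------------------------------------

def spike_template(fs: float, sigma_ms: float = 5.0, rebound: float = 0.3) -> np.ndarray:
    """Biphasic negative transient: dominant negative Gaussian lobe with a
    smaller, broader positive rebound — unit negative-peak amplitude.

    The main lobe's FWHM is ~2.4 sigma, well under 100 ms at the default."""
    sigma = sigma_ms / 1000.0
    tt = np.arange(-3 * sigma, 8 * sigma, 1 / fs)
    f = -np.exp(-(tt**2) / (2 * sigma**2))
    f += rebound * np.exp(-((tt - 3.5 * sigma) ** 2) / (2 * (2 * sigma) ** 2))
    return f


def swd_template(fs: float, rate_hz: float, n_cycles: int) -> np.ndarray:
    """Spike-wave train: each cycle a sharp negative spike followed by a
    slower positive wave; unit negative-spike amplitude."""
    period = 1.0 / rate_hz
    cyc_n = int(round(period * fs))
    tt = np.arange(cyc_n) / fs
    spike = -np.exp(-((tt - 0.15 * period) ** 2) / (2 * (0.04 * period) ** 2))
    wave_mask = (tt > 0.3 * period)
    wave = np.zeros_like(tt)
    wave[wave_mask] = 0.5 * np.sin(np.pi * (tt[wave_mask] - 0.3 * period) / (0.7 * period))
    cycle = spike + wave
    return np.tile(cycle, n_cycles)


def giant_template(fs: float, spike_sigma_ms: float = 6.0, ahp_s: float = 0.3,
                   ahp_amp: float = 0.5) -> np.ndarray:
    """Large negative spike followed by a positive deflection lasting
    ``ahp_s`` seconds (the 'after-hyperpolarization'); unit spike amplitude."""
    spike = spike_template(fs, spike_sigma_ms, rebound=0.0)
    n_ahp = int(round(ahp_s * fs))
    ahp = ahp_amp * np.sin(np.pi * np.arange(n_ahp) / n_ahp)
    return np.concatenate([spike, ahp])


@dataclass
class IsolatedSpikeSpec:
    channel: str
    times_s: list[float]
    amplitude_sd: float = 10.0
    sigma_ms: float = 5.0


@dataclass
class SWDSpec:
    channel: str
    start_s: float
    rate_hz: float = 7.0
    n_cycles: int = 8
    p2p_factor: float = 3.0  # vs background peak-to-peak


@dataclass
class GiantSpikeSpec:
    times_s: list[float]
    hc_amplitude_sd: float = 12.0
    other_amplitude_sd: float = 10.5


class PlacementError(ValueError):
    """Event template does not fit inside the recording."""


def _detection_band_peak(template: np.ndarray, fs: float, band: Band) -> float:
    """|negative peak| of the template after the detection band-pass.

    Calibrating against this (rather than the raw template peak) makes a
    requested amplitude exact in the units the classifier thresholds:
    the band's high-pass eats a broad transient's DC content, so the raw
    peak would systematically overstate the measured amplitude.
    """
    taps = int(np.ceil(3 * fs / band.lo)) + 1
    pad = np.zeros(4 * taps)
    center = len(pad) // 2
    start = center - int(np.argmin(template))
    pad[start : start + len(template)] += template
    filt = bandpass(pad, fs, band)
    return float(np.abs(filt).max())


def _add(x: np.ndarray, template: np.ndarray, t_s: float, fs: float,
         align: str = "center") -> None:
    """Add ``template`` with its center ("center") or its most negative
    sample ("peak") at time ``t_s``."""
    anchor = len(template) // 2 if align == "center" else int(np.argmin(template))
    i0 = int(round(t_s * fs)) - anchor
    if i0 < 0 or i0 + len(template) > x.size:
        raise PlacementError(f"template at t={t_s:.2f}s exceeds recording bounds")
    x[i0 : i0 + len(template)] += template


def inject_events(
    recording: Recording,
    isolated: list[IsolatedSpikeSpec] = (),
    swds: list[SWDSpec] = (),
    giants: GiantSpikeSpec | None = None,
) -> EventCatalog:
    """Insert event templates into ``recording`` (in place) and return the
    exact ground-truth catalog.

    Amplitudes are calibrated against the *pre-injection* trace: isolated
    and giant spikes in robust-SD units of the 5-200 Hz filtered baseline,
    SWD trains against the median 1-s peak-to-peak of the 1-80 Hz trace.
    """
    from .events import SPIKE_BAND  # calibrate in the band detection measures in

    fs = recording.fs
    base_sd = {}
    base_p2p = {}
    for c in recording.channels:
        x = recording.get(c.name)
        hi = min(SPIKE_BAND.hi, 0.95 * fs / 2)
        filt = bandpass(x, fs, Band(SPIKE_BAND.lo, hi))
        base_sd[c.name] = robust_sd(filt) or 1.0
        low = bandpass(x, fs, Band(1.0, min(80.0, 0.9 * fs / 2)))
        win = int(fs)
        p2ps = [np.ptp(low[i : i + win]) for i in range(0, low.size - win + 1, win)]
        base_p2p[c.name] = float(np.median(p2ps)) if p2ps else 1.0

    events: list[SpikeEvent] = []
    episodes: list[SWDEpisode] = []
    det_band = Band(SPIKE_BAND.lo, min(SPIKE_BAND.hi, 0.95 * fs / 2))
    for spec in isolated:
        ch = spec.channel
        tmpl = spike_template(fs, spec.sigma_ms)
        tmpl = tmpl * (spec.amplitude_sd * base_sd[ch] / _detection_band_peak(tmpl, fs, det_band))
        x = recording.data[recording.channel_index(ch)]
        for t in spec.times_s:
            _add(x, tmpl, t, fs, align="peak")
            meta = recording.channels[recording.channel_index(ch)]
            etype = EventType.isolated_hc if meta.region == "HC" else EventType.isolated_ctx
            events.append(SpikeEvent(t, ch, "negative", 4 * spec.sigma_ms, -spec.amplitude_sd, etype))
    for spec in swds:
        ch = spec.channel
        tmpl = swd_template(fs, spec.rate_hz, spec.n_cycles)
        # scale so train peak-to-peak = p2p_factor x background
        tmpl = tmpl * (spec.p2p_factor * base_p2p[ch] / np.ptp(tmpl))
        x = recording.data[recording.channel_index(ch)]
        dur = spec.n_cycles / spec.rate_hz
        _add(x, tmpl, spec.start_s + dur / 2, fs)
        episodes.append(SWDEpisode(spec.start_s, spec.start_s + dur, spec.n_cycles,
                                   spec.rate_hz, spec.p2p_factor, ch))
    if giants is not None:
        hc = [c.name for c in recording.channels if c.region == "HC"]
        for t in giants.times_s:
            for c in recording.channels:
                amp = giants.hc_amplitude_sd if c.name in hc[:1] else giants.other_amplitude_sd
                tmpl = giant_template(fs)
                tmpl = tmpl * (amp * base_sd[c.name] / _detection_band_peak(tmpl, fs, det_band))
                _add(recording.data[recording.channel_index(c.name)], tmpl, t, fs,
                     align="peak")
            events.append(SpikeEvent(t, hc[0] if hc else recording.channels[0].name,
                                     "negative", 48.0, -giants.hc_amplitude_sd, EventType.giant))
    return EventCatalog(events, episodes, recording.duration_s)


# ---------------------------------------------------------------------------
# longitudinal cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortEffect:
    """Genotype-by-age shifts applied on top of the cohort baselines."""

    h_shift: float = 0.0
    chi_shift: float = 0.0
    spike_rate: float = 0.0       # isolated HC spikes, Hz
    fei_bias: float = 0.0         # excitation bias of the low-gamma envelope


def app_like_effects(
    months: tuple[int, ...],
    onset_month: int = 6,
    h_shift: float = 0.08,
    chi_deficit: float = -0.3,
    spike_rate: float = 0.05,
    fei_bias: float = 0.3,
    baseline_spike_rate: float = 0.01,
) -> dict[tuple[str, int], CohortEffect]:
    """Default planted effects: WT flat; APP-like genotype develops a
    criticality shift, a theta-gamma coupling deficit, an excitation bias
    and elevated spiking from ``onset_month`` on."""
    eff = {}
    for m in months:
        eff[("WT", m)] = CohortEffect()
        if m >= onset_month:
            eff[("APP", m)] = CohortEffect(h_shift, chi_deficit, spike_rate, fei_bias)
        else:
            eff[("APP", m)] = CohortEffect(0.0, 0.0, baseline_spike_rate, 0.0)
    return eff


def null_effects(months: tuple[int, ...],
                 spike_rate: float = 0.02) -> dict[tuple[str, int], CohortEffect]:
    """Zero genotype effects (for type-I-error calibration); both genotypes
    share the same nonzero spike rate so rate-gated joins stay populated."""
    return {
        (g, m): CohortEffect(0.0, 0.0, spike_rate, 0.0)
        for g in ("WT", "APP")
        for m in months
    }


DEFAULT_CHANNELS = (
    ChannelMeta("PFC1", "PFC", None, "left"),
    ChannelMeta("PTC_L", "PTC", None, "left"),
    ChannelMeta("PTC_R", "PTC", None, "right"),
    ChannelMeta("HC_L", "HC", "pyramidal", "left"),
    ChannelMeta("HC_R", "HC", "pyramidal", "right"),
)


@dataclass
class RecordingTruth:
    true_H: float
    true_chi: float
    excitation_bias: float
    spike_rate: float
    spike_times: dict[str, list[float]]
    states: list[str]


@dataclass
class Cohort:
    manifest: pd.DataFrame
    recordings: dict[tuple[str, int], Recording]        # (subject, age_week)
    annotations: dict[tuple[str, int], VigilanceTrack]
    truth: dict[tuple[str, int], RecordingTruth]
    effects: dict[tuple[str, int], CohortEffect]
    seed: int


def _non_state_intervals(states: list[str], state: str,
                         epoch_s: float = EPOCH_S) -> list[tuple[float, float]]:
    """Merged (start_s, end_s) intervals of epochs NOT labelled ``state``."""
    out = []
    start = None
    for i, lab in enumerate(states):
        if lab != state and start is None:
            start = i
        elif lab == state and start is not None:
            out.append((start * epoch_s, i * epoch_s))
            start = None
    if start is not None:
        out.append((start * epoch_s, len(states) * epoch_s))
    return out


def _uniform_in_intervals(intervals: list[tuple[float, float]], n: int,
                          rng: np.random.Generator) -> np.ndarray:
    if not intervals or n == 0:
        return np.empty(0)
    lengths = np.array([e - s for s, e in intervals])
    starts = np.array([s for s, _ in intervals])
    total = lengths.sum()
    u = rng.uniform(0, total, n)
    idx = np.searchsorted(np.cumsum(lengths), u, side="right")
    offset = u - np.concatenate([[0.0], np.cumsum(lengths)])[idx]
    return starts[idx] + offset


def _state_sequence(n_epochs: int, rng: np.random.Generator) -> list[str]:
    """Block-structured state sequence: alternating wake/sleep bouts with
    geometric block lengths (means: quiet 13, active 9, sleep 6 epochs)."""
    mean_len = {"quiet_wake": 13, "active_wake": 9, "sleep": 6}
    order = ["quiet_wake", "active_wake", "quiet_wake", "sleep"]
    labels: list[str] = []
    i = 0
    while len(labels) < n_epochs:
        st = order[i % len(order)]
        ln = 1 + rng.geometric(1.0 / mean_len[st])
        labels.extend([st] * ln)
        i += 1
    return labels[:n_epochs]


def _channel_signal(
    n: int,
    fs: float,
    rng: np.random.Generator,
    H: float,
    chi: float,
    bias: float,
    sleep_mask: np.ndarray,
    carrier_band: Band,
) -> np.ndarray:
    """One channel: LRTC low-gamma + theta-gamma PAC + sleep delta +
    broadband LRTC background noise (all in µV)."""
    duration_s = n / fs
    spec = SynthSpec(duration_s, fs, carrier_band, envelope_H=H,
                     excitation_bias=bias, amplitude=10.0, noise_sd=0.0,
                     seed=0)
    lrtc, _ = gen_lrtc_oscillation(spec, rng)
    pac, _ = gen_pac_signal(7.0, 60.0, chi, duration_s, fs, noise_sd=0.0,
                            seed=rng, amp_phase=30.0, amp_fast=8.0)
    t = np.arange(n) / fs
    delta = 40.0 * np.sin(2 * np.pi * 2.5 * t + rng.uniform(0, 2 * np.pi)) * sleep_mask
    # broadband noise with symmetric LRTC envelope: every band keeps beta>0.6
    # and a near-balanced fE/I, so non-carrier bands stay analysable
    bg_env = np.exp(0.25 * slow_fgn_process(0.7, duration_s, fs, 20.0, rng))
    noise = 4.0 * bg_env * rng.standard_normal(n)
    return lrtc + pac + delta + noise


def gen_cohort(
    n_per_genotype: int = 3,
    months: tuple[int, ...] = (5, 6),
    fs: float = 500.0,
    duration_s: float = 400.0,
    channels: tuple[ChannelMeta, ...] = DEFAULT_CHANNELS,
    effects: dict[tuple[str, int], CohortEffect] | None = None,
    seed: int = 0,
    base_H: float = 0.75,
    base_chi: float = 0.5,
    carrier_band: Band | None = None,
    weeks_per_month: int = 4,
    spike_channel_region: str = "HC",
) -> Cohort:
    """Nested longitudinal cohort: genotype -> mouse -> (month, week) ->
    multichannel recording with vigilance structure and injected spikes.

    Mouse- and channel-level random offsets are applied to H and chi;
    genotype-by-month effects come from ``effects``.  Per-mouse/per-week
    random streams are derived from the master seed with fixed offsets, so
    the whole cohort is reproducible.
    """
    if effects is None:
        effects = app_like_effects(months)
    for g in ("WT", "APP"):
        for m in months:
            if (g, m) not in effects:
                raise ValueError(f"effects missing for {(g, m)}")
    if carrier_band is None:
        carrier_band = Band(35.0, 45.0)
    n = int(round(duration_s * fs))
    n_epochs = int(duration_s // EPOCH_S)
    rows = []
    recordings: dict[tuple[str, int], Recording] = {}
    annotations: dict[tuple[str, int], VigilanceTrack] = {}
    truths: dict[tuple[str, int], RecordingTruth] = {}
    spike_channels = [c.name for c in channels if c.region == spike_channel_region]
    spike_channel = spike_channels[0] if spike_channels else channels[0].name

    for gi, genotype in enumerate(("WT", "APP")):
        for mi in range(n_per_genotype):
            subject = f"{genotype}{mi + 1:02d}"
            mouse_rng = np.random.default_rng(
                np.random.SeedSequence([seed, 101, gi, mi])
            )
            h_mouse = mouse_rng.normal(0, 0.02)
            chi_mouse = mouse_rng.normal(0, 0.03)
            ch_off = {
                c.name: (mouse_rng.normal(0, 0.01), mouse_rng.normal(0, 0.02))
                for c in channels
            }
            for month in months:
                eff = effects[(genotype, month)]
                for wk in range(weeks_per_month):
                    age_week = month * weeks_per_month + wk
                    rng = np.random.default_rng(
                        np.random.SeedSequence([seed, 7, gi, mi, month, wk])
                    )
                    states = _state_sequence(n_epochs, rng)
                    sleep_mask = np.repeat(
                        np.array([s == "sleep" for s in states], dtype=float),
                        int(EPOCH_S * fs),
                    )
                    sleep_mask = np.pad(sleep_mask, (0, n - sleep_mask.size), mode="edge")
                    data = np.empty((len(channels), n))
                    for ci, cm in enumerate(channels):
                        H = float(np.clip(base_H + eff.h_shift + h_mouse + ch_off[cm.name][0],
                                          0.05, 0.95))
                        chi = float(np.clip(base_chi + eff.chi_shift + chi_mouse
                                            + ch_off[cm.name][1], 0.0, 1.0))
                        data[ci] = _channel_signal(
                            n, fs, rng, H, chi, eff.fei_bias, sleep_mask, carrier_band
                        )
                    rec = Recording(data, fs, list(channels), subject,
                                    age_week=age_week, age_month=month)
                    # spikes go outside quiet wake: the fE/I contract assumes
                    # its (quiet-wake) input is artifact/spike-cleaned, which
                    # the generator emulates by keeping it clean at source
                    n_spk = rng.poisson(eff.spike_rate * duration_s)
                    margin = 1.0
                    non_quiet = [
                        (max(s, margin), min(e, duration_s - margin))
                        for s, e in _non_state_intervals(states, "quiet_wake")
                    ]
                    non_quiet = [(s, e) for s, e in non_quiet if e > s]
                    times = np.sort(_uniform_in_intervals(non_quiet, n_spk, rng))
                    # enforce a minimal separation so templates stay resolvable
                    keep = []
                    last = -np.inf
                    for tsp in times:
                        if tsp - last >= 0.3:
                            keep.append(float(tsp))
                            last = tsp
                    cat = inject_events(
                        rec,
                        isolated=[IsolatedSpikeSpec(spike_channel, keep, amplitude_sd=10.0)]
                        if keep else [],
                    )
                    velocity = np.where(
                        np.array(states) == "active_wake",
                        2.0 + np.abs(rng.normal(0, 1, n_epochs)),
                        np.abs(rng.normal(0, 0.3, n_epochs)),
                    )
                    ann = VigilanceTrack(states, velocity=velocity)
                    key = (subject, age_week)
                    recordings[key] = rec
                    annotations[key] = ann
                    truths[key] = RecordingTruth(
                        true_H=base_H + eff.h_shift + h_mouse,
                        true_chi=float(np.clip(base_chi + eff.chi_shift + chi_mouse, 0, 1)),
                        excitation_bias=eff.fei_bias,
                        spike_rate=len(keep) / duration_s,
                        spike_times={spike_channel: keep},
                        states=states,
                    )
                    del cat
                    for cm in channels:
                        rows.append(dict(
                            subject_id=subject, genotype=genotype,
                            age_week=age_week, age_month=month, file="",
                            channel=cm.name, region=cm.region,
                            hc_layer=cm.hc_layer or "none",
                            hemisphere=cm.hemisphere,
                        ))
    manifest = pd.DataFrame(rows)
    return Cohort(manifest, recordings, annotations, truths, dict(effects), seed)
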