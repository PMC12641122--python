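"""Detrended fluctuation analysis (DFA-1) of amplitude envelopes.

The DFA exponent beta quantifies long-range temporal correlations of an
oscillation's amplitude envelope: beta ~ 0.5 for an uncorrelated envelope,
beta > 0.6 is taken downstream as evidence that LRTC are present (the gate
for computing fE/I).  The exponent is the slope of mean fluctuation versus
window size in log-log coordinates, fitted over 0.4-30 s by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal import Envelope

DEFAULT_FIT_RANGE_S = (0.4, 30.0)
DEFAULT_N_SIZES = 20
DEFAULT_OVERLAP = 0.5


class DFAEstimationError(ValueError):
    """Not enough usable window sizes to fit an exponent."""


@dataclass
class DFAResult:
    beta: float
    window_sizes_s: np.ndarray
    F: np.ndarray
    fit_range_s: tuple[float, float]
    fit_r2: float
    n_samples: int
    skipped_sizes_s: list[float] = field(default_factory=list)


def signal_profile(values: np.ndarray, global_mean: float | None = None) -> np.ndarray:
    """Cumulative sum of the mean-subtracted envelope.

    With the default (own-mean) centering the last profile value is ~0 by
    the telescoping identity.  ``global_mean`` lets multi-segment callers
    center every segment on the pooled mean.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("profile requires at least 2 samples")
    mu = values.mean() if global_mean is None else global_mean
    return np.cumsum(values - mu)


def profile_prefixes(profile: np.ndarray) -> tuple[np.ndarray, ...]:
    """Extended-precision prefix sums of y, y^2 and k*y for a (centred)
    profile; shared across window sizes by :func:`detrended_window_rms`."""
    # centring the whole profile keeps the prefix sums small enough that
    # the later subtractions stay accurate (the result is shift-invariant)
    y = (profile - profile.mean()).astype(np.longdouble)
    zero = np.zeros(1, dtype=np.longdouble)
    c1 = np.concatenate([zero, np.cumsum(y)])
    c2 = np.concatenate([zero, np.cumsum(y * y)])
    ck = np.concatenate([zero, np.cumsum(np.arange(y.size, dtype=np.longdouble) * y)])
    return c1, c2, ck


def detrended_window_rms(profile: np.ndarray, win: int, step: int,
                         prefixes: tuple[np.ndarray, ...] | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Residual RMS of each linearly detrended length-``win`` window.

    Computed from prefix sums of y, y^2 and k*y, so the cost is O(n) per
    window size instead of O(n * win): for a window the residual sum of
    squares after removing mean and slope is
    SS = sum(y^2) - (sum y)^2 / L - slope^2 * sum(t^2) with t centred.
    Returns (rms per window, window starts).
    """
    n = profile.size
    if n < win or win < 2:
        return np.empty(0), np.empty(0, dtype=int)
    c1, c2, ck = profile_prefixes(profile) if prefixes is None else prefixes
    starts = np.arange(0, n - win + 1, step)
    L = float(win)
    s1 = c1[starts + win] - c1[starts]
    s2 = c2[starts + win] - c2[starts]
    sk = ck[starts + win] - ck[starts]
    # sum(t*y) with t = (k - start) - (L-1)/2
    sty = sk - starts * s1 - (L - 1) / 2.0 * s1
    tt = L * (L * L - 1.0) / 12.0
    slope = sty / tt
    ss = s2 - s1 * s1 / L - slope * slope * tt
    # windows whose residual SS sits below the cancellation noise floor of
    # the prefix sums (e.g. an exactly linear profile) are recomputed by
    # explicit detrending, which cancels exactly
    noise_floor = 1e6 * np.finfo(np.longdouble).eps * float(c2[-1])
    suspect = np.flatnonzero(ss < noise_floor)
    rms = np.sqrt(np.maximum(ss, 0.0) / L).astype(float)
    if suspect.size:
        t = np.arange(win, dtype=float)
        t -= t.mean()
        tt_f = float(t @ t)
        base = profile - profile.mean()
        for i in suspect:
            a = starts[i]
            w = base[a : a + win] - base[a : a + win].mean()
            sl = float(w @ t) / tt_f
            rms[i] = np.sqrt(np.mean((w - sl * t) ** 2))
    return rms, starts


def _window_rms(profile: np.ndarray, win: int, step: int,
                prefixes=None) -> tuple[float, int]:
    """Sum of per-window detrended RMS values, plus the window count."""
    rms, starts = detrended_window_rms(profile, win, step, prefixes)
    return float(rms.sum()), len(starts)


def fluctuation_function(
    profiles: np.ndarray | list[np.ndarray],
    fs: float,
    window_sizes_s: np.ndarray | None = None,
    overlap_frac: float = DEFAULT_OVERLAP,
    fit_range_s: tuple[float, float] = DEFAULT_FIT_RANGE_S,
    n_sizes: int = DEFAULT_N_SIZES,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Mean fluctuation F(size) over log-spaced window sizes.

    ``profiles`` may be a single profile or a list of per-segment profiles
    (seam-respecting: windows are laid out within segments and fluctuations
    pooled across segments).  Sizes that fit no segment, or exceed a quarter
    of the total length, are skipped and reported.
    """
    if isinstance(profiles, np.ndarray):
        profiles = [profiles]
    profiles = [np.asarray(p, dtype=float) for p in profiles]
    n_total = sum(p.size for p in profiles)
    if window_sizes_s is None:
        window_sizes_s = np.geomspace(fit_range_s[0], fit_range_s[1], n_sizes)
    prefixes = [profile_prefixes(p) for p in profiles]
    sizes_out, F_out, skipped = [], [], []
    for size_s in np.asarray(window_sizes_s, dtype=float):
        win = int(round(size_s * fs))
        if win < 4 or win > n_total // 4:
            skipped.append(float(size_s))
            continue
        step = max(1, int(round(win * (1 - overlap_frac))))
        tot, cnt = 0.0, 0
        for p, pre in zip(profiles, prefixes):
            s, c = _window_rms(p, win, step, pre)
            tot += s
            cnt += c
        if cnt == 0:
            skipped.append(float(size_s))
            continue
        sizes_out.append(size_s)
        F_out.append(tot / cnt)
    return np.asarray(sizes_out), np.asarray(F_out), skipped


def dfa_exponent(
    sizes_s: np.ndarray,
    F: np.ndarray,
    fit_range_s: tuple[float, float] = DEFAULT_FIT_RANGE_S,
    n_samples: int = 0,
    skipped: list[float] | None = None,
) -> DFAResult:
    """Least-squares slope of log10 F on log10 size within the fit range."""
    sizes_s = np.asarray(sizes_s, dtype=float)
    F = np.asarray(F, dtype=float)
    lo, hi = fit_range_s
    # small tolerance so geomspace endpoints are not lost to rounding
    mask = (sizes_s >= lo * (1 - 1e-9)) & (sizes_s <= hi * (1 + 1e-9)) & (F > 0)
    if mask.sum() < 4:
        raise DFAEstimationError(
            f"only {int(mask.sum())} window sizes inside the fit range {fit_range_s}"
        )
    lx = np.log10(sizes_s[mask])
    ly = np.log10(F[mask])
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return DFAResult(
        beta=float(slope),
        window_sizes_s=sizes_s,
        F=F,
        fit_range_s=fit_range_s,
        fit_r2=r2,
        n_samples=n_samples,
        skipped_sizes_s=skipped or [],
    )


def dfa(
    envelope_segments: Envelope | np.ndarray | list[np.ndarray],
    fs: float | None = None,
    fit_range_s: tuple[float, float] = DEFAULT_FIT_RANGE_S,
    overlap_frac: float = DEFAULT_OVERLAP,
    n_sizes: int = DEFAULT_N_SIZES,
) -> DFAResult:
    """Full DFA of an envelope (or list of seam-separated envelope segments)."""
    if isinstance(envelope_segments, Envelope):
        fs = envelope_segments.fs
        segs = [envelope_segments.values]
    elif isinstance(envelope_segments, np.ndarray):
        segs = [envelope_segments]
    else:
        segs = list(envelope_segments)
    if fs is None:
        raise ValueError("fs is required for array input")
    segs = [np.asarray(s, dtype=float) for s in segs if np.asarray(s).size >= 2]
    if not segs:
        raise DFAEstimationError("no usable envelope segments")
    n_total = sum(s.size for s in segs)
    gmean = float(sum(s.sum() for s in segs) / n_total)
    profiles = [signal_profile(s, global_mean=gmean) for s in segs]
    sizes, F, skipped = fluctuation_function(
        profiles, fs, overlap_frac=overlap_frac, fit_range_s=fit_range_s, n_sizes=n_sizes
    )
    return dfa_exponent(sizes, F, fit_range_s, n_samples=n_total, skipped=skipped)
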