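"""Vigilance-state scoring per 5-s epoch.

A simplified stand-in for video-plus-LFP sleep scoring: each epoch gets one
of {active_wake, quiet_wake, sleep} from the animal's velocity and the
delta/theta band-power ratio of a reference LFP channel.  High velocity
means active wake; an immobile epoch is scored sleep when delta dominates
theta and quiet wake otherwise.  The default thresholds are declared
stand-ins — synthetic cohorts carry ground-truth labels, so downstream
analyses never depend on them.
"""

from __future__ import annotations

import numpy as np

from .bands import Band
from .signal import EPOCH_S, VigilanceTrack, bandpass, SegmentTooShortError
from scipy.signal import hilbert

DELTA = Band(1.0, 4.0)
THETA = Band(4.0, 10.0)
DEFAULT_V_HI = 1.0  # cm/s
DEFAULT_R_SLEEP = 1.5


def delta_theta_ratio(x: np.ndarray, fs: float, epoch_s: float = EPOCH_S) -> np.ndarray:
    """Delta (1-4 Hz) over theta (4-10 Hz) envelope power per epoch.

    The full trace is filtered once per band (cheaper and smoother than
    per-epoch filtering); epochs shorter than 1 s yield NaN.
    """
    x = np.asarray(x, dtype=float)
    powers = {}
    for name, band in (("delta", DELTA), ("theta", THETA)):
        try:
            env = np.abs(hilbert(bandpass(x, fs, band)))
        except SegmentTooShortError:
            return np.full(max(0, int(len(x) / (epoch_s * fs))), np.nan)
        powers[name] = env**2
    n_epochs = int(len(x) // int(epoch_s * fs))
    win = int(epoch_s * fs)
    ratios = np.full(n_epochs, np.nan)
    for i in range(n_epochs):
        seg = slice(i * win, (i + 1) * win)
        if win < fs:  # epoch under 1 s of data
            continue
        d = powers["delta"][seg].mean()
        t = powers["theta"][seg].mean()
        ratios[i] = d / t if t > 0 else np.inf
    return ratios


def score_epochs(
    ratios: np.ndarray,
    velocity: np.ndarray,
    v_hi: float = DEFAULT_V_HI,
    r_sleep: float = DEFAULT_R_SLEEP,
    epoch_s: float = EPOCH_S,
) -> VigilanceTrack:
    """Pure per-epoch rule: velocity > v_hi -> active_wake; otherwise
    delta/theta >= r_sleep -> sleep, else quiet_wake."""
    ratios = np.asarray(ratios, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if ratios.shape != velocity.shape:
        raise ValueError("ratio and velocity sequences must align")
    labels = []
    for r, v in zip(ratios, velocity):
        if v > v_hi:
            labels.append("active_wake")
        elif r >= r_sleep:
            labels.append("sleep")
        else:
            labels.append("quiet_wake")
    return VigilanceTrack(labels, epoch_s=epoch_s, delta_theta=ratios, velocity=velocity)
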