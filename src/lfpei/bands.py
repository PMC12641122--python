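"""Frequency-band grid construction.

The analysis spectrum is partitioned into one delta band (1-4 Hz) and a set
of geometrically spaced bands covering 4-150 Hz, so that every band has
(approximately) constant relative bandwidth.  Display labels round the raw
geometric edges to the nearest 0.5 Hz; filtering always uses the raw edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Band", "build_band_grid", "DEFAULT_BAND_GRID_PARAMS"]

DEFAULT_BAND_GRID_PARAMS = dict(
    f_delta_lo=1.0, f_delta_hi=4.0, f_lo=4.0, f_hi=150.0, n_log_bands=15
)


def _fmt_edge(x: float) -> str:
    """Round to the nearest 0.5 Hz and drop a trailing '.0'."""
    r = round(x * 2) / 2
    return str(int(r)) if r == int(r) else f"{r:g}"


@dataclass(frozen=True)
class Band:
    """A frequency band [lo, hi] in Hz with a cosmetic display label."""

    lo: float
    hi: float
    label: str = field(default="", compare=False)

    def __post_init__(self):
        if not (0 < self.lo < self.hi):
            raise ValueError(f"invalid band edges ({self.lo}, {self.hi})")
        if not self.label:
            object.__setattr__(self, "label", make_label(self.lo, self.hi))

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)


def make_label(lo: float, hi: float) -> str:
    return f"{_fmt_edge(lo)}–{_fmt_edge(hi)} Hz"


def build_band_grid(
    f_delta_lo: float = 1.0,
    f_delta_hi: float = 4.0,
    f_lo: float = 4.0,
    f_hi: float = 150.0,
    n_log_bands: int = 15,
) -> list[Band]:
    """Build the delta band plus ``n_log_bands`` geometrically spaced bands.

    Log-band edges are ``e_k = f_lo * (f_hi / f_lo) ** (k / n_log_bands)``
    for ``k = 0..n_log_bands``; adjacent bands share an edge so the grid is
    an exact partition of ``[f_delta_lo, f_hi]``.

    Returns ``1 + n_log_bands`` :class:`Band` objects.  With the defaults
    (1, 4, 4, 150, 15) this yields 16 bands; e.g. band index 10 has raw
    edges (35.19, 44.81) and label "35–45 Hz".
    """
    if not (0 < f_delta_lo < f_delta_hi and f_delta_hi == f_lo and f_lo < f_hi):
        raise ValueError(
            "require 0 < f_delta_lo < f_delta_hi = f_lo < f_hi; got "
            f"({f_delta_lo}, {f_delta_hi}, {f_lo}, {f_hi})"
        )
    if n_log_bands < 1:
        raise ValueError("n_log_bands must be >= 1")
    ratio = f_hi / f_lo
    edges = [f_lo * ratio ** (k / n_log_bands) for k in range(n_log_bands + 1)]
    bands = [Band(f_delta_lo, f_delta_hi)]
    for lo, hi in zip(edges[:-1], edges[1:]):
        bands.append(Band(lo, hi))
    return bands
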