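"""End-to-end orchestration: per-week fE/I spectra, per-month PAC, event
catalogs, aggregation, genotype contrasts and the three repeated-measures
correlation analyses.

Every stage consumes a :class:`~lfpei.synth.Cohort` (in-memory or loaded
from the delimited layout) plus a :class:`RunConfig` carrying the analysis
constants.  Defaults follow the reference procedure: 16-band grid over
1-150 Hz, quiet wake for fE/I (>= 2 min rule, beta >= 0.6 gate), active
wake for PAC (10 min per month), vigilance-agnostic event detection, and a
fixed per-comparison alpha of 0.01 across the fE/I band sweep with
0.01-0.05 reported as marginal.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import stats
from .bands import Band, build_band_grid, DEFAULT_BAND_GRID_PARAMS
from .events import EventType, build_catalog, event_rate
from .fei import fei_spectrum
from .pac import amp_grid_bands, monthly_pac, phase_grid_bands
from .signal import Recording, VigilanceTrack
from .synth import Cohort

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable analysis constants with their reference defaults."""

    # band grid
    band_grid: dict = field(default_factory=lambda: dict(DEFAULT_BAND_GRID_PARAMS))
    # fE/I
    fei_state: str = "quiet_wake"
    fei_window_s: float = 5.0
    fei_overlap: float = 0.8
    fei_min_total_s: float = 120.0
    fei_min_windows: int = 40
    beta_threshold: float = 0.6
    dfa_fit_range_s: tuple = (0.4, 30.0)
    # PAC
    pac_state: str = "active_wake"
    pac_target_minutes: float = 10.0
    pac_phase_grid: dict = field(default_factory=lambda: dict(lo_c=2.0, hi_c=14.0, step=1.0, bw=2.0))
    pac_amp_grid: dict | None = None  # None -> region defaults (cortical/HC)
    # events
    k_thresh: float = 8.0
    # correlations
    alpha_primary: float = 0.01
    alpha_marginal: float = 0.05
    weeks_per_month: int = 4
    # misc
    seed: int = 0

    def bands(self) -> list[Band]:
        return build_band_grid(**self.band_grid)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)


def _meta_row(rec: Recording, channel: str) -> dict:
    meta = rec.channels[rec.channel_index(channel)]
    return dict(channel=channel, region=meta.region,
                hc_layer=meta.hc_layer or "none")


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def run_fei(cohort: Cohort, cfg: RunConfig | None = None,
            regions: tuple[str, ...] = ("PTC", "HC")) -> pd.DataFrame:
    """Weekly per-channel-per-band fE/I table (tidy).

    Rows carry the fE/I value (NaN when missing) alongside the typed
    missing reason, the DFA exponent and the window count, so exclusions
    stay auditable.
    """
    cfg = cfg or RunConfig()
    bands = cfg.bands()
    geno = dict(zip(cohort.manifest["subject_id"], cohort.manifest["genotype"]))
    rows = []
    for (subject, week), rec in sorted(cohort.recordings.items()):
        ann = cohort.annotations[(subject, week)]
        for meta in rec.channels:
            if meta.region not in regions:
                continue
            results = fei_spectrum(
                rec, meta.name, bands, ann,
                state=cfg.fei_state, min_total_s=cfg.fei_min_total_s,
                beta_threshold=cfg.beta_threshold, window_s=cfg.fei_window_s,
                overlap_frac=cfg.fei_overlap, min_windows=cfg.fei_min_windows,
            )
            for res in results:
                rows.append(dict(
                    subject=subject, genotype=geno.get(subject, ""),
                    age_week=week, age_month=rec.age_month,
                    **_meta_row(rec, meta.name),
                    metric="fei", band=res.band.label,
                    value=np.nan if res.fei is None else res.fei,
                    r=np.nan if res.r is None else res.r,
                    dfa_beta=np.nan if res.dfa_beta is None else res.dfa_beta,
                    n_windows=res.n_windows,
                    missing_reason=res.missing_reason.value,
                ))
    return pd.DataFrame(rows)


def run_pac(cohort: Cohort, cfg: RunConfig | None = None,
            regions: tuple[str, ...] = ("PTC", "HC")) -> pd.DataFrame:
    """Monthly per-channel PAC summary table (theta x low/high/total gamma)."""
    cfg = cfg or RunConfig()
    phase_bands = phase_grid_bands(**cfg.pac_phase_grid)
    geno = dict(zip(cohort.manifest["subject_id"], cohort.manifest["genotype"]))
    by_month: dict[tuple[str, int], list[tuple[Recording, VigilanceTrack]]] = {}
    for (subject, week), rec in sorted(cohort.recordings.items()):
        by_month.setdefault((subject, rec.age_month), []).append(
            (rec, cohort.annotations[(subject, week)])
        )
    rows = []
    for (subject, month), weekly in sorted(by_month.items()):
        rec0 = weekly[0][0]
        for meta in rec0.channels:
            if meta.region not in regions:
                continue
            if cfg.pac_amp_grid is not None:
                amp_bands = amp_grid_bands(meta.region, fs=rec0.fs, **cfg.pac_amp_grid)
            else:
                amp_bands = amp_grid_bands(meta.region, fs=rec0.fs)
            mp = monthly_pac(
                weekly, meta.name, meta.region,
                target_minutes=cfg.pac_target_minutes, state=cfg.pac_state,
                phase_bands=phase_bands, amp_bands=amp_bands,
            )
            if mp.excluded:
                continue
            summaries = dict(theta_low_gamma=mp.summary.theta_low_gamma,
                             theta_high_gamma=mp.summary.theta_high_gamma)
            if mp.summary.theta_total_gamma is not None:
                summaries["theta_total_gamma"] = mp.summary.theta_total_gamma
            for metric, val in summaries.items():
                rows.append(dict(
                    subject=subject, genotype=geno.get(subject, ""),
                    age_month=month, **_meta_row(rec0, meta.name),
                    metric=metric, band="", value=val,
                    minutes_used=mp.minutes_used, shortfall=mp.shortfall,
                ))
    return pd.DataFrame(rows)


def run_events(cohort: Cohort, cfg: RunConfig | None = None
               ) -> tuple[pd.DataFrame, dict]:
    """Weekly event-rate table plus the full per-recording catalogs."""
    cfg = cfg or RunConfig()
    geno = dict(zip(cohort.manifest["subject_id"], cohort.manifest["genotype"]))
    rows = []
    catalogs = {}
    for (subject, week), rec in sorted(cohort.recordings.items()):
        cat = build_catalog(rec, k_thresh=cfg.k_thresh)
        catalogs[(subject, week)] = cat
        for etype in (EventType.isolated_hc, EventType.isolated_ctx, EventType.giant):
            rows.append(dict(
                subject=subject, genotype=geno.get(subject, ""),
                age_week=week, age_month=rec.age_month,
                event_type=etype.value, rate_hz=event_rate(cat, etype),
            ))
        rows.append(dict(
            subject=subject, genotype=geno.get(subject, ""),
            age_week=week, age_month=rec.age_month,
            event_type="swd", rate_hz=len(cat.episodes) / cat.recording_duration_s,
        ))
    return pd.DataFrame(rows), catalogs


# ---------------------------------------------------------------------------
# correlation sweeps and contrasts
# ---------------------------------------------------------------------------

def _flag(p: float, cfg: RunConfig) -> str:
    if p < cfg.alpha_primary:
        return "significant"
    if p < cfg.alpha_marginal:
        return "marginal"
    return "ns"


def correlate_fei_spikes(fei_table: pd.DataFrame, rates: pd.DataFrame,
                         cfg: RunConfig | None = None,
                         event_type: str = "isolated_hc",
                         region: str | None = None) -> pd.DataFrame:
    """Band sweep of rmcorr between weekly mouse-level fE/I and spike rate.

    Zero-rate weeks are excluded; analyses are per region when ``region``
    is given (HC layers never pool with PTC upstream of this call).
    """
    cfg = cfg or RunConfig()
    sub = fei_table if region is None else fei_table[fei_table["region"] == region]
    rsub = rates[rates["event_type"] == event_type][["subject", "age_week", "rate_hz"]]
    rows = []
    for band, btab in sub.groupby("band", observed=True):
        try:
            pairs = stats.match_fei_spikes(btab, rsub)
            res = stats.rmcorr(pairs)
        except stats.EstimationError as e:
            log.info("band %s: %s", band, e)
            continue
        rows.append(dict(band=band, r_rm=res.r_rm, p=res.p, dof=res.dof,
                         n_pairs=res.n_pairs, n_subjects=res.n_subjects,
                         flag=_flag(res.p, cfg)))
    return pd.DataFrame(rows)


def correlate_fei_pac(fei_table: pd.DataFrame, pac_table: pd.DataFrame,
                      cfg: RunConfig | None = None,
                      pac_metric: str = "theta_low_gamma",
                      region: str | None = None) -> pd.DataFrame:
    """Band sweep of rmcorr between monthly electrode-level fE/I and PAC."""
    cfg = cfg or RunConfig()
    fsub = fei_table if region is None else fei_table[fei_table["region"] == region]
    psub = pac_table[pac_table["metric"] == pac_metric]
    if region is not None:
        psub = psub[psub["region"] == region]
    pac_m = psub[["subject", "channel", "age_month", "value"]]
    rows = []
    for band, btab in fsub.groupby("band", observed=True):
        fei_m, _ = stats.weekly_to_monthly(btab)
        try:
            pairs = stats.match_fei_pac(
                fei_m[["subject", "channel", "age_month", "value"]], pac_m)
            res = stats.rmcorr(pairs)
        except stats.EstimationError as e:
            log.info("band %s: %s", band, e)
            continue
        rows.append(dict(band=band, r_rm=res.r_rm, p=res.p, dof=res.dof,
                         n_pairs=res.n_pairs, n_subjects=res.n_subjects,
                         flag=_flag(res.p, cfg)))
    return pd.DataFrame(rows)


def correlate_pac_spikes(pac_table: pd.DataFrame, rates: pd.DataFrame,
                         cfg: RunConfig | None = None,
                         pac_metric: str = "theta_low_gamma",
                         event_type: str = "isolated_hc",
                         region: str | None = None):
    """rmcorr between monthly mouse-level PAC and monthly spike rate."""
    cfg = cfg or RunConfig()
    psub = pac_table[pac_table["metric"] == pac_metric]
    if region is not None:
        psub = psub[psub["region"] == region]
    rsub = rates[rates["event_type"] == event_type][
        ["subject", "age_week", "age_month", "rate_hz"]]
    pairs = stats.match_pac_spikes(psub, rsub, weeks_per_month=cfg.weeks_per_month)
    res = stats.rmcorr(pairs)
    return res


def genotype_contrast_fei(fei_table: pd.DataFrame, band_label: str,
                          cfg: RunConfig | None = None,
                          region: str | None = None) -> list[stats.GroupComparison]:
    """Monthly genotype contrast on mouse-level fE/I in one band."""
    cfg = cfg or RunConfig()
    sub = fei_table[fei_table["band"] == band_label]
    if region is not None:
        sub = sub[sub["region"] == region]
    _, mouse_month = stats.weekly_to_monthly(sub)
    return stats.genotype_compare(mouse_month)


def genotype_contrast_pac(pac_table: pd.DataFrame,
                          pac_metric: str = "theta_low_gamma",
                          region: str | None = None) -> list[stats.GroupComparison]:
    """Monthly genotype contrast on mouse-level PAC."""
    sub = pac_table[pac_table["metric"] == pac_metric]
    if region is not None:
        sub = sub[sub["region"] == region]
    _, mouse_month = stats.weekly_to_monthly(sub)
    return stats.genotype_compare(mouse_month)
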