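"""Longitudinal aggregation, genotype comparisons and repeated-measures
correlations.

The central tool is the repeated-measures correlation (rmcorr): an ANCOVA
with one intercept per subject and a common slope, whose correlation
coefficient r_rm = sign(slope) * sqrt(SS_x / (SS_x + SS_resid)) estimates
the shared within-subject association between two repeatedly measured
variables while discarding between-subject variability.  Degrees of
freedom are N - k - 1 for N pairs from k subjects; the confidence interval
uses the Fisher z transform with the dof-matched standard error.

Aggregation follows the two-stage scheme used throughout: weekly values
are first averaged per electrode within a month, then across electrodes
per mouse.  Genotype contrasts per month use Levene's test to choose
between Student's and Welch's t-test, with Benjamini-Hochberg correction
across months.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

VALUE_COLS = ("subject", "genotype", "age_week", "age_month", "channel",
              "region", "hc_layer", "metric", "band", "value")


class EstimationError(ValueError):
    """Too little usable data to estimate the requested quantity."""


# ---------------------------------------------------------------------------
# repeated-measures correlation
# ---------------------------------------------------------------------------

@dataclass
class RmcorrResult:
    r_rm: float
    ci95: tuple[float, float]
    p: float
    dof: int
    n_pairs: int
    n_subjects: int


def rmcorr(pairs: pd.DataFrame, x: str = "x", y: str = "y",
           subject: str = "subject") -> RmcorrResult:
    """Repeated-measures correlation of ``x`` and ``y`` within subjects.

    Subjects contributing fewer than two pairs, or with zero variance in
    ``x``, carry no slope information and are dropped (the fit is invariant
    to them up to their intercept).  Raises :class:`EstimationError` when
    fewer than two informative subjects remain.
    """
    df = pairs[[subject, x, y]].dropna()
    counts = df.groupby(subject)[x].agg(["count", "std"])
    good = counts[(counts["count"] >= 2) & (counts["std"] > 0)].index
    df = df[df[subject].isin(good)]
    subjects = df[subject].unique()
    k = len(subjects)
    n = len(df)
    if k < 2:
        raise EstimationError("rmcorr requires >= 2 subjects with >= 2 varying pairs")
    # within-subject centering == subject-indicator ANCOVA
    xc = df[x] - df.groupby(subject)[x].transform("mean")
    yc = df[y] - df.groupby(subject)[y].transform("mean")
    ss_xc = float(np.dot(xc, xc))
    slope = float(np.dot(xc, yc)) / ss_xc
    resid = yc - slope * xc
    ss_effect = slope**2 * ss_xc
    ss_resid = float(np.dot(resid, resid))
    denom = ss_effect + ss_resid
    r = 0.0 if denom == 0 else np.sign(slope) * np.sqrt(ss_effect / denom)
    dof = n - k - 1
    if dof < 1:
        raise EstimationError("non-positive degrees of freedom")
    if abs(r) >= 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt(dof / (1 - r**2))
        p = 2 * sps.t.sf(abs(tstat), dof)
    # Fisher z CI with the dof-matched SE (1/sqrt(dof - 1))
    if dof > 1 and abs(r) < 1.0:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(dof - 1)
        ci = (float(np.tanh(z - 1.959963984540054 * se)),
              float(np.tanh(z + 1.959963984540054 * se)))
    else:
        ci = (float(r), float(r))
    return RmcorrResult(float(r), ci, float(p), int(dof), int(n), int(k))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def weekly_to_monthly(table: pd.DataFrame, value: str = "value"
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-stage monthly aggregation of a tidy weekly table.

    Stage 1 averages the weekly values of each electrode within a month
    (missing weeks simply drop out of the mean); stage 2 averages the
    electrode-months across electrodes per mouse.  Returns
    ``(electrode_month, mouse_month)`` — the intermediate is retained
    because channel-level matching (e.g. fE/I vs PAC) joins on it.
    """
    keys_e = [c for c in ("subject", "genotype", "age_month", "channel",
                          "region", "hc_layer", "metric", "band")
              if c in table.columns]
    electrode_month = (
        table.dropna(subset=[value])
        .groupby(keys_e, dropna=False, observed=True)[value]
        .mean()
        .reset_index()
    )
    keys_m = [c for c in keys_e if c not in ("channel", "region", "hc_layer")]
    mouse_month = (
        electrode_month.groupby(keys_m, dropna=False, observed=True)[value]
        .mean()
        .reset_index()
    )
    return electrode_month, mouse_month


# ---------------------------------------------------------------------------
# metric matching for the three correlation analyses
# ---------------------------------------------------------------------------

def match_fei_pac(fei_monthly: pd.DataFrame, pac_monthly: pd.DataFrame
                  ) -> pd.DataFrame:
    """Electrode-level monthly fE/I joined with monthly PAC MI.

    Inner join on (subject, channel, age_month); repeated measures within a
    subject are months x channels.
    """
    keys = ["subject", "channel", "age_month"]
    merged = fei_monthly.merge(
        pac_monthly, on=keys, suffixes=("_fei", "_pac"), how="inner"
    )
    if merged.empty:
        raise EstimationError("empty fE/I-PAC join")
    return merged.rename(columns={"value_fei": "x", "value_pac": "y"})


def match_fei_spikes(fei_weekly: pd.DataFrame, rates_weekly: pd.DataFrame
                     ) -> pd.DataFrame:
    """Mouse-level weekly fE/I (averaged across channels) joined with the
    weekly spike rate; zero-rate weeks are excluded."""
    fei_mouse = (
        fei_weekly.dropna(subset=["value"])
        .groupby(["subject", "age_week"], observed=True)["value"]
        .mean()
        .reset_index()
    )
    merged = fei_mouse.merge(rates_weekly, on=["subject", "age_week"], how="inner")
    merged = merged[merged["rate_hz"] > 0]
    if merged.empty:
        raise EstimationError("empty fE/I-spike join (all weeks zero-rate?)")
    return merged.rename(columns={"value": "x", "rate_hz": "y"})


def match_pac_spikes(pac_monthly: pd.DataFrame, rates_weekly: pd.DataFrame,
                     weeks_per_month: int = 4) -> pd.DataFrame:
    """Mouse-level monthly PAC joined with the monthly mean spike rate;
    zero-rate months are excluded."""
    pac_mouse = (
        pac_monthly.dropna(subset=["value"])
        .groupby(["subject", "age_month"], observed=True)["value"]
        .mean()
        .reset_index()
    )
    rates = rates_weekly.copy()
    if "age_month" not in rates.columns:
        rates["age_month"] = rates["age_week"] // weeks_per_month
    rate_month = (
        rates.groupby(["subject", "age_month"], observed=True)["rate_hz"]
        .mean()
        .reset_index()
    )
    merged = pac_mouse.merge(rate_month, on=["subject", "age_month"], how="inner")
    merged = merged[merged["rate_hz"] > 0]
    if merged.empty:
        raise EstimationError("empty PAC-spike join (all months zero-rate?)")
    return merged.rename(columns={"value": "x", "rate_hz": "y"})


# ---------------------------------------------------------------------------
# genotype comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    age_month: int
    mean_wt: float
    mean_app: float
    delta: float
    test: str           # "student" | "welch"
    p_raw: float
    p_fdr: float
    levene_p: float
    n_wt: int
    n_app: int
    significant: bool = False


def genotype_compare(
    mouse_month: pd.DataFrame,
    value: str = "value",
    genotypes: tuple[str, str] = ("WT", "APP"),
    alpha_levene: float = 0.05,
    q: float = 0.05,
) -> list[GroupComparison]:
    """Per-month genotype contrast on mouse-level values.

    Levene's test picks Student's (equal variance) versus Welch's t-test;
    raw p-values are Benjamini-Hochberg corrected across the months at
    FDR level ``q``.  Months with fewer than two mice per group are
    skipped.
    """
    out: list[GroupComparison] = []
    for month, sub in mouse_month.groupby("age_month", observed=True):
        a = sub.loc[sub["genotype"] == genotypes[0], value].dropna().to_numpy()
        b = sub.loc[sub["genotype"] == genotypes[1], value].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        lev_p = float(sps.levene(a, b).pvalue)
        equal_var = lev_p >= alpha_levene
        t = sps.ttest_ind(a, b, equal_var=equal_var)
        out.append(GroupComparison(
            age_month=int(month),
            mean_wt=float(a.mean()), mean_app=float(b.mean()),
            delta=float(b.mean() - a.mean()),
            test="student" if equal_var else "welch",
            p_raw=float(t.pvalue), p_fdr=np.nan, levene_p=lev_p,
            n_wt=len(a), n_app=len(b),
        ))
    if out:
        rej, p_fdr, _, _ = multipletests([c.p_raw for c in out], alpha=q, method="fdr_bh")
        for c, pf, rj in zip(out, p_fdr, rej):
            c.p_fdr = float(pf)
            c.significant = bool(rj)
    return out


def bmlm_export(table: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Analysis-ready table for external multilevel model fitting:
    (value, genotype, age_month, mouse, channel)."""
    cols = {"value": table[value], "genotype": table.get("genotype"),
            "age_month": table.get("age_month"), "mouse": table.get("subject"),
            "channel": table.get("channel")}
    return pd.DataFrame(cols).dropna(subset=["value"])
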