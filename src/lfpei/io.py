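"""Reading and writing the delimited interchange formats.

Recordings travel either as EDF/EDF+ (read through :mod:`mne`, installed
separately) or as delimited columnar text: first column ``time_s``, one
column per channel (header row carries channel names), physical units µV.
Channel region metadata lives in the cohort manifest.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .signal import ChannelMeta, Recording, VigilanceTrack

MANIFEST_COLUMNS = ["subject_id", "genotype", "age_week", "age_month", "file",
                    "channel", "region", "hc_layer", "hemisphere"]


def write_recording_csv(rec: Recording, path: str | os.PathLike) -> None:
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time_s": t})
    for i, c in enumerate(rec.channels):
        df[c.name] = rec.data[i]
    df.to_csv(path, index=False, float_format="%.5f")


def read_recording_csv(
    path: str | os.PathLike,
    channels: list[ChannelMeta] | None = None,
    subject_id: str = "",
    age_week: int | None = None,
    age_month: int | None = None,
) -> Recording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: first column must be time_s")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: too few samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    names = [c for c in df.columns if c != "time_s"]
    if channels is None:
        # without a manifest, region metadata is unknown; guess from names
        channels = [ChannelMeta(n, "HC", "pyramidal") if n.upper().startswith("HC")
                    else ChannelMeta(n, "PFC" if n.upper().startswith("PFC") else "PTC")
                    for n in names]
    else:
        order = {c.name: c for c in channels}
        missing = set(n for n in names) - set(order)
        if missing:
            raise ValueError(f"{path}: channels {sorted(missing)} not in manifest")
        channels = [order[n] for n in names]
    data = df[names].to_numpy().T
    return Recording(data, round(fs, 6), channels, subject_id, age_week, age_month)


def read_recording_edf(path: str | os.PathLike, channels: list[ChannelMeta] | None = None,
                       **meta) -> Recording:
    """Read an EDF/EDF+ file (one signal per channel, µV) via mne."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError("EDF support requires the 'mne' package") from e
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> µV
    names = raw.ch_names
    if channels is None:
        channels = [ChannelMeta(n, "PTC") for n in names]
    else:
        order = {c.name: c for c in channels}
        channels = [order[n] for n in names]
    return Recording(data, float(raw.info["sfreq"]), channels, **meta)


def read_recording(path: str | os.PathLike, channels: list[ChannelMeta] | None = None,
                   **meta) -> Recording:
    if str(path).lower().endswith((".edf", ".edf+")):
        return read_recording_edf(path, channels, **meta)
    return read_recording_csv(path, channels, **meta)


def write_annotation(track: VigilanceTrack, path: str | os.PathLike) -> None:
    pd.DataFrame({
        "epoch_index": np.arange(len(track)),
        "state": track.labels,
    }).to_csv(path, index=False)


def read_annotation(path: str | os.PathLike, epoch_s: float = 5.0) -> VigilanceTrack:
    df = pd.read_csv(path).sort_values("epoch_index")
    return VigilanceTrack(list(df["state"]), epoch_s=epoch_s)


def write_velocity(velocity: np.ndarray, path: str | os.PathLike) -> None:
    pd.DataFrame({"epoch_index": np.arange(len(velocity)),
                  "cm_s": velocity}).to_csv(path, index=False)


def read_velocity(path: str | os.PathLike) -> np.ndarray:
    df = pd.read_csv(path).sort_values("epoch_index")
    return df["cm_s"].to_numpy()


def channels_from_manifest(manifest: pd.DataFrame, subject: str, age_week: int
                           ) -> list[ChannelMeta]:
    sub = manifest[(manifest["subject_id"] == subject)
                   & (manifest["age_week"] == age_week)]
    metas = []
    for _, row in sub.iterrows():
        layer = row["hc_layer"] if row["hc_layer"] not in ("none", "", None) else None
        metas.append(ChannelMeta(row["channel"], row["region"], layer,
                                 row.get("hemisphere", "unknown")))
    return metas


def write_cohort(cohort, outdir: str | os.PathLike) -> Path:
    """Write a synthetic cohort to ``outdir`` in the interchange layout:
    manifest.csv plus recordings/ and annotations/ subdirectories."""
    out = Path(outdir)
    (out / "recordings").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    for (subject, week), rec in cohort.recordings.items():
        fname = f"recordings/{subject}_w{week:03d}.csv"
        write_recording_csv(rec, out / fname)
        ann = cohort.annotations[(subject, week)]
        write_annotation(ann, out / "annotations" / f"{subject}_w{week:03d}.csv")
        if ann.velocity is not None:
            write_velocity(ann.velocity,
                           out / "annotations" / f"{subject}_w{week:03d}_velocity.csv")
        mask = (manifest["subject_id"] == subject) & (manifest["age_week"] == week)
        manifest.loc[mask, "file"] = fname
    manifest.to_csv(out / "manifest.csv", index=False)
    return out


def load_cohort(indir: str | os.PathLike):
    """Load a cohort written by :func:`write_cohort` (or hand-assembled in
    the same layout) back into in-memory structures."""
    from .synth import Cohort  # local import to avoid a cycle

    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    recordings, annotations = {}, {}
    for (subject, week), sub in manifest.groupby(["subject_id", "age_week"]):
        metas = channels_from_manifest(manifest, subject, week)
        fname = sub["file"].iloc[0]
        month = int(sub["age_month"].iloc[0])
        rec = read_recording(indir / fname, metas, subject_id=subject,
                             age_week=int(week), age_month=month)
        recordings[(subject, int(week))] = rec
        ann_path = indir / "annotations" / f"{subject}_w{int(week):03d}.csv"
        ann = read_annotation(ann_path)
        vel_path = indir / "annotations" / f"{subject}_w{int(week):03d}_velocity.csv"
        if vel_path.exists():
            ann.velocity = read_velocity(vel_path)
        annotations[(subject, int(week))] = ann
    return Cohort(manifest, recordings, annotations, truth={}, effects={}, seed=-1)
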