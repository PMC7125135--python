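"""Readers and writers for the package's on-disk layouts.

HDF5 containers hold one group per stream (``values``, ``start_time`` as
ISO-8601, ``rate``); epoch count series, minute labels and episode tables are
exchanged as plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import EpochCountSeries, MinuteLabels, TriaxialRecording
from .gold_standard import EPISODE_COLUMNS
from .simulate import GroundTruth


def write_recording_h5(
    path,
    hip: TriaxialRecording,
    chest: TriaxialRecording,
    heart_rate: pd.Series,
    truth: GroundTruth | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        for name, rec in (("hip", hip), ("chest", chest)):
            g = f.create_group(name)
            g.create_dataset("values", data=rec.data.astype(np.float32))
            g.attrs["start_time"] = rec.start_time.isoformat()
            g.attrs["rate"] = float(rec.rate)
        g = f.create_group("heart_rate")
        g.create_dataset("values", data=heart_rate.to_numpy(dtype=np.float64))
        g.attrs["start_time"] = pd.Timestamp(heart_rate.index[0]).isoformat()
        g.attrs["rate"] = 1.0
        if truth is not None:
            g = f.create_group("truth")
            g.create_dataset("minute_labels", data=truth.minute_labels.values)
            g.attrs["start_time"] = truth.minute_labels.start_time.isoformat()
            ep = g.create_group("episodes")
            n_ep = len(truth.episodes)
            for col in ("start_minute", "end_minute"):
                values = truth.episodes[col].to_numpy(dtype=np.int64) if n_ep else []
                ep.create_dataset(col, data=values, dtype=np.int64)
            for col in ("label", "scenario"):
                strings = [
                    "" if v is None or v is np.nan else str(v)
                    for v in truth.episodes[col]
                ]
                ep.create_dataset(col, data=strings, dtype=h5py.string_dtype())


def _read_stream(g) -> TriaxialRecording:
    return TriaxialRecording(
        start_time=g.attrs["start_time"], rate=float(g.attrs["rate"]),
        data=g["values"][()],
    )


def read_recording_h5(path):
    """Returns ``(hip, chest, heart_rate, truth)``; truth may be None."""
    with h5py.File(path, "r") as f:
        hip = _read_stream(f["hip"])
        chest = _read_stream(f["chest"])
        g = f["heart_rate"]
        idx = pd.date_range(
            g.attrs["start_time"], periods=g["values"].shape[0], freq="1s"
        )
        heart_rate = pd.Series(g["values"][()], index=idx, name="heart_rate_bpm")
        truth = None
        if "truth" in f:
            g = f["truth"]
            labels = MinuteLabels(g.attrs["start_time"], g["minute_labels"][()])
            ep = g["episodes"]
            episodes = pd.DataFrame(
                {
                    "start_minute": ep["start_minute"][()],
                    "end_minute": ep["end_minute"][()],
                    "label": [s.decode() for s in ep["label"][()]],
                    "scenario": [s.decode() or None for s in ep["scenario"][()]],
                }
            )
            truth = GroundTruth(labels, episodes)
    return hip, chest, heart_rate, truth


def write_epoch_csv(path, series: EpochCountSeries) -> None:
    series.to_frame().to_csv(path, index=False)


def read_epoch_csv(path) -> EpochCountSeries:
    df = pd.read_csv(path, parse_dates=["epoch_start"])
    if len(df) == 0:
        raise ValueError(f"empty epoch series in {path}")
    starts = pd.DatetimeIndex(df["epoch_start"])
    epoch_length = (
        (starts[1] - starts[0]).total_seconds() if len(df) > 1 else 60.0
    )
    counts = df[["cx", "cy", "cz"]].to_numpy(dtype=np.int64)
    return EpochCountSeries(starts[0], counts, epoch_length)


def write_labels_csv(path, labels: MinuteLabels) -> None:
    labels.to_frame().to_csv(path, index=False)


def read_labels_csv(path) -> MinuteLabels:
    df = pd.read_csv(path, parse_dates=["minute_start"])
    if len(df) == 0:
        raise ValueError(f"empty label vector in {path}")
    return MinuteLabels(df["minute_start"].iloc[0], df["nonwear"].to_numpy())


def write_episodes_csv(path, episodes: pd.DataFrame) -> None:
    cols = [c for c in EPISODE_COLUMNS if c in episodes.columns]
    cols += [c for c in episodes.columns if c not in cols]
    episodes[cols].to_csv(path, index=False)


def read_episodes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("start_minute", "end_minute", "label") if c not in df]
    if missing:
        raise ValueError(f"episode table {path} lacks columns {missing}")
    return df
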