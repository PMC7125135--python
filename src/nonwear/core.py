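"""Core containers shared by every stage of the non-wear pipeline.

Conventions used throughout the package:

* acceleration is expressed in gravitational units (*g*); thresholds quoted in
  milli-g (mg) are converted with :data:`G_TO_MG`;
* the minute grid is zero-based and half-open: minute ``i`` of a recording
  covers ``[start + 60 i, start + 60 (i + 1))`` seconds;
* in label vectors the positive class is **non-wear** (1 = non-wear, 0 = wear).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

G_TO_MG = 1000.0
#: default accelerometer dynamic range in g
DYNAMIC_RANGE_G = 8.0


def _as_timestamp(t) -> pd.Timestamp:
    ts = pd.Timestamp(t)
    if ts is pd.NaT:
        raise ValueError("invalid start_time")
    return ts


@dataclass
class TriaxialRecording:
    """Uniformly sampled triaxial acceleration in g.

    Parameters
    ----------
    start_time
        Timestamp of the first sample.
    rate
        Sampling rate in Hz (> 0).
    data
        Array of shape ``(n_samples, 3)``; axis order x, y, z.
    """

    start_time: pd.Timestamp
    rate: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.start_time = _as_timestamp(self.start_time)
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ValueError("data must have shape (n_samples, 3)")

    def validate(self, dynamic_range: float = DYNAMIC_RANGE_G) -> "TriaxialRecording":
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if not np.isfinite(self.data).all():
            idx = int(np.flatnonzero(~np.isfinite(self.data).all(axis=1))[0])
            raise ValueError(f"non-finite acceleration at sample index {idx}")
        amax = float(np.abs(self.data).max(initial=0.0))
        if amax > dynamic_range:
            raise ValueError(
                f"acceleration magnitude {amax:.3f} g exceeds the ±{dynamic_range} g dynamic range"
            )
        return self

    # -- convenience accessors -------------------------------------------------
    @property
    def acc_x(self) -> np.ndarray:
        return self.data[:, 0]

    @property
    def acc_y(self) -> np.ndarray:
        return self.data[:, 1]

    @property
    def acc_z(self) -> np.ndarray:
        return self.data[:, 2]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.to_timedelta(self.duration_s, unit="s")

    @property
    def samples_per_minute(self) -> int:
        return int(round(self.rate * 60))

    @property
    def n_minutes(self) -> int:
        """Number of whole minutes covered by the recording."""
        return self.n_samples // self.samples_per_minute

    def minute_slice(self, start_minute: int, n_minutes: int = 1) -> np.ndarray:
        """Samples covering ``[start_minute, start_minute + n_minutes)``."""
        spm = self.samples_per_minute
        i, j = start_minute * spm, (start_minute + n_minutes) * spm
        if start_minute < 0 or j > self.n_samples:
            raise ValueError(
                f"window [{start_minute}, {start_minute + n_minutes}) min outside recording"
            )
        return self.data[i:j]


@dataclass
class EpochCountSeries:
    """Per-epoch activity counts for three axes.

    ``counts`` has shape ``(n_epochs, 3)`` and holds non-negative integers; the
    vector magnitude (VMU) per epoch is derived on demand and therefore always
    consistent with the axis counts.
    """

    start_time: pd.Timestamp
    counts: np.ndarray
    epoch_length: float = 60.0

    def __post_init__(self) -> None:
        self.start_time = _as_timestamp(self.start_time)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 3:
            raise ValueError("counts must have shape (n_epochs, 3)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.epoch_length > 0:
            raise ValueError("epoch_length must be positive")

    @property
    def vmu(self) -> np.ndarray:
        c = self.counts.astype(float)
        return np.sqrt((c * c).sum(axis=1))

    def __len__(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        idx = self.start_time + pd.to_timedelta(
            np.arange(len(self)) * self.epoch_length, unit="s"
        )
        return pd.DataFrame(
            {
                "epoch_start": idx,
                "cx": self.counts[:, 0],
                "cy": self.counts[:, 1],
                "cz": self.counts[:, 2],
                "vmu": self.vmu,
            }
        )


@dataclass
class MinuteLabels:
    """Per-minute binary wear/non-wear vector (1 = non-wear)."""

    start_time: pd.Timestamp
    values: np.ndarray

    def __post_init__(self) -> None:
        self.start_time = _as_timestamp(self.start_time)
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("labels must be binary (0 = wear, 1 = non-wear)")
        self.values = v.astype(np.uint8)

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def minute_starts(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(np.arange(len(self)), unit="min")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"minute_start": self.minute_starts, "nonwear": self.values})


@dataclass(frozen=True)
class ConfusionCounts:
    """Minute-wise confusion tallies; the positive class is non-wear."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def runs_of_ones(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open ``(start, end)`` index pairs of maximal True runs in ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))
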