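"""Epoch-based non-wear algorithms operating on 60-s count series.

Three classic count-based detectors, each returning one wear/non-wear label
per minute (1 = non-wear):

* **Hecht** — a per-minute vote over the current VMU value and the number of
  supra-threshold minutes in the surrounding windows;
* **Troiano** — maximal runs of zero-count minutes of at least a minimum
  length, tolerating a bounded number of small "artificial movement" spikes;
* **Choi** — zero-count runs that may absorb short non-zero bursts when the
  flanking windows are themselves quiet.

Hyperparameters default to the values published with each algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EpochCountSeries, MinuteLabels


@dataclass
class HechtParams:
    """VMU threshold in counts/min, window length in minutes, spikes required."""

    vmu_threshold: float = 5.0
    window: int = 20
    window_spikes: int = 2

    def validate(self) -> "HechtParams":
        if self.window < 1:
            raise ValueError("window must be >= 1 minute")
        if self.window_spikes < 0:
            raise ValueError("window_spikes must be >= 0")
        if self.vmu_threshold < 0:
            raise ValueError("vmu_threshold must be >= 0")
        return self


@dataclass
class TroianoParams:
    min_interval: int = 60
    spikes_allowed: int = 2
    spike_lower: float = 0.0
    spike_upper: float = 100.0
    use_vmu: bool = False

    def validate(self) -> "TroianoParams":
        if self.min_interval < 1:
            raise ValueError("min_interval must be >= 1 minute")
        if self.spikes_allowed < 0:
            raise ValueError("spikes_allowed must be >= 0")
        if not self.spike_lower < self.spike_upper:
            raise ValueError("spike_lower must be < spike_upper")
        return self


@dataclass
class ChoiParams:
    min_interval: int = 90
    interval_spikes: int = 2
    window: int = 30
    window_spikes: int = 0
    use_vmu: bool = False

    def validate(self) -> "ChoiParams":
        if self.min_interval < 1:
            raise ValueError("min_interval must be >= 1 minute")
        if self.interval_spikes < 0 or self.window_spikes < 0:
            raise ValueError("spike counts must be >= 0")
        if self.window < 0:
            raise ValueError("window must be >= 0")
        return self


def _check_minute_epochs(series: EpochCountSeries) -> None:
    if series.epoch_length != 60:
        raise ValueError(
            f"expected 60-s epochs, got {series.epoch_length}-s; aggregate first"
        )


def _activity(series: EpochCountSeries, use_vmu: bool, axis: int = 0) -> np.ndarray:
    """The scalar activity series an algorithm scans: one axis, or the VMU."""
    if use_vmu:
        return series.vmu
    return series.counts[:, axis].astype(float)


def hecht(series: EpochCountSeries, params: HechtParams | None = None) -> MinuteLabels:
    """Hecht wear/non-wear vote on the per-minute VMU.

    For each minute three conditions are evaluated: (1) the VMU of the minute
    exceeds the threshold; (2) at least ``window_spikes`` of the following
    ``window`` minutes exceed it; (3) the same for the preceding minutes.  A
    minute is wear time iff at least two conditions hold.  Windows truncated
    at the recording boundary are evaluated over the minutes that exist.
    """
    p = (params or HechtParams()).validate()
    _check_minute_epochs(series)
    vmu = series.vmu
    if not np.isfinite(vmu).all():
        raise ValueError("VMU contains non-finite values")
    n = vmu.shape[0]
    above = vmu > p.vmu_threshold
    cs = np.concatenate(([0], np.cumsum(above)))
    idx = np.arange(n)
    following = cs[np.minimum(n, idx + 1 + p.window)] - cs[idx + 1]
    preceding = cs[idx] - cs[np.maximum(0, idx - p.window)]
    votes = (
        above.astype(int)
        + (following >= p.window_spikes).astype(int)
        + (preceding >= p.window_spikes).astype(int)
    )
    nonwear = (votes < 2).astype(np.uint8)
    return MinuteLabels(series.start_time, nonwear)


def troiano(
    series: EpochCountSeries, params: TroianoParams | None = None, axis: int = 0
) -> MinuteLabels:
    """Troiano zero-count interval scan.

    A forward scan collects maximal runs of zero-activity minutes (activity
    <= ``spike_lower``), tolerating up to ``spikes_allowed`` spike minutes
    with activity strictly between ``spike_lower`` and ``spike_upper``; a
    minute at or above ``spike_upper`` terminates the run.  Runs of total
    length >= ``min_interval`` are labelled non-wear, spike minutes included.
    """
    p = (params or TroianoParams()).validate()
    _check_minute_epochs(series)
    a = _activity(series, p.use_vmu, axis)
    n = a.shape[0]
    nonwear = np.zeros(n, dtype=np.uint8)
    i = 0
    while i < n:
        if a[i] > p.spike_lower:
            i += 1
            continue
        j, spikes = i, 0
        while j < n:
            if a[j] <= p.spike_lower:
                j += 1
            elif a[j] < p.spike_upper and spikes < p.spikes_allowed:
                spikes += 1
                j += 1
            else:
                break
        if j - i >= p.min_interval:
            nonwear[i:j] = 1
        i = j + 1 if j < n and a[j] > p.spike_lower else j
    return MinuteLabels(series.start_time, nonwear)


def choi(
    series: EpochCountSeries, params: ChoiParams | None = None, axis: int = 0
) -> MinuteLabels:
    """Choi zero-count interval scan with flank-checked burst absorption.

    Zero-count runs may absorb a burst of up to ``interval_spikes``
    consecutive non-zero minutes provided the ``window`` minutes immediately
    upstream and downstream of the burst each contain at most
    ``window_spikes`` non-zero minutes.  Scanning is a single left-to-right
    pass; runs of total length >= ``min_interval`` are labelled non-wear.
    Flank windows truncated by the recording boundary are evaluated over the
    minutes that exist.
    """
    p = (params or ChoiParams()).validate()
    _check_minute_epochs(series)
    a = _activity(series, p.use_vmu, axis)
    n = a.shape[0]
    nz = a > 0
    cs = np.concatenate(([0], np.cumsum(nz)))

    def flank_quiet(burst_start: int, burst_end: int) -> bool:
        lo = max(0, burst_start - p.window)
        hi = min(n, burst_end + p.window)
        up = cs[burst_start] - cs[lo]
        down = cs[hi] - cs[burst_end]
        return up <= p.window_spikes and down <= p.window_spikes

    nonwear = np.zeros(n, dtype=np.uint8)
    i = 0
    while i < n:
        if nz[i]:
            i += 1
            continue
        j = i
        while j < n:
            if not nz[j]:
                j += 1
                continue
            b = j
            while b < n and nz[b]:
                b += 1
            if b - j <= p.interval_spikes and b < n and flank_quiet(j, b):
                j = b
            else:
                break
        if j - i >= p.min_interval:
            nonwear[i:j] = 1
        i = max(j, i + 1)
    return MinuteLabels(series.start_time, nonwear)
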