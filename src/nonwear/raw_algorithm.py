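"""Raw-acceleration non-wear detection (van Hees) with a sliding window.

Windows of ``min_interval`` minutes are evaluated at every multiple of
``window_step``; a window is flagged as non-wear when enough axes are
simultaneously quiet in standard deviation or in value range.  A minute is
non-wear iff at least one flagged window covers it (union rule), which keeps
boundary detection as sensitive as the overlapping windows allow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import G_TO_MG, MinuteLabels, TriaxialRecording

logger = logging.getLogger(__name__)


@dataclass
class HeesParams:
    """Thresholds in mg; window lengths in minutes.

    ``min_interval`` defaults to 60 min (the revised published value; the
    original study used 30) with a 15-min sliding step.
    """

    min_interval: int = 60
    std_threshold: float = 3.0
    std_min_axes: int = 2
    range_threshold: float = 50.0
    range_min_axes: int = 2
    window_step: int = 15

    def validate(self) -> "HeesParams":
        if not self.min_interval >= self.window_step >= 1:
            raise ValueError("need min_interval >= window_step >= 1")
        if self.std_threshold <= 0 or self.range_threshold <= 0:
            raise ValueError("thresholds must be positive")
        for axes in (self.std_min_axes, self.range_min_axes):
            if axes not in (1, 2, 3):
                raise ValueError("min_axes must be 1, 2 or 3")
        return self


def window_stats(
    rec: TriaxialRecording, start: int, length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis (population std, value range) in mg over a minute window.

    ``start`` and ``length`` are in whole minutes; the window must lie inside
    the recording.
    """
    data = rec.minute_slice(start, length).astype(np.float64)
    std = data.std(axis=0) * G_TO_MG
    rng = (data.max(axis=0) - data.min(axis=0)) * G_TO_MG
    return std, rng


def _minute_moments(rec: TriaxialRecording):
    """Per-minute sum, sum of squares, min and max per axis (float64)."""
    n_min, spm = rec.n_minutes, rec.samples_per_minute
    d = rec.data[: n_min * spm].astype(np.float64).reshape(n_min, spm, 3)
    return d.sum(axis=1), (d * d).sum(axis=1), d.min(axis=1), d.max(axis=1)


def hees(rec: TriaxialRecording, params: HeesParams | None = None) -> MinuteLabels:
    """Label each whole minute of ``rec`` via the union of flagged windows.

    A window is flagged when at least ``std_min_axes`` axes have a standard
    deviation below ``std_threshold`` *or* at least ``range_min_axes`` axes
    have a value range below ``range_threshold``.  A trailing stretch shorter
    than one window inherits labels only from earlier covering windows; a
    recording shorter than one window returns all-wear with a warning.
    """
    p = (params or HeesParams()).validate()
    n_min = rec.n_minutes
    nonwear = np.zeros(n_min, dtype=np.uint8)
    if n_min < p.min_interval:
        logger.warning(
            "recording (%d min) shorter than one %d-min window; returning all wear",
            n_min, p.min_interval,
        )
        return MinuteLabels(rec.start_time, nonwear)

    sums, sumsqs, mins, maxs = _minute_moments(rec)
    spm = rec.samples_per_minute
    n_w = p.min_interval * spm
    for s in range(0, n_min - p.min_interval + 1, p.window_step):
        e = s + p.min_interval
        tot = sums[s:e].sum(axis=0)
        totsq = sumsqs[s:e].sum(axis=0)
        var = np.maximum(totsq / n_w - (tot / n_w) ** 2, 0.0)
        std = np.sqrt(var) * G_TO_MG
        rng = (maxs[s:e].max(axis=0) - mins[s:e].min(axis=0)) * G_TO_MG
        if (std < p.std_threshold).sum() >= p.std_min_axes or (
            rng < p.range_threshold
        ).sum() >= p.range_min_axes:
            nonwear[s:e] = 1
    return MinuteLabels(rec.start_time, nonwear)
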