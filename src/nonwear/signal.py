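"""Deterministic signal transforms shared by all pipeline stages.

ENMO and VMU metrics, band-limited sample-rate conversion, dual-stream
synchronization, a documented surrogate raw-to-count algorithm, and epoch
aggregation.  The surrogate count algorithm replaces the proprietary
raw-to-count conversion shipped with commercial actigraphy software; its
magnitudes are internally consistent across the package but are not claimed to
match any vendor's count scale.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
import scipy.signal
from scipy.ndimage import uniform_filter1d

from .core import EpochCountSeries, TriaxialRecording

logger = logging.getLogger(__name__)

#: deadband of the surrogate count algorithm, in g (10 mg)
COUNT_DEADBAND_G = 0.010
#: scale factor from summed rectified acceleration (g) to counts
COUNT_SCALE = 100.0


def compute_enmo(rec: TriaxialRecording) -> np.ndarray:
    """Euclidean norm minus one, clamped at zero.

    ENMO = max(sqrt(x² + y² + z²) − 1, 0) per sample, in g.  A motionless,
    perfectly calibrated device reads ENMO 0 regardless of orientation.
    """
    data = np.asarray(rec.data, dtype=np.float64)
    finite = np.isfinite(data).all(axis=1)
    if not finite.all():
        idx = int(np.flatnonzero(~finite)[0])
        raise ValueError(f"non-finite acceleration at sample index {idx}")
    norm = np.sqrt((data * data).sum(axis=1))
    return np.maximum(norm - 1.0, 0.0)


def compute_vmu(counts) -> np.ndarray | float:
    """Vector magnitude of per-epoch axis counts: sqrt(cx² + cy² + cz²).

    Accepts a single ``(3,)`` triple or an ``(n, 3)`` array.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if c.ndim == 1:
        return float(np.sqrt((c * c).sum()))
    return np.sqrt((c * c).sum(axis=1))


def resample(rec: TriaxialRecording, target_rate: float) -> TriaxialRecording:
    """Band-limited sample-rate conversion (polyphase sinc filtering).

    Content below the target Nyquist frequency is preserved; the duration is
    preserved to within one sample period.  Linear-trend padding keeps a
    constant (gravity-offset) signal constant through the edges.
    """
    if not target_rate > 0:
        raise ValueError("target_rate must be positive")
    if rec.n_samples == 0:
        raise ValueError("cannot resample an empty recording")
    if target_rate == rec.rate:
        return TriaxialRecording(rec.start_time, rec.rate, rec.data.copy())
    frac = Fraction(target_rate / rec.rate).limit_denominator(1000)
    out = scipy.signal.resample_poly(
        np.asarray(rec.data, dtype=np.float64), frac.numerator, frac.denominator,
        axis=0, padtype="line",
    )
    return TriaxialRecording(rec.start_time, target_rate, out)


def synchronize(
    a: TriaxialRecording, b: TriaxialRecording
) -> tuple[TriaxialRecording, TriaxialRecording]:
    """Trim two recordings to their overlapping span at a common rate.

    The common rate is the lower of the two (the faster stream is resampled
    down); both outputs start at the same timestamp and have equal length.
    """
    common = min(a.rate, b.rate)
    a, b = resample(a, common), resample(b, common)
    start = max(a.start_time, b.start_time)
    end = min(a.end_time, b.end_time)
    n = int(np.floor((end - start).total_seconds() * common))
    if n <= 0:
        raise ValueError("recordings do not overlap in time")
    out = []
    for rec in (a, b):
        i = int(round((start - rec.start_time).total_seconds() * common))
        out.append(TriaxialRecording(start, common, rec.data[i : i + n].copy()))
    return out[0], out[1]


def surrogate_counts(
    rec: TriaxialRecording, epoch_length: float = 10.0
) -> EpochCountSeries:
    """Documented surrogate raw-to-count conversion.

    Per axis: subtract a 1-s centered moving average (gravity removal),
    rectify, zero everything below a 10 mg deadband, sum per epoch, scale by
    100 and round to integer counts.  Stillness maps to zero counts.  Note
    that an abrupt offset step leaks a residual of about half the step height
    into the 1-s neighbourhood of the boundary, so offset changes are only
    count-free when the step is below twice the deadband.
    """
    spe = int(round(epoch_length * rec.rate))
    if spe <= 0 or rec.n_samples < spe:
        raise ValueError("recording shorter than one epoch")
    data = np.asarray(rec.data, dtype=np.float64)
    w = max(int(round(rec.rate)), 1)
    gravity = uniform_filter1d(data, size=w, axis=0, mode="nearest")
    rect = np.abs(data - gravity)
    rect[rect < COUNT_DEADBAND_G] = 0.0
    n_epochs = rec.n_samples // spe
    if rec.n_samples % spe:
        logger.warning(
            "dropping trailing partial epoch of %d samples", rec.n_samples % spe
        )
    sums = rect[: n_epochs * spe].reshape(n_epochs, spe, 3).sum(axis=1)
    counts = np.rint(sums * COUNT_SCALE).astype(np.int64)
    return EpochCountSeries(rec.start_time, counts, epoch_length)


def sum_epochs(series: EpochCountSeries, factor: int = 6) -> EpochCountSeries:
    """Aggregate count epochs by summation (e.g. 10-s epochs → 60-s epochs)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n = len(series) // factor
    if len(series) % factor:
        logger.warning(
            "dropping trailing partial group of %d epochs", len(series) % factor
        )
    counts = series.counts[: n * factor].reshape(n, factor, 3).sum(axis=1)
    return EpochCountSeries(series.start_time, counts, series.epoch_length * factor)
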