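"""Minute-resolution ground-truth construction from dual-device data.

The hip stream alone cannot distinguish true non-wear from worn stillness
(sleep, sedentary time): both are quiescent minute-by-minute.  This module
implements the dual-device resolution of that ambiguity:

1. ``detect_candidates`` — find maximal runs of quiescent minutes (per-axis
   1-min standard deviation at or below 4 mg on all three axes) on the hip
   stream; these are *candidate* non-wear episodes;
2. ``extract_features`` — characterize each candidate with 41 features drawn
   from the hip ENMO, the chest ENMO and the chest heart-rate channel,
   including an inter-device dynamic-time-warping lower bound;
3. ``train_episode_classifier`` / ``label_episodes`` — a pluggable binary
   classifier (default: standardize, degree-2 polynomial expansion,
   regularized logistic regression) separates true non-wear from worn
   stillness;
4. ``episodes_to_minutes`` — expand the classified episode table back onto
   the minute grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

from .core import G_TO_MG, TriaxialRecording, runs_of_ones

#: candidate quiescence threshold from visual calibration against the
#: accelerometer noise floor, in mg
CANDIDATE_STD_THRESHOLD_MG = 4.0

#: default Sakoe-Chiba band for the DTW lower bound, in seconds
DTW_BAND_SECONDS = 10.0

_STAT_NAMES = (
    "mean", "std", "min", "max", "kurtosis", "snr", "mode", "median", "range",
    "variance",
)
_STREAMS = ("hip_enmo", "chest_enmo", "heart_rate")

EPISODE_COLUMNS = ["start_minute", "end_minute", "label", "scenario"]


def feature_names() -> list[str]:
    """The 41 feature names: 10 statistics x 3 streams, the inter-device DTW
    lower bound, and the hip-chest difference of each ENMO statistic."""
    names = [f"{stream}_{stat}" for stream in _STREAMS for stat in _STAT_NAMES]
    names.append("dtw_lower_bound")
    names += [f"diff_{stat}" for stat in _STAT_NAMES]
    return names


def detect_candidates(
    rec: TriaxialRecording, std_threshold: float = CANDIDATE_STD_THRESHOLD_MG
) -> pd.DataFrame:
    """Candidate non-wear episodes on a raw stream.

    A minute is quiescent iff all three axes have a 1-minute population
    standard deviation at or below ``std_threshold`` (mg); maximal runs of
    quiescent minutes become candidate episodes.
    """
    n_min = rec.n_minutes
    if n_min < 1:
        raise ValueError("recording must cover at least one minute")
    spm = rec.samples_per_minute
    d = rec.data[: n_min * spm].astype(np.float64).reshape(n_min, spm, 3)
    std_mg = d.std(axis=1) * G_TO_MG
    quiescent = (std_mg <= std_threshold).all(axis=1)
    rows = [
        (s, e, "candidate", None) for s, e in runs_of_ones(quiescent)
    ]
    return pd.DataFrame(rows, columns=EPISODE_COLUMNS)


def _stats(x: np.ndarray) -> dict[str, float]:
    """The ten per-stream statistics.

    Conventions for degenerate inputs (the source descriptions fix none of
    them): the signal-to-noise ratio (mean/std) and the excess kurtosis of a
    constant stream are both 0; the mode is taken over values rounded to
    3 decimals (mg resolution for ENMO in g), smallest value winning ties.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot compute statistics of an empty stream")
    std = float(x.std())
    rounded = np.round(x, 3)
    values, counts = np.unique(rounded, return_counts=True)
    mode = float(values[np.argmax(counts)])
    return {
        "mean": float(x.mean()),
        "std": std,
        "min": float(x.min()),
        "max": float(x.max()),
        "kurtosis": float(scipy.stats.kurtosis(x, fisher=True)) if std > 0 else 0.0,
        "snr": float(x.mean() / std) if std > 0 else 0.0,
        "mode": mode,
        "median": float(np.median(x)),
        "range": float(x.max() - x.min()),
        "variance": std * std,
    }


def dtw_lower_bound(a: np.ndarray, b: np.ndarray, band: int) -> float:
    """Keogh envelope lower bound on the band-constrained DTW distance.

    The exceedance of ``b`` outside the running [min, max] envelope of ``a``
    over a Sakoe-Chiba band of ``+- band`` samples is squared and summed; the
    result is symmetrized as ``max(LB(a, b), LB(b, a))``.  The value is a
    lower bound on the DTW distance (sum of squared local costs) restricted
    to warping paths within the same band, and is 0 whenever the sequences
    coincide or one lies inside the other's envelope.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("sequences must be one-dimensional and of equal length")
    if band < 0:
        raise ValueError("band must be >= 0")

    def one_sided(ref: np.ndarray, query: np.ndarray) -> float:
        size = 2 * band + 1
        upper = maximum_filter1d(ref, size=size, mode="nearest")
        lower = minimum_filter1d(ref, size=size, mode="nearest")
        exceed = np.where(
            query > upper, query - upper, np.where(query < lower, lower - query, 0.0)
        )
        return float((exceed * exceed).sum())

    return max(one_sided(a, b), one_sided(b, a))


def extract_features(
    start_minute: int,
    end_minute: int,
    hip_enmo: np.ndarray,
    chest_enmo: np.ndarray,
    heart_rate: np.ndarray,
    enmo_rate: float,
    hr_rate: float = 1.0,
    dtw_band_seconds: float = DTW_BAND_SECONDS,
) -> pd.Series:
    """The 41 features of one candidate episode.

    ``hip_enmo`` and ``chest_enmo`` must be synchronized to the same rate and
    start; ``heart_rate`` is aligned to the same start at ``hr_rate``.  The
    episode interval is half-open in minutes.
    """
    if end_minute <= start_minute:
        raise ValueError("episode must span at least one minute")
    values: dict[str, float] = {}
    streams = {}
    for name, series, rate in (
        ("hip_enmo", hip_enmo, enmo_rate),
        ("chest_enmo", chest_enmo, enmo_rate),
        ("heart_rate", heart_rate, hr_rate),
    ):
        i = int(round(start_minute * 60 * rate))
        j = int(round(end_minute * 60 * rate))
        if j > len(series):
            raise ValueError(f"episode extends past the end of the {name} stream")
        streams[name] = np.asarray(series[i:j], dtype=np.float64)
        for stat, v in _stats(streams[name]).items():
            values[f"{name}_{stat}"] = v
    band = int(round(dtw_band_seconds * enmo_rate))
    values["dtw_lower_bound"] = dtw_lower_bound(
        streams["hip_enmo"], streams["chest_enmo"], band
    )
    for stat in _STAT_NAMES:
        values[f"diff_{stat}"] = (
            values[f"hip_enmo_{stat}"] - values[f"chest_enmo_{stat}"]
        )
    out = pd.Series(values).reindex(feature_names())
    if not np.isfinite(out.to_numpy()).all():
        bad = out.index[~np.isfinite(out.to_numpy())].tolist()
        raise ValueError(f"non-finite features: {bad}")
    return out


def episode_feature_table(
    episodes: pd.DataFrame,
    hip: TriaxialRecording,
    chest: TriaxialRecording,
    heart_rate: pd.Series,
    dtw_band_seconds: float = DTW_BAND_SECONDS,
) -> pd.DataFrame:
    """Features for every episode row, from raw dual-device streams.

    Synchronizes the two recordings to their common rate and span, computes
    per-sample ENMO on each, aligns the heart-rate series, and extracts the
    41 features per episode.  Episode minute indices refer to the
    synchronized start (for generator output both devices start together, so
    they coincide with recording minutes).
    """
    from .signal import compute_enmo, synchronize

    hip_s, chest_s = synchronize(hip, chest)
    hip_enmo = compute_enmo(hip_s)
    chest_enmo = compute_enmo(chest_s)
    hr_start_lag = (hip_s.start_time - heart_rate.index[0]).total_seconds()
    hr = heart_rate.to_numpy()[int(round(hr_start_lag)) :]
    rows = [
        extract_features(
            int(row.start_minute), int(row.end_minute), hip_enmo, chest_enmo, hr,
            enmo_rate=hip_s.rate, dtw_band_seconds=dtw_band_seconds,
        )
        for row in episodes.itertuples()
    ]
    if not rows:
        return pd.DataFrame(columns=feature_names())
    return pd.DataFrame(rows).reset_index(drop=True)


def build_episode_training_set(
    n_wear: int = 200,
    n_nonwear: int = 200,
    config=None,
    seed: int | np.random.Generator | None = None,
    both_off_frac: float = 0.2,
    duration_cuts: tuple[int, int] = (3, 60),
) -> tuple[pd.DataFrame, np.ndarray]:
    """A labelled feature table of simulated candidate episodes.

    Wear-class episodes follow the worn-but-still scenario; non-wear-class
    episodes mix hip-off and (a ``both_off_frac`` share of) both-off
    scenarios.  Durations are drawn from the short-episode family.  Returns
    ``(features, labels)`` with 1 = true non-wear.
    """
    from .signal import compute_enmo, synchronize
    from .simulate import SimulationConfig, sample_episode_durations, simulate_candidate_episode

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = config or SimulationConfig()
    n_both = int(round(both_off_frac * n_nonwear))
    scenarios = (
        ["worn-both"] * n_wear + ["hip-off"] * (n_nonwear - n_both) + ["both-off"] * n_both
    )
    lo, hi = duration_cuts
    mean = float(np.clip(cfg.short_duration_mean, lo, hi - 1))
    durations = sample_episode_durations(
        len(scenarios), mean, cfg.short_duration_sd, lo, hi, seed=rng
    )
    rows, labels = [], []
    for scenario, dur in zip(scenarios, durations):
        hip, chest, hr = simulate_candidate_episode(scenario, int(dur), cfg, seed=rng)
        hip_s, chest_s = synchronize(hip, chest)
        rows.append(
            extract_features(
                0, int(dur), compute_enmo(hip_s), compute_enmo(chest_s),
                hr.to_numpy(), enmo_rate=hip_s.rate,
            )
        )
        labels.append(0 if scenario == "worn-both" else 1)
    return pd.DataFrame(rows).reset_index(drop=True), np.asarray(labels)


def make_episode_classifier(seed: int | None = None) -> Pipeline:
    """Reference episode classifier: standardize -> degree-2 polynomial
    expansion -> regularized logistic regression.

    Any binary classifier accepting the feature table can be substituted; the
    scaler and expansion are part of the fitted pipeline, so train-time
    preprocessing is replayed identically at prediction time.
    """
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("poly", PolynomialFeatures(degree=2, include_bias=False)),
            ("clf", LogisticRegression(max_iter=5000, C=1.0, random_state=seed)),
        ]
    )


def train_episode_classifier(
    features: pd.DataFrame, labels: np.ndarray, seed: int | None = None
) -> Pipeline:
    """Fit the reference classifier; ``labels`` use 1 = true non-wear."""
    model = make_episode_classifier(seed)
    model.fit(features.to_numpy(), np.asarray(labels).astype(int))
    return model


def label_episodes(
    episodes: pd.DataFrame, features: pd.DataFrame, model
) -> pd.DataFrame:
    """Classify candidate episodes as true non-wear or wear.

    Returns a copy of ``episodes`` with ``label`` set to ``true-nonwear`` or
    ``wear``, plus a ``review`` flag on episodes longer than 120 minutes that
    were classified as wear — long quiescent candidates are almost always
    true non-wear, so such rows deserve manual inspection rather than silent
    acceptance.
    """
    out = episodes.copy().reset_index(drop=True)
    if len(out) == 0:
        out["review"] = pd.Series(dtype=bool)
        return out
    if len(features) != len(out):
        raise ValueError("features and episodes tables must have equal length")
    x = features.reindex(columns=feature_names()).to_numpy()
    if not np.isfinite(x).all():
        raise ValueError("feature table contains non-finite or missing values")
    pred = np.asarray(model.predict(x)).astype(int)
    out["label"] = np.where(pred == 1, "true-nonwear", "wear")
    duration = out["end_minute"] - out["start_minute"]
    out["review"] = (duration > 120) & (out["label"] == "wear")
    return out


def episodes_to_minutes(
    episodes: pd.DataFrame,
    n_minutes: int,
    positive_labels: tuple[str, ...] = ("true-nonwear",),
) -> np.ndarray:
    """Expand an episode table to a per-minute 0/1 vector (1 = non-wear).

    Episodes must be disjoint and lie within ``[0, n_minutes)``.
    """
    values = np.zeros(n_minutes, dtype=np.uint8)
    covered = np.zeros(n_minutes, dtype=bool)
    for row in episodes.itertuples():
        s, e = int(row.start_minute), int(row.end_minute)
        if s < 0 or e > n_minutes or s >= e:
            raise ValueError(f"episode [{s}, {e}) outside [0, {n_minutes})")
        if covered[s:e].any():
            raise ValueError(f"episode [{s}, {e}) overlaps another episode")
        covered[s:e] = True
        if row.label in positive_labels:
            values[s:e] = 1
    return values
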