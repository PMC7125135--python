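"""Synthetic dual-device recordings with known minute-level ground truth.

The generator emulates the statistical structure of free-living dual-device
actigraphy: a hip-worn device (100 Hz) and a chest-worn device (32 Hz) with a
1 Hz heart-rate channel, recorded simultaneously over a day.  Wear time
alternates movement bursts with sedentary stretches; sleep is modelled as
worn stillness with occasional posture changes (turnovers); true non-wear
episodes are planted on the hip stream as flat signal while the chest device
keeps recording activity and heart rate (or, rarely, both devices are off and
the heart-rate channel goes silent).

Short non-wear episodes (< 60 min) are drawn from a right-skewed log-normal
family (mean 11 min, SD 9.9) and start in the morning window 06:00-08:00;
long episodes (>= 60 min) from a broad truncated normal (mean 355 min,
SD 204) starting in the night window 00:00-08:00.

A key feature of the signal model is a slow orientation drift of the gravity
vector while a device is worn.  Within one minute the drift is far below the
4 mg candidate-quiescence threshold, but across a 60-minute window it moves
the per-axis gravity projection by tens of mg.  This reproduces the essential
asymmetry of real data: worn stillness (sleep, sedentary time) is quiescent
minute-by-minute yet not flat over an hour, whereas a device lying on a table
is flat on every time scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

from .core import G_TO_MG, MinuteLabels, TriaxialRecording, runs_of_ones

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "sample_episode_durations",
    "simulate_dual_recording",
    "simulate_candidate_episode",
    "evaluation_config",
]

_PLACEMENT_ATTEMPTS = 1000


def _clock_to_minute(clock: str) -> int:
    h, m = clock.split(":")
    return int(h) * 60 + int(m)


@dataclass
class SimulationConfig:
    """Parameters of one simulated dual-device day.

    Durations are in the units stated per field; noise levels are in mg and
    are converted internally.  ``sedentary_noise_sd`` defaults to 2 mg —
    deliberately below the 4 mg candidate threshold, so that worn stillness
    produces candidate non-wear episodes (the "worn, not true non-wear"
    scenario); set it above 4 mg to suppress that behaviour.
    """

    duration_hours: float = 24.0
    start_time: str = "2020-01-06 00:00:00"
    hip_rate: float = 100.0
    chest_rate: float = 32.0

    n_short_episodes: int = 2
    n_long_episodes: int = 0
    short_duration_mean: float = 11.0  # minutes
    short_duration_sd: float = 9.9
    long_duration_mean: float = 355.0
    long_duration_sd: float = 204.1
    short_cuts: tuple[int, int] = (1, 60)  # [min, max) minutes
    long_cuts: tuple[int, int] = (60, 720)
    short_peak_window: tuple[str, str] = ("06:00", "08:00")
    long_peak_window: tuple[str, str] = ("00:00", "08:00")
    p_both_off: float = 0.1

    wear_burst_amplitude: float = 0.3  # g
    sedentary_noise_sd: float = 2.0  # mg
    nonwear_noise_sd: float = 1.0  # mg
    hr_mean: float = 70.0  # bpm

    sleep_start: str = "23:00"
    sleep_end: str = "07:00"
    sedentary_bout_mean: float = 30.0  # minutes
    active_bout_mean: float = 10.0  # minutes
    turnover_interval_mean: float = 20.0  # minutes between sleep posture changes
    gentle_turnover_frac: float = 0.6  # fraction of turnovers that are gentle
    gentle_amplitude: float = 4.0  # mg; near the count deadband -> small count values
    drift_deg_per_min: float = 0.2  # orientation random-walk step SD

    seed: int | None = None

    @property
    def n_minutes(self) -> int:
        return int(round(self.duration_hours * 60))

    def validate(self) -> "SimulationConfig":
        if self.duration_hours <= 0:
            raise ValueError("duration_hours must be positive")
        for rate in (self.hip_rate, self.chest_rate):
            if rate <= 0:
                raise ValueError("sample rates must be positive")
        if self.n_short_episodes < 0 or self.n_long_episodes < 0:
            raise ValueError("episode counts must be non-negative")
        for lo, hi in (self.short_cuts, self.long_cuts):
            if not 0 <= lo < hi:
                raise ValueError("duration cuts must satisfy 0 <= min < max")
        if not 0 <= self.p_both_off <= 1:
            raise ValueError("p_both_off must be a probability")
        if self.sedentary_noise_sd <= 0 or self.nonwear_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")
        # crude feasibility bound; exact placement is rejection-sampled later
        worst = (
            self.n_short_episodes * (self.short_cuts[1] - 1)
            + self.n_long_episodes * (self.long_cuts[1] - 1)
        )
        if self.n_minutes <= min(
            worst,
            self.n_short_episodes * self.short_cuts[0]
            + self.n_long_episodes * self.long_cuts[0],
        ):
            raise ValueError("planted episodes cannot fit inside the recording")
        return self


@dataclass
class GroundTruth:
    """Minute labels plus the episode table that generated them.

    ``episodes`` rows carry half-open minute intervals, ``label``
    ('true-nonwear') and ``scenario`` ('hip-off' or 'both-off').
    """

    minute_labels: MinuteLabels
    episodes: pd.DataFrame

    def __post_init__(self) -> None:
        ep = self.episodes.sort_values("start_minute").reset_index(drop=True)
        if len(ep):
            if (ep["end_minute"] <= ep["start_minute"]).any():
                raise ValueError("episodes must satisfy start < end")
            if (ep["start_minute"].values[1:] < ep["end_minute"].values[:-1]).any():
                raise ValueError("episodes must be disjoint")
        self.episodes = ep
        mask = np.zeros(len(self.minute_labels), dtype=bool)
        for s, e in zip(ep["start_minute"], ep["end_minute"]):
            mask[s:e] = True
        if not np.array_equal(mask, self.minute_labels.values.astype(bool)):
            raise ValueError("episode union does not match the positive minutes")


def sample_episode_durations(
    n: int,
    mean: float,
    sd: float,
    min_cut: int,
    max_cut: int,
    seed: int | np.random.Generator | None = None,
    family: str = "lognormal",
) -> np.ndarray:
    """Integer episode durations from a truncated distribution family.

    The continuous family (log-normal for the right-skewed short episodes,
    normal for the broad long episodes) is moment-matched to ``mean``/``sd``,
    discretized to integer minutes ``k`` in ``[min_cut, max_cut)`` with
    probability proportional to ``F(k+1) - F(k)``, and sampled exactly from
    those renormalized probabilities (no rejection loops, so degenerate
    supports such as ``[10, 11)`` are handled).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if mean <= 0:
        raise ValueError("mean must be positive")
    if not min_cut <= mean < max_cut:
        raise ValueError(
            f"mean {mean} outside the duration support [{min_cut}, {max_cut})"
        )
    if n == 0:
        return np.zeros(0, dtype=int)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = np.arange(min_cut, max_cut)
    if family == "lognormal":
        sigma2 = np.log1p((sd / mean) ** 2)
        dist = scipy.stats.lognorm(
            s=np.sqrt(sigma2), scale=mean * np.exp(-sigma2 / 2)
        )
    elif family == "normal":
        dist = scipy.stats.norm(loc=mean, scale=sd)
    else:
        raise ValueError(f"unknown duration family {family!r}")
    p = dist.cdf(k + 1) - dist.cdf(k)
    total = p.sum()
    if total <= 0:
        raise ValueError("distribution places no mass on the duration support")
    return rng.choice(k, size=n, p=p / total)


def duration_distribution_mean(
    mean: float, sd: float, min_cut: int, max_cut: int, family: str = "lognormal"
) -> float:
    """Expected value of the discretized truncated duration distribution."""
    k = np.arange(min_cut, max_cut)
    if family == "lognormal":
        sigma2 = np.log1p((sd / mean) ** 2)
        dist = scipy.stats.lognorm(s=np.sqrt(sigma2), scale=mean * np.exp(-sigma2 / 2))
    else:
        dist = scipy.stats.norm(loc=mean, scale=sd)
    p = dist.cdf(k + 1) - dist.cdf(k)
    p = p / p.sum()
    return float((k * p).sum())


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------


def _bandlimited_noise(rng: np.random.Generator, n_sec: float, coarse_fs: float = 8.0):
    """Unit-variance 0.5-3 Hz noise sampled at ``coarse_fs``, with its time grid."""
    n = int(round(n_sec * coarse_fs))
    white = rng.standard_normal((n, 3))
    sos = scipy.signal.butter(2, [0.5, 3.0], btype="bandpass", fs=coarse_fs, output="sos")
    bl = scipy.signal.sosfilt(sos, white, axis=0)
    sd = bl.std(axis=0)
    sd[sd == 0] = 1.0
    return bl / sd, np.arange(n) / coarse_fs


def _gen_stream(
    rng: np.random.Generator,
    n_min: int,
    rate: float,
    off_min: np.ndarray,
    amp_env_sec: np.ndarray,
    cfg: SimulationConfig,
) -> np.ndarray:
    """One device's (n_samples, 3) signal in g.

    ``off_min`` marks minutes during which the device is not worn (frozen
    orientation, low noise floor, no movement); ``amp_env_sec`` is a 1 Hz
    movement-amplitude envelope in g (0 = still).
    """
    spm = int(round(rate * 60))
    n_samples = n_min * spm
    step = np.deg2rad(cfg.drift_deg_per_min)

    # Worn orientation drifts as a random walk plus two slow incommensurate
    # oscillations (posture settling, breathing-scale sway).  Both are built
    # from per-minute angle increments that are zeroed while the device is
    # off, so non-wear freezes the orientation without boundary jumps.  The
    # base tilt stays away from the coordinate poles so that every axis sees
    # first-order motion: within one minute the drift is ~1 mg-scale, across
    # an hour it moves each axis by tens of mg.
    k = np.arange(n_min + 1, dtype=np.float64)
    amp_t, per_t = np.deg2rad(4.0), 35.0
    amp_p, per_p = np.deg2rad(5.0), 45.0
    osc_t = amp_t * np.sin(2 * np.pi * k / per_t + rng.uniform(0, 2 * np.pi))
    osc_p = amp_p * np.sin(2 * np.pi * k / per_p + rng.uniform(0, 2 * np.pi))
    dtheta = rng.normal(0.0, step, n_min) + np.diff(osc_t)
    dphi = rng.normal(0.0, step, n_min) + np.diff(osc_p)
    dtheta[off_min] = 0.0
    dphi[off_min] = 0.0
    theta = np.concatenate(([rng.uniform(np.deg2rad(35), np.deg2rad(55))], dtheta)).cumsum()
    phi = np.concatenate(([rng.uniform(0.0, 2 * np.pi)], dphi)).cumsum()
    knots = np.column_stack(
        (np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta))
    ).astype(np.float32)

    # broadcastable linear interpolation between minute knots; consecutive
    # knots are unit vectors ~0.3 deg apart, so the interpolated norm deviates
    # from 1 by < 4e-6 g and renormalization is unnecessary
    frac = (np.arange(spm, dtype=np.float32) / spm)[None, :, None]
    out = (knots[:-1, None, :] + frac * (knots[1:] - knots[:-1])[:, None, :]).reshape(
        n_samples, 3
    )

    # white measurement noise, wear vs non-wear floor
    sd_min = (
        np.where(off_min, cfg.nonwear_noise_sd, cfg.sedentary_noise_sd) / G_TO_MG
    ).astype(np.float32)
    noise = rng.standard_normal((n_samples, 3), dtype=np.float32)
    noise *= np.repeat(sd_min, spm)[:, None]
    out += noise
    del noise

    # band-limited movement under the 1 Hz amplitude envelope
    if amp_env_sec.any():
        bl, t_coarse = _bandlimited_noise(rng, n_min * 60)
        t_sec = np.arange(n_samples) / rate
        per_sec = int(round(rate))
        env_amp = np.repeat(amp_env_sec.astype(np.float32), per_sec)[:n_samples]
        for ax in range(3):
            out[:, ax] += np.interp(t_sec, t_coarse, bl[:, ax]).astype(np.float32) * env_amp
    return out


def _alternating_bouts(
    rng: np.random.Generator, length: int, mean_a: float, mean_b: float
) -> np.ndarray:
    """Boolean mask alternating True bouts (mean ``mean_a``) with False bouts."""
    mask = np.zeros(length, dtype=bool)
    pos, state = 0, bool(rng.integers(0, 2))
    while pos < length:
        mean = mean_a if state else mean_b
        dur = max(1, int(round(rng.exponential(mean))))
        if state:
            mask[pos : pos + dur] = True
        pos += dur
        state = not state
    return mask


def _turnover_envelope(
    rng: np.random.Generator, sleep_min: np.ndarray, cfg: SimulationConfig
) -> np.ndarray:
    """1 Hz movement-amplitude envelope (g) of posture changes within sleep.

    Most turnovers are gentle — their amplitude sits near the surrogate count
    deadband, so they are plainly visible in the raw signal but register only
    small count values (the "artificial movement" spikes that count-based
    run scanners must tolerate).  The rest are full-amplitude movements that
    produce large counts.
    """
    n_sec = sleep_min.size * 60
    env = np.zeros(n_sec, dtype=np.float32)
    strong = np.float32(cfg.wear_burst_amplitude)
    gentle = np.float32(cfg.gentle_amplitude / G_TO_MG)
    for s, e in runs_of_ones(sleep_min):
        t = float(s * 60) + rng.exponential(cfg.turnover_interval_mean * 60)
        while t < e * 60:
            dur = rng.uniform(10.0, 40.0)
            amp = gentle if rng.random() < cfg.gentle_turnover_frac else strong
            env[int(t) : int(min(t + dur, e * 60))] = amp
            t += dur + rng.exponential(cfg.turnover_interval_mean * 60)
    return env


def _minute_clock(cfg: SimulationConfig) -> np.ndarray:
    start = pd.Timestamp(cfg.start_time)
    offset = start.hour * 60 + start.minute
    return (offset + np.arange(cfg.n_minutes)) % 1440


def _clock_window_mask(clock: np.ndarray, window: tuple[str, str]) -> np.ndarray:
    lo, hi = (_clock_to_minute(w) for w in window)
    if lo <= hi:
        return (clock >= lo) & (clock < hi)
    return (clock >= lo) | (clock < hi)


def _place_episodes(
    rng: np.random.Generator, cfg: SimulationConfig
) -> pd.DataFrame:
    """Plant short and long episodes with rejection-sampled start minutes."""
    clock = _minute_clock(cfg)
    occupied = np.zeros(cfg.n_minutes, dtype=bool)
    rows = []
    groups = [
        (
            cfg.n_short_episodes,
            (cfg.short_duration_mean, cfg.short_duration_sd, *cfg.short_cuts),
            "lognormal",
            cfg.short_peak_window,
        ),
        (
            cfg.n_long_episodes,
            (cfg.long_duration_mean, cfg.long_duration_sd, *cfg.long_cuts),
            "normal",
            cfg.long_peak_window,
        ),
    ]
    for n_episodes, dist, family, window in groups:
        candidates = np.flatnonzero(_clock_window_mask(clock, window))
        if n_episodes and candidates.size == 0:
            raise ValueError(f"peak window {window} not covered by the recording")
        durations = sample_episode_durations(n_episodes, *dist, seed=rng, family=family)
        for dur in durations:
            dur = int(dur)
            for attempt in range(_PLACEMENT_ATTEMPTS):
                s = int(rng.choice(candidates))
                e = s + dur
                if e <= cfg.n_minutes and not occupied[s:e].any():
                    occupied[s:e] = True
                    scenario = "both-off" if rng.random() < cfg.p_both_off else "hip-off"
                    rows.append((s, e, "true-nonwear", scenario))
                    break
                if attempt % 50 == 49:
                    # start-time rejection alone can deadlock (e.g. a long
                    # episode that cannot avoid already-placed short ones);
                    # redraw the duration from its family and keep trying
                    dur = int(
                        sample_episode_durations(1, *dist, seed=rng, family=family)[0]
                    )
            else:
                raise ValueError(
                    f"could not place a {dur}-min episode without overlap "
                    f"after {_PLACEMENT_ATTEMPTS} attempts"
                )
    return pd.DataFrame(
        rows, columns=["start_minute", "end_minute", "label", "scenario"]
    ).sort_values("start_minute").reset_index(drop=True)


def _heart_rate(
    rng: np.random.Generator, n_sec: int, mean: float, off_sec: np.ndarray
) -> np.ndarray:
    """1 Hz heart rate: AR(1) wander around ``mean``; 0 bpm while unworn."""
    rho, sd = 0.995, 8.0
    eps = rng.standard_normal(n_sec) * sd * np.sqrt(1 - rho**2)
    hr = mean + scipy.signal.lfilter([1.0], [1.0, -rho], eps)
    hr = np.clip(hr, 35.0, 200.0)
    hr[off_sec] = 0.0
    return hr


def simulate_dual_recording(
    config: SimulationConfig,
) -> tuple[TriaxialRecording, TriaxialRecording, pd.Series, GroundTruth]:
    """Generate one synthetic dual-device day.

    Returns the hip recording, the chest recording, the 1 Hz heart-rate
    series (0 bpm encodes "no wearer"), and the minute-level ground truth.
    Identical configs (including ``seed``) produce bit-identical output.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    n_min = cfg.n_minutes
    n_sec = n_min * 60
    clock = _minute_clock(cfg)

    episodes = _place_episodes(rng, cfg)
    hip_off = np.zeros(n_min, dtype=bool)
    chest_off = np.zeros(n_min, dtype=bool)
    for _, row in episodes.iterrows():
        hip_off[row.start_minute : row.end_minute] = True
        if row.scenario == "both-off":
            chest_off[row.start_minute : row.end_minute] = True

    sleep = _clock_window_mask(clock, (cfg.sleep_start, cfg.sleep_end))
    awake = ~sleep
    active = _alternating_bouts(
        rng, n_min, cfg.active_bout_mean, cfg.sedentary_bout_mean
    ) & awake

    turnover = _turnover_envelope(rng, sleep, cfg)
    # chest keeps seeing intermittent movement while only the hip is off
    chest_extra = np.zeros(n_min, dtype=bool)
    only_hip_off = hip_off & ~chest_off
    chest_extra[only_hip_off] = rng.random(int(only_hip_off.sum())) < 0.3

    def sec(mask_min: np.ndarray) -> np.ndarray:
        return np.repeat(mask_min, 60)

    burst_g = np.float32(cfg.wear_burst_amplitude)

    def amp_env(active_min: np.ndarray, off: np.ndarray) -> np.ndarray:
        env = np.maximum(sec(active_min).astype(np.float32) * burst_g, turnover)
        env[sec(off)] = 0.0
        return env

    env_hip = amp_env(active, hip_off)
    env_chest = amp_env(active | chest_extra, chest_off)

    hip = TriaxialRecording(
        cfg.start_time, cfg.hip_rate, _gen_stream(rng, n_min, cfg.hip_rate, hip_off, env_hip, cfg)
    )
    chest = TriaxialRecording(
        cfg.start_time, cfg.chest_rate,
        _gen_stream(rng, n_min, cfg.chest_rate, chest_off, env_chest, cfg),
    )
    hr = _heart_rate(rng, n_sec, cfg.hr_mean, sec(chest_off))
    hr_index = pd.date_range(cfg.start_time, periods=n_sec, freq="1s")
    heart_rate = pd.Series(hr, index=hr_index, name="heart_rate_bpm")

    truth = GroundTruth(
        MinuteLabels(cfg.start_time, hip_off.astype(np.uint8)), episodes
    )
    return hip, chest, heart_rate, truth


def simulate_candidate_episode(
    scenario: str,
    duration_min: int,
    config: SimulationConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[TriaxialRecording, TriaxialRecording, pd.Series]:
    """A standalone candidate episode under one of the dual-device scenarios.

    ``scenario`` is one of ``worn-both`` (both devices worn but still — sleep
    or sedentary time), ``hip-off`` (hip unworn, chest worn and moving, heart
    rate present) or ``both-off`` (both unworn, heart rate silent).  Used to
    build labelled training sets for the episode classifier without
    simulating full days.
    """
    cfg = (config or SimulationConfig()).validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if duration_min < 1:
        raise ValueError("duration_min must be >= 1")
    if scenario not in ("worn-both", "hip-off", "both-off"):
        raise ValueError(f"unknown scenario {scenario!r}")
    n_min = int(duration_min)
    n_sec = n_min * 60
    zeros_min = np.zeros(n_min, dtype=bool)
    ones_min = np.ones(n_min, dtype=bool)
    quiet = np.zeros(n_sec, dtype=np.float32)

    hip_off = zeros_min if scenario == "worn-both" else ones_min
    chest_off = ones_min if scenario == "both-off" else zeros_min
    if scenario == "hip-off":
        moving = np.repeat(rng.random(n_min) < 0.3, 60).astype(np.float32) * np.float32(
            cfg.wear_burst_amplitude
        )
    else:
        moving = quiet

    hip = TriaxialRecording(
        cfg.start_time, cfg.hip_rate, _gen_stream(rng, n_min, cfg.hip_rate, hip_off, quiet, cfg)
    )
    chest = TriaxialRecording(
        cfg.start_time, cfg.chest_rate,
        _gen_stream(rng, n_min, cfg.chest_rate, chest_off, moving, cfg),
    )
    hr = _heart_rate(rng, n_sec, cfg.hr_mean, np.repeat(chest_off, 60))
    heart_rate = pd.Series(
        hr, index=pd.date_range(cfg.start_time, periods=n_sec, freq="1s"),
        name="heart_rate_bpm",
    )
    return hip, chest, heart_rate


def evaluation_config(seed: int | None = None, **overrides) -> SimulationConfig:
    """The 24-h benchmark configuration used to compare the four algorithms.

    Plants the two short morning episodes of the default configuration plus
    one long night episode, giving each algorithm family something it can
    (and something it cannot) detect.
    """
    params = dict(n_short_episodes=2, n_long_episodes=1, seed=seed)
    params.update(overrides)
    return SimulationConfig(**params)
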