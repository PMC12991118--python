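"""Closed-loop brain-computer interface transform and trial state machine.

A single conditioned neuron (CN) controls the speed of a motorized reward
port. The CN's raw fluorescence is mapped piecewise-linearly onto an analog
voltage between two thresholds (the median and maximum of a preceding
spontaneous period), the voltage sets the stepping frequency of the port
motor, and a trial is a hit if the port covers the start-to-reward distance
before a timeout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BCIConfig",
    "Thresholds",
    "TrialEvents",
    "compute_thresholds",
    "control_voltage",
    "step_frequency",
    "run_closed_loop",
]


@dataclass(frozen=True)
class BCIConfig:
    """Parameters of the BCI transform and trial geometry.

    gain            steps/s per volt of the motor controller
    v_max           maximum analog control voltage (V)
    step_size       size of one motor step (um)
    start_distance  port distance from the mouse at trial start (mm)
    reward_distance travel required for a hit (mm)
    timeout         trial duration limit (s)
    fl_dwell        time the CN must stay below F_L after a hit (s)
    intertrial_delay delay after the dwell before the port returns (s)
    port_return_time time for the port to return to start (s)
    frame_rate      imaging rate (Hz)
    feedback_lag    optional control lag (s) emulating online motion
                    correction delay; 0 disables it
    """

    gain: float = 7.9
    v_max: float = 3.3
    step_size: float = 685.0
    start_distance: float = 7.0
    reward_distance: float = 6.0
    timeout: float = 10.0
    fl_dwell: float = 0.2
    intertrial_delay: float = 2.0
    port_return_time: float = 0.3
    frame_rate: float = 20.0
    feedback_lag: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "gain", "v_max", "step_size", "start_distance", "reward_distance",
            "timeout", "fl_dwell", "intertrial_delay", "port_return_time",
            "frame_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"BCIConfig.{name} must be strictly positive")
        if self.reward_distance > self.start_distance:
            raise ValueError("reward_distance must not exceed start_distance")
        if self.fl_dwell >= self.timeout:
            raise ValueError("fl_dwell must be smaller than timeout")
        if self.feedback_lag < 0:
            raise ValueError("feedback_lag must be non-negative")

    @property
    def frame_dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def max_speed_mm_s(self) -> float:
        """Port speed at voltage ceiling, in mm/s."""
        return self.step_size * 1e-3 * self.gain * self.v_max


@dataclass(frozen=True)
class Thresholds:
    """Lower (median) and upper (maximum) fluorescence thresholds.

    ``degenerate`` flags F_U == F_L, for which the voltage map is undefined
    on the open interval.
    """

    FL: float
    FU: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.FU < self.FL:
            raise ValueError("FU must be >= FL")


@dataclass
class TrialEvents:
    """Per-trial event times. ``reward_times`` is NaN on miss trials."""

    trial_start_times: np.ndarray
    reward_times: np.ndarray
    outcomes: np.ndarray  # 'hit' | 'miss'
    durations: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.trial_start_times)
        if not (len(self.reward_times) == len(self.outcomes) == len(self.durations) == n):
            raise ValueError("TrialEvents fields must have equal length")
        if n:
            if np.any(np.diff(self.trial_start_times) <= 0):
                raise ValueError("trial start times must be strictly increasing")
            if np.any(self.durations <= 0):
                raise ValueError("durations must be positive")

    def __len__(self) -> int:
        return len(self.trial_start_times)

    @property
    def n_hits(self) -> int:
        return int(np.sum(self.outcomes == "hit"))

    @property
    def hit_rate(self) -> float:
        return self.n_hits / len(self) if len(self) else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": self.trial_start_times,
                "reward_s": self.reward_times,
                "outcome": self.outcomes,
                "duration_s": self.durations,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="NA")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialEvents":
        return cls(
            trial_start_times=df["start_s"].to_numpy(float),
            reward_times=df["reward_s"].to_numpy(float),
            outcomes=df["outcome"].to_numpy(object),
            durations=df["duration_s"].to_numpy(float),
        )

    @classmethod
    def from_csv(cls, path) -> "TrialEvents":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def empty(cls) -> "TrialEvents":
        z = np.empty(0)
        return cls(z.copy(), z.copy(), np.empty(0, object), z.copy())


def compute_thresholds(spontaneous_trace: np.ndarray) -> Thresholds:
    """Thresholds from a spontaneous period: F_L = median, F_U = maximum."""
    trace = np.asarray(spontaneous_trace, dtype=float)
    if trace.size == 0:
        raise ValueError("spontaneous trace is empty")
    if not np.all(np.isfinite(trace)):
        raise ValueError("spontaneous trace contains non-finite values")
    fl = float(np.median(trace))
    fu = float(np.max(trace))
    return Thresholds(FL=fl, FU=fu, degenerate=(fu == fl))


def control_voltage(h_cn, thr: Thresholds, cfg: BCIConfig = BCIConfig()):
    """Piecewise-linear map from CN fluorescence to control voltage.

    0 below F_L, linear between F_L and F_U, clamped at v_max above F_U.
    Accepts scalars or arrays.
    """
    if thr.degenerate:
        raise ValueError("voltage map undefined for degenerate thresholds (FU == FL)")
    h = np.asarray(h_cn, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("non-finite CN fluorescence")
    v = cfg.v_max * (h - thr.FL) / (thr.FU - thr.FL)
    v = np.clip(v, 0.0, cfg.v_max)
    return float(v) if np.isscalar(h_cn) else v


def step_frequency(v, cfg: BCIConfig = BCIConfig()):
    """Motor step frequency (steps/s) at control voltage ``v``."""
    varr = np.asarray(v, dtype=float)
    if np.any(varr < 0) or np.any(varr > cfg.v_max):
        raise ValueError(f"voltage outside [0, {cfg.v_max}]")
    f = cfg.gain * varr
    return float(f) if np.isscalar(v) else f


def _port_speed_mm_s(h, thr: Thresholds, cfg: BCIConfig):
    """Expected port speed (mm/s) for CN fluorescence h."""
    return cfg.step_size * 1e-3 * step_frequency(control_voltage(h, thr, cfg), cfg)


def run_closed_loop(
    cn_trace: np.ndarray,
    thr: Thresholds,
    cfg: BCIConfig = BCIConfig(),
    *,
    t0: float = 0.0,
    stochastic_steps: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[TrialEvents, np.ndarray]:
    """Run the trial state machine over a CN fluorescence trace.

    Port motion integrates the expected displacement step_size * f_step * dt
    each frame; with ``stochastic_steps`` the number of motor steps per frame
    is instead drawn Poisson(f_step * dt). Returns the trial events and the
    port *travelled distance* trace in mm (0 at each trial start, clipped at
    reward_distance; 0 between trials).

    Trial sequencing: a trial is a hit once cumulative travel reaches
    ``reward_distance`` within ``timeout``; after a hit the CN must stay
    below F_L for ``fl_dwell``, then ``intertrial_delay`` elapses, then the
    port returns over ``port_return_time`` and the next trial starts. After
    a miss the port resets and the next trial starts after
    ``port_return_time``. All event times are frame-aligned.
    """
    trace = np.asarray(cn_trace, dtype=float)
    dt = cfg.frame_dt
    n = trace.size
    if n < 2:
        warnings.warn("trace too short for a single trial; returning empty events")
        return TrialEvents.empty(), np.zeros(n)
    if stochastic_steps and rng is None:
        raise ValueError("stochastic_steps requires an rng")

    lag_frames = int(round(cfg.feedback_lag / dt))
    dwell_frames = max(1, int(round(cfg.fl_dwell / dt)))
    timeout_frames = int(round(cfg.timeout / dt))

    port = np.zeros(n)
    starts: list[float] = []
    rewards: list[float] = []
    outcomes: list[str] = []
    durations: list[float] = []

    IN_TRIAL, POST_HIT_DWELL, DELAY = 0, 1, 2
    state = IN_TRIAL
    trial_start_frame = 0
    displacement = 0.0
    dwell_count = 0
    delay_frames_left = 0
    starts.append(t0)
    trial_open = True

    for k in range(n):
        h = trace[max(0, k - lag_frames)]
        if state == IN_TRIAL:
            if stochastic_steps:
                f = step_frequency(control_voltage(h, thr, cfg), cfg)
                displacement += rng.poisson(f * dt) * cfg.step_size * 1e-3
            else:
                displacement += _port_speed_mm_s(h, thr, cfg) * dt
            port[k] = min(displacement, cfg.reward_distance)
            elapsed = k - trial_start_frame + 1
            if displacement >= cfg.reward_distance:
                t_rew = t0 + k * dt
                rewards.append(t_rew)
                outcomes.append("hit")
                durations.append(max(elapsed * dt, dt))
                trial_open = False
                state = POST_HIT_DWELL
                dwell_count = 0
            elif elapsed >= timeout_frames:
                rewards.append(np.nan)
                outcomes.append("miss")
                durations.append(cfg.timeout)
                trial_open = False
                state = DELAY
                delay_frames_left = int(round(cfg.port_return_time / dt))
        elif state == POST_HIT_DWELL:
            dwell_count = dwell_count + 1 if h < thr.FL else 0
            if dwell_count >= dwell_frames:
                state = DELAY
                delay_frames_left = int(
                    round((cfg.intertrial_delay + cfg.port_return_time) / dt)
                )
        else:  # DELAY
            delay_frames_left -= 1
            if delay_frames_left <= 0 and k + 1 < n:
                state = IN_TRIAL
                trial_start_frame = k + 1
                displacement = 0.0
                starts.append(t0 + (k + 1) * dt)
                trial_open = True

    if trial_open:
        # drop the unfinished trailing trial
        starts.pop()

    m = len(outcomes)
    events = TrialEvents(
        trial_start_times=np.asarray(starts[:m], dtype=float),
        reward_times=np.asarray(rewards, dtype=float),
        outcomes=np.asarray(outcomes, dtype=object),
        durations=np.asarray(durations, dtype=float),
    )
    if m == 0:
        warnings.warn("no completed trials in trace")
    return events, port
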