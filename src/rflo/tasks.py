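"""Synthetic benchmark tasks: periodic output, Ready-Set-Go, cursor reaches.

These generators are the package's only data source.  They are pure
functions of (spec, seed): same arguments, same trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .rnn_core import ConfigurationError, TrialData

__all__ = [
    "PeriodicTaskSpec",
    "ReadySetGoSpec",
    "ReachTaskSpec",
    "periodic_trial",
    "ready_set_go_trial",
    "reach_syllable_trial",
]


@dataclass(frozen=True)
class PeriodicTaskSpec:
    """Autonomous periodic-output task: one trial is one period of T steps.

    The target is the fixed waveform
    y*(t) = sin(2 pi t/T) + 0.5 sin(4 pi t/T) + 0.25 sin(8 pi t/T)
    and there is no external input (N_x = 0).
    """

    T: int = 200

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ConfigurationError("periodic task needs T >= 2")


def periodic_trial(spec: PeriodicTaskSpec) -> TrialData:
    t = np.arange(1, spec.T + 1, dtype=float)
    w = 2.0 * np.pi * t / spec.T
    ystar = np.sin(w) + 0.5 * np.sin(2 * w) + 0.25 * np.sin(4 * w)
    return TrialData(
        x_seq=np.zeros((spec.T, 0)),
        ystar_seq=ystar[:, np.newaxis],
        meta={"task": "periodic", "period": spec.T},
    )


@dataclass(frozen=True)
class ReadySetGoSpec:
    """Interval-matching task.

    A single input channel carries two unit-amplitude Gaussian pulses of
    width ``pulse_sigma`` separated by a delay drawn uniformly from
    [delay_min, delay_max]; the target is one pulse trailing the second
    input pulse by the same delay.  ``trial_T`` defaults to
    t_first_pulse + 2*delay_max + 4*pulse_sigma.
    """

    delay_min: int = 50
    delay_max: int = 100
    pulse_sigma: float = 15.0
    t_first_pulse: int = 50
    trial_T: Optional[int] = None

    def __post_init__(self) -> None:
        if self.delay_min > self.delay_max:
            raise ConfigurationError("delay_min must be <= delay_max")
        if self.delay_min < 1:
            raise ConfigurationError("delays must be positive")
        T = self.resolved_T
        if self.t_first_pulse + 2 * self.delay_max >= T:
            raise ConfigurationError("trial_T too short for the latest target pulse")

    @property
    def resolved_T(self) -> int:
        if self.trial_T is not None:
            return self.trial_T
        return int(self.t_first_pulse + 2 * self.delay_max + 4 * self.pulse_sigma)


def _gaussian_bump(T: int, center: float, sigma: float) -> np.ndarray:
    t = np.arange(1, T + 1, dtype=float)
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def ready_set_go_trial(
    spec: ReadySetGoSpec,
    seed: int | np.random.Generator = 0,
    delay: Optional[int] = None,
) -> TrialData:
    """Sample one Ready-Set-Go trial (or build one with a fixed ``delay``)."""
    if delay is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        delay = int(rng.integers(spec.delay_min, spec.delay_max + 1))
    if not spec.delay_min <= delay <= spec.delay_max:
        raise ConfigurationError(f"delay {delay} outside [{spec.delay_min}, {spec.delay_max}]")
    T = spec.resolved_T
    t1 = spec.t_first_pulse
    t2 = t1 + delay
    t_target = t1 + 2 * delay
    x = _gaussian_bump(T, t1, spec.pulse_sigma) + _gaussian_bump(T, t2, spec.pulse_sigma)
    ystar = _gaussian_bump(T, t_target, spec.pulse_sigma)
    return TrialData(
        x_seq=x[:, np.newaxis],
        ystar_seq=ystar[:, np.newaxis],
        meta={
            "task": "ready_set_go",
            "delay": delay,
            "t_first_pulse": t1,
            "t_second_pulse": t2,
            "t_target_pulse": t_target,
        },
    )


def _default_directions() -> tuple:
    return (
        (1.0, 0.0),
        (0.0, 1.0),
        (-1.0, 0.0),
        (0.0, -1.0),
    )


@dataclass(frozen=True)
class ReachTaskSpec:
    """Cursor reach-and-hold syllables driven by tonic inputs.

    Each of ``n_syllables`` tonic input channels selects a reach direction;
    the 2-D target output is the cursor *velocity*: a Gaussian speed bump
    whose integral over the syllable equals ``reach_length``.  A hold
    syllable keeps a tonic channel active but demands zero velocity.
    ``bounds`` is the half-width of the square workspace.
    """

    n_syllables: int = 4
    syllable_T: int = 200  # 20 tau at tau = 10
    directions: Sequence = field(default_factory=_default_directions)
    reach_length: float = 1.0
    bounds: float = 1.5

    def __post_init__(self) -> None:
        if len(self.directions) != self.n_syllables:
            raise ConfigurationError("need one direction per syllable")
        for d in self.directions:
            if not np.isclose(np.hypot(*d), 1.0):
                raise ConfigurationError("directions must be unit vectors")

    def displacement(self, syllable_id: int, hold: bool = False) -> np.ndarray:
        """Net cursor displacement produced by one syllable."""
        if hold:
            return np.zeros(2)
        return self.reach_length * np.asarray(self.directions[syllable_id], dtype=float)


def reach_syllable_trial(spec: ReachTaskSpec, syllable_id: int, hold: bool = False) -> TrialData:
    """One syllable: tonic channel ``syllable_id`` on, bell-shaped velocity.

    The speed profile is a Gaussian bump (sd = syllable_T/8, centred
    mid-syllable) normalised so the summed velocity equals the reach
    length; a hold syllable has identically zero target velocity.
    """
    if not 0 <= syllable_id < spec.n_syllables:
        raise ConfigurationError(f"syllable_id {syllable_id} out of range")
    T = spec.syllable_T
    x = np.zeros((T, spec.n_syllables))
    x[:, syllable_id] = 1.0
    if hold:
        v = np.zeros((T, 2))
    else:
        speed = _gaussian_bump(T, (T + 1) / 2.0, T / 8.0)
        speed *= spec.reach_length / speed.sum()
        v = np.outer(speed, np.asarray(spec.directions[syllable_id], dtype=float))
    return TrialData(
        x_seq=x,
        ystar_seq=v,
        meta={"task": "reach", "syllable_id": syllable_id, "hold": hold},
    )
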