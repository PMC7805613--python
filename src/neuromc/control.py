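"""Hierarchical controller: EP schedules, spindle feedback with delay, CPG, noise.

The controller has three layers.  The top level ``u_central`` is the integer
index of the active equilibrium-point (EP) segment over time.  The middle
level ``u_topdown`` consists of the twelve piecewise-constant muscle-specific
commands (six open-loop stimulations ``u_open`` and six desired fiber lengths
``lambda``); all twelve switch at the same instants.  The bottom level is the
motor command

    u_i(t) = { u_open_i + k_p (l_CE_i(t - delta) - lambda_i) / l_opt_i
               + u_cpg_i(t) }_0^1 ,

clamped once, to the full sum.  The feedback uses the muscle-spindle sign
convention (stretch beyond lambda adds drive) with the gain normalized by the
optimal fiber length, and fiber-length information is delayed by
``delta = 10 ms`` (short-latency reflex).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ControllerParams


@dataclass
class EPSegment:
    t_start: float
    u_open: np.ndarray           # (6,)
    lam: np.ndarray              # (6,) desired CE lengths, m
    angles: np.ndarray | None = None   # (2,) EP joint angles, informational


@dataclass
class EPSchedule:
    """Ordered piecewise-constant top-down commands; all muscles switch together."""

    segments: list[EPSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [s.t_start for s in self.segments]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("EP switch times must be strictly increasing")

    def segment_index(self, t: float) -> int:
        """1-based index of the active EP segment at time t (u_central)."""
        idx = 0
        for k, s in enumerate(self.segments):
            if t >= s.t_start:
                idx = k
        return idx + 1

    def commands(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        s = self.segments[self.segment_index(t) - 1]
        return s.u_open, s.lam

    @property
    def switch_times(self) -> np.ndarray:
        return np.array([s.t_start for s in self.segments])


# ---------------------------------------------------------------------- signals

def cpg_signal(t: float, amp: float, freq: float, phase: np.ndarray | float
               ) -> np.ndarray | float:
    """Sinusoidal central-pattern-generator stimulation ``amp sin(2 pi f t + phase)``.

    Flexing muscles use phase 0, extending muscles phase pi, so flexor and
    extensor contributions are antiphase.  The excitation window is applied by
    the caller.
    """
    return amp * np.sin(2.0 * np.pi * freq * t + phase)


def motor_command(t: float, u_open: np.ndarray, lam: np.ndarray,
                  l_ce_delayed: np.ndarray, u_cpg: np.ndarray | float,
                  k_p: float, l_opt: np.ndarray) -> np.ndarray:
    """Total stimulation per muscle, clamped once to [0, 1]."""
    raw = u_open + k_p * (l_ce_delayed - lam) / l_opt + u_cpg
    return np.clip(raw, 0.0, 1.0)


# ----------------------------------------------------------------------- delay

class DelayBuffer:
    """Dense history of fiber lengths on the integration grid.

    The reflex delay (10 ms) is much larger than the integrator step, so
    linear interpolation in the stored history realizes the delayed signal to
    negligible error; before the history starts, the initial fiber lengths
    are returned.
    """

    def __init__(self, dt: float, n_steps: int, l0: np.ndarray):
        self.dt = dt
        self.data = np.empty((n_steps + 1, l0.size))
        self.data[0] = l0
        self.filled = 0           # index of the last stored sample

    def push(self, l_ce: np.ndarray) -> None:
        self.filled += 1
        self.data[self.filled] = l_ce

    def at(self, t: float) -> np.ndarray:
        if self.filled < 0:
            raise ValueError("empty history")
        if t <= 0.0:
            return self.data[0]
        s = t / self.dt
        i = int(s)
        if i >= self.filled:
            return self.data[self.filled]
        w = s - i
        return (1.0 - w) * self.data[i] + w * self.data[i + 1]


def delayed_length(history_t: np.ndarray, history_l: np.ndarray, t: float,
                   delta: float = 0.010) -> np.ndarray:
    """Fiber lengths at ``t - delta`` by linear interpolation in a stored history.

    ``history_l`` has shape (n_samples, n_muscles).  For ``t < delta`` the
    initial lengths are returned.  An empty history is a hard error.
    """
    history_t = np.asarray(history_t, dtype=float)
    history_l = np.atleast_2d(np.asarray(history_l, dtype=float))
    if history_t.size == 0:
        raise ValueError("empty fiber-length history")
    tq = t - delta
    if tq <= history_t[0]:
        return history_l[0].copy()
    out = np.array([np.interp(tq, history_t, history_l[:, j])
                    for j in range(history_l.shape[1])])
    return out


# ----------------------------------------------------------------------- noise

NOISE_LEVELS = {"none": 0.0, "medium": 40.0 / 300.0, "high": 80.0 / 300.0}


def add_stimulation_noise(u_trace: np.ndarray, level: float | str,
                          seed: int | np.random.Generator) -> np.ndarray:
    """Add i.i.d. zero-mean uniform noise to a stimulation trace, then re-clamp.

    ``level`` is the total noise width as a fraction of the per-muscle range of
    the clean trace (named levels: ``medium`` = 40/300, ``high`` = 80/300); the
    noise is uniform on ``[-w/2, +w/2]`` with ``w = level * (u_max - u_min)``
    computed per muscle.  The result is clamped to [0, 1].  Reproducible for a
    fixed seed.
    """
    if isinstance(level, str):
        level = NOISE_LEVELS[level]
    if level < 0:
        raise ValueError("noise level must be >= 0")
    u = np.atleast_2d(np.asarray(u_trace, dtype=float))
    if level == 0.0:
        return np.asarray(u_trace, dtype=float).copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    width = level * (u.max(axis=0) - u.min(axis=0))
    noise = rng.uniform(-0.5, 0.5, size=u.shape) * width[None, :]
    out = np.clip(u + noise, 0.0, 1.0)
    return out.reshape(np.asarray(u_trace).shape)
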