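"""Forward simulation of the full layered model.

One global state vector couples the skeleton, the rod and the six MTUs:

    y = [phi, psi, phid, psid, x_rod, v_rod, a_1..6, l_CE_1..6]   (18 states)

integrated with a fixed-step classical Runge--Kutta scheme.  A fixed step is
used (rather than an adaptive solver) because the delayed spindle feedback
needs a dense fiber-length history: the 10 ms delay is realized by linear
interpolation in the per-step history buffer, and runs are bit-reproducible
for a given configuration.  The default step of 0.5 ms resolves the stiffest
tendon/damping time constants with a comfortable margin; traces are recorded
on a coarser uniform output grid (1 kHz by default).

Two drive modes exist: *closed loop* (EP schedule + spindle feedback + CPG,
the normal case) and *replay*, where a prescribed stimulation time series is
fed to the muscles directly (used for the stimulation-noise experiments,
which perturb ``u`` downstream of the controller).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import body, muscle
from .body import ArmConfiguration, MusclePathModel, RodState
from .config import MUSCLE_NAMES, ModelConfig
from .control import DelayBuffer, EPSchedule, cpg_signal, motor_command
from .muscle import MuscleGroup
from .trace import HierarchyTrace

#: CPG phase per muscle: 0 for flexing, pi for extending muscles
CPG_PHASES = np.array([0.0 if "flexor" in m else np.pi for m in MUSCLE_NAMES])


class SimulationError(RuntimeError):
    """Raised when the state diverges; carries the partial trace for diagnosis."""

    def __init__(self, msg: str, partial: pd.DataFrame | None = None):
        super().__init__(msg)
        self.partial = partial


class _Model:
    """Pre-built vectorized model pieces shared by all runs of one config."""

    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        self.paths = MusclePathModel(cfg)
        self.muscles = MuscleGroup(cfg)


def _unpack(y: np.ndarray):
    return y[0:2], y[2:4], y[4], y[5], y[6:12], y[12:18]


def simulate(cfg: ModelConfig,
             schedule: EPSchedule | None,
             duration: float,
             q0: np.ndarray,
             a0: np.ndarray,
             l_ce0: np.ndarray,
             cpg_freq: float | None = None,
             u_replay: tuple[np.ndarray, np.ndarray] | None = None,
             meta: dict | None = None) -> HierarchyTrace:
    """Integrate the layered model and record a :class:`HierarchyTrace`.

    ``u_replay = (t_grid, u_grid)`` switches to replay mode (``schedule`` is
    then only used to record the top-down channels).  The CPG is active inside
    the configured excitation window when ``cpg_freq`` is given.
    """
    model = _Model(cfg)
    g, paths, seg = model.muscles, model.paths, cfg.segments
    ctl, rodp, sim = cfg.controller, cfg.rod, cfg.simulation
    dt = sim.dt
    n_steps = int(round(duration / dt))
    rec_every = int(round(1.0 / (sim.output_rate * dt)))

    hist = DelayBuffer(dt, n_steps, np.asarray(l_ce0, dtype=float))
    amp = ctl.cpg_amp if cpg_freq is not None else 0.0
    w0, w1 = ctl.cpg_window

    if u_replay is not None:
        rt, ru = u_replay

        def u_of(t: float, _l_delayed: np.ndarray) -> np.ndarray:
            return np.array([np.interp(t, rt, ru[:, j]) for j in range(6)])
    else:
        if schedule is None:
            raise ValueError("closed-loop simulation needs an EP schedule")

        def u_of(t: float, l_delayed: np.ndarray) -> np.ndarray:
            u_open, lam = schedule.commands(t)
            u_cpg = cpg_signal(t, amp, cpg_freq or 0.0, CPG_PHASES) if (
                amp > 0.0 and w0 <= t <= w1) else 0.0
            return motor_command(t, u_open, lam, l_delayed, u_cpg, ctl.k_p, g.l_opt)

    rod_on = rodp.enabled

    def rhs(t: float, y: np.ndarray, u_cache: dict | None = None):
        q, qd, xr, vr, act, lce = _unpack(y)
        lce = np.maximum(lce, 0.05 * g.l_opt)
        l_delayed = hist.at(t - ctl.delay)
        u = u_of(t, l_delayed)
        if u_cache is not None:
            u_cache["u"] = u
        l_mtu = paths.mtu_lengths(q)
        r = paths.moment_arms(q)
        l_mtu_dot = -(r * qd[None, :]).sum(axis=1)
        act_c = np.clip(act, 0.0, 1.0)
        dadt = muscle.activation_rate(act_c, u, lce, g)
        v_ce, f_ce, f_mtu = muscle.contraction_dynamics(lce, act_c, l_mtu, l_mtu_dot, g)
        torque = r.T @ f_mtu
        rod = RodState(xr, vr) if rod_on else None
        qdd = body.arm_accelerations(ArmConfiguration(q, qd), torque, rod, cfg)
        if rod_on:
            a_hand = body.hand_acceleration(q, qd, qdd, seg)
            xrdd = body.rod_accel(RodState(xr, vr), a_hand, rodp)
            rod_d = (vr, xrdd)
        else:
            rod_d = (0.0, 0.0)
        dy = np.concatenate([qd, qdd, rod_d, dadt, v_ce])
        if u_cache is not None:
            u_cache.update(f_ce=f_ce, f_mtu=f_mtu, torque=torque)
        return dy

    y = np.concatenate([np.asarray(q0, float), np.zeros(2),
                        [0.0, 0.0], np.asarray(a0, float), np.asarray(l_ce0, float)])

    n_rec = n_steps // rec_every + 1
    cols: dict[str, np.ndarray] = {"time": np.zeros(n_rec)}
    chan_names = (["u_central"]
                  + [f"u_open_{m}" for m in MUSCLE_NAMES]
                  + [f"lambda_{m}" for m in MUSCLE_NAMES]
                  + [f"u_{m}" for m in MUSCLE_NAMES]
                  + [f"a_{m}" for m in MUSCLE_NAMES]
                  + [f"F_CE_{m}" for m in MUSCLE_NAMES]
                  + [f"F_MTU_{m}" for m in MUSCLE_NAMES]
                  + ["T_elbow", "T_shoulder", "q_elbow", "q_shoulder"])
    if rod_on:
        chan_names.append("rod_x")
    for c in chan_names:
        cols[c] = np.zeros(n_rec)

    def record(k_rec: int, t: float, y: np.ndarray):
        cache: dict = {}
        rhs(t, y, cache)
        q, qd, xr, vr, act, lce = _unpack(y)
        if schedule is not None:
            u_open, lam = schedule.commands(t)
            seg_idx = schedule.segment_index(t)
        else:
            u_open = np.full(6, np.nan)
            lam = np.full(6, np.nan)
            seg_idx = 1
        cols["time"][k_rec] = t
        cols["u_central"][k_rec] = seg_idx
        for j, m in enumerate(MUSCLE_NAMES):
            cols[f"u_open_{m}"][k_rec] = u_open[j]
            cols[f"lambda_{m}"][k_rec] = lam[j]
            cols[f"u_{m}"][k_rec] = cache["u"][j]
            cols[f"a_{m}"][k_rec] = np.clip(act[j], 0.0, 1.0)
            cols[f"F_CE_{m}"][k_rec] = cache["f_ce"][j]
            cols[f"F_MTU_{m}"][k_rec] = cache["f_mtu"][j]
        cols["T_elbow"][k_rec] = cache["torque"][0]
        cols["T_shoulder"][k_rec] = cache["torque"][1]
        cols["q_elbow"][k_rec] = q[0]
        cols["q_shoulder"][k_rec] = q[1]
        if rod_on:
            cols["rod_x"][k_rec] = xr

    record(0, 0.0, y)
    k_rec = 1
    t = 0.0
    for step in range(n_steps):
        k1 = rhs(t, y)
        k2 = rhs(t + 0.5 * dt, y + 0.5 * dt * k1)
        k3 = rhs(t + 0.5 * dt, y + 0.5 * dt * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        # enforce physical bounds after every step
        y[6:12] = np.clip(y[6:12], 0.0, 1.0)
        y[12:18] = np.maximum(y[12:18], 0.05 * g.l_opt)
        t = (step + 1) * dt
        hist.push(y[12:18])
        if not np.isfinite(y).all() or np.abs(y[0:2]).max() > 20.0:
            raise SimulationError(
                f"simulation diverged at t = {t:.4f} s",
                pd.DataFrame({c: v[:k_rec] for c, v in cols.items()}))
        if (step + 1) % rec_every == 0:
            record(k_rec, t, y)
            k_rec += 1

    df = pd.DataFrame({c: v[:k_rec] for c, v in cols.items()})
    return HierarchyTrace(df, dict(meta or {}, dt=dt, output_rate=sim.output_rate,
                                   rod=bool(rod_on)))
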