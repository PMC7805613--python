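"""Movement protocols and validation benchmarks.

Two simulated movement protocols generate the hierarchy traces analyzed in
this package:

* **point-to-point** -- a reach along a roughly vertical hand path through
  three equilibrium postures (start, peak-elbow, target), CPG off.  Natural
  trial-to-trial variability is emulated by jittering the EP joint angles
  (default sigma = 2 deg, truncated at +/-2 sigma), which changes only the
  muscle-specific top-down commands.
* **oscillation** -- a single held posture with a hand-held vibrating rod;
  a sinusoidal CPG drive (amplitude 0.1) excites the rod near its 3.8 Hz
  resonance for the first 4 s, after which the rod rings down freely.
  Variability is emulated by drawing the CPG frequency uniformly from
  3.8 +/- 0.2 Hz.

The module also generates discrete Markov benchmark processes with exactly
known morphological computation (conditional mutual information of the
generating kernel), used to validate the estimator.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from . import body, muscle
from .body import MusclePathModel
from .config import JOINT_RANGES, ModelConfig
from .control import EPSchedule, EPSegment, add_stimulation_noise
from .engine import simulate
from .muscle import MuscleGroup
from .trace import HierarchyTrace

DEG = np.pi / 180.0

#: default EP joint angles (elbow, shoulder) in rad for the headline reach
P2P_BASE_ANGLES = {
    "start": np.array([0.60, 0.15]),
    "peak": np.array([2.10, 0.45]),
    "target": np.array([1.70, 0.65]),
}
P2P_SWITCH_TIMES = (0.0, 0.7, 1.3)
P2P_DURATION = 3.0

OSC_POSTURE = np.array([1.57, 0.35])
OSC_DURATION = 6.5

_MONO = {"elbow": (2, 3), "shoulder": (0, 1)}   # (flexor, extensor) indices per joint


# -------------------------------------------------------------- EP planning

def equilibrium_commands(q_star: np.ndarray, cfg: ModelConfig,
                         a_max: float = 0.9) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plan open-loop stimulations and desired fiber lengths for one posture.

    Solves the closed-loop statics: biarticular muscles and antagonists sit at
    the baseline co-activation, and the monoarticular muscle on the loaded
    side of each joint is raised until the muscle torques balance gravity at
    ``q_star``.  Desired lengths ``lambda`` are the steady-state fiber lengths
    there, so the spindle feedback vanishes at the planned posture and the EP
    is a genuine equilibrium of the closed loop.

    Returns ``(u_open, lam, a_star)``.
    """
    g = MuscleGroup(cfg)
    paths = MusclePathModel(cfg)
    q_star = np.asarray(q_star, dtype=float)
    l_mtu = paths.mtu_lengths(q_star)
    r = paths.moment_arms(q_star)           # (6, 2), columns (elbow, shoulder)
    grav = body.gravity_torque(q_star, cfg.segments)
    a = np.full(6, cfg.controller.co_activation)

    def forces(act: np.ndarray) -> np.ndarray:
        l_ce = muscle.isometric_fiber_length(act, l_mtu, g)
        return muscle.tendon_force(l_mtu - l_ce, g)

    f_base = forces(a)
    for j, joint in enumerate(("elbow", "shoulder")):
        flex, ext = _MONO[joint]
        resid = float(r[:, j] @ forces(a) - grav[j])
        if abs(resid) < 1e-9:
            continue
        idx = flex if resid < 0 else ext
        f_need = f_base[idx] + abs(resid) / abs(r[idx, j])
        # bisection on the activity of the adjusted muscle (force is monotone)
        lo_a, hi_a = cfg.controller.co_activation, a_max
        trial = a.copy()
        trial[idx] = hi_a
        if forces(trial)[idx] < f_need:
            raise ValueError(
                f"posture {q_star} infeasible: {joint} demands more force than available")
        for _ in range(60):
            mid = 0.5 * (lo_a + hi_a)
            trial[idx] = mid
            if forces(trial)[idx] < f_need:
                lo_a = mid
            else:
                hi_a = mid
        a[idx] = 0.5 * (lo_a + hi_a)

    lam = muscle.isometric_fiber_length(a, l_mtu, g)
    u_open = muscle.stimulation_for_activity(a, lam, g)
    if (u_open < 0).any() or (u_open > 1).any():
        raise ValueError("planned open-loop stimulation outside [0, 1]")
    return u_open, lam, a


def _schedule_from_angles(angle_sets: list[np.ndarray], times, cfg: ModelConfig
                          ) -> EPSchedule:
    segs = []
    for t, q in zip(times, angle_sets):
        u_open, lam, _ = equilibrium_commands(q, cfg)
        segs.append(EPSegment(t, u_open, lam, np.asarray(q, dtype=float)))
    return EPSchedule(segs)


def sample_ep_variations(n: int, angle_jitter: float = 2.0 * DEG,
                         seed: int | np.random.Generator = 0,
                         base: dict[str, np.ndarray] | None = None,
                         cfg: ModelConfig | None = None,
                         times=P2P_SWITCH_TIMES) -> list[EPSchedule]:
    """Draw ``n`` EP schedules differing only in their equilibrium postures.

    Start and target postures are jittered in both joints, the peak posture in
    the elbow only; jitter is normal with the given sigma, truncated at
    +/-2 sigma, and postures outside the joint working range are redrawn.
    All other controller parameters are shared, so the schedules differ only
    at the muscle-specific top-down level.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or ModelConfig.default()
    base = base or P2P_BASE_ANGLES
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def trunc_jitter(size):
        out = np.zeros(size)
        for i in range(size):
            while True:
                x = rng.normal(0.0, angle_jitter) if angle_jitter > 0 else 0.0
                if abs(x) <= 2.0 * angle_jitter + 1e-15:
                    out[i] = x
                    break
        return out

    def in_range(q):
        return all(JOINT_RANGES[j][0] <= q[k] <= JOINT_RANGES[j][1]
                   for k, j in enumerate(("elbow", "shoulder")))

    schedules = []
    for _ in range(n):
        while True:
            start = base["start"] + trunc_jitter(2)
            peak = base["peak"] + np.array([trunc_jitter(1)[0], 0.0])
            target = base["target"] + trunc_jitter(2)
            if all(in_range(q) for q in (start, peak, target)):
                break
        schedules.append(_schedule_from_angles([start, peak, target], times, cfg))
    return schedules


# ----------------------------------------------------------------- protocols

def run_point_to_point(schedule: EPSchedule, cfg: ModelConfig | None = None,
                       seed: int = 0, duration: float = P2P_DURATION
                       ) -> HierarchyTrace:
    """Simulate one point-to-point reach (CPG off, no rod)."""
    cfg = copy.deepcopy(cfg or ModelConfig.default())
    cfg.rod.enabled = False
    first = schedule.segments[0]
    q0 = first.angles
    if q0 is None:
        raise ValueError("schedule segments need EP angles for the initial state")
    _, lam0, a0 = equilibrium_commands(q0, cfg)
    return simulate(cfg, schedule, duration, q0, a0, lam0, cpg_freq=None,
                    meta={"protocol": "point_to_point", "seed": seed})


def run_oscillation(f_cpg: float, cfg: ModelConfig | None = None, seed: int = 0,
                    duration: float = OSC_DURATION,
                    posture: np.ndarray = OSC_POSTURE) -> HierarchyTrace:
    """Simulate the rod-oscillation protocol: CPG active on [0, 4] s, then free."""
    cfg = copy.deepcopy(cfg or ModelConfig.default())
    cfg.rod.enabled = True
    u_open, lam, a0 = equilibrium_commands(posture, cfg)
    schedule = EPSchedule([EPSegment(0.0, u_open, lam, np.asarray(posture, float))])
    return simulate(cfg, schedule, duration, posture, a0, lam, cpg_freq=f_cpg,
                    meta={"protocol": "oscillation", "seed": seed, "f_cpg": float(f_cpg)})


def sample_cpg_frequencies(n: int, center: float = 3.8, spread: float = 0.2,
                           seed: int | np.random.Generator = 0) -> np.ndarray:
    """Uniform draw of n CPG frequencies from [center - spread, center + spread] Hz."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(center - spread, center + spread, size=n)


def noisy_replay(clean: HierarchyTrace, schedule: EPSchedule, level: float | str,
                 seed: int, cfg: ModelConfig | None = None) -> HierarchyTrace:
    """Re-simulate a run with uniform noise injected into the stimulation ``u``.

    The clean run's stimulation trace is perturbed (see
    :func:`neuromc.control.add_stimulation_noise`) and replayed through the
    muscles and skeleton, so the downstream levels (a, forces, torques,
    angles) respond to the noise while the top-down commands are unchanged.
    """
    cfg = copy.deepcopy(cfg or ModelConfig.default())
    cfg.rod.enabled = bool(clean.meta.get("rod", False))
    from .config import MUSCLE_NAMES
    u_cols = [f"u_{m}" for m in MUSCLE_NAMES]
    u_clean = clean.values(u_cols)
    u_noisy = add_stimulation_noise(u_clean, level, seed)
    first = schedule.segments[0]
    _, lam0, a0 = equilibrium_commands(first.angles, cfg)
    duration = float(clean.time[-1])
    trace = simulate(cfg, schedule, duration, first.angles, a0, lam0,
                     u_replay=(clean.time, u_noisy),
                     meta=dict(clean.meta, noise=str(level), noise_seed=seed))
    return trace


# ---------------------------------------------------------------- benchmarks

@dataclass
class DiscreteBenchmark:
    """Symbol sequences with an exactly known morphological computation.

    ``w_next, w, a`` are aligned transition samples (one triple per step)
    drawn from the generating kernel; ``analytic_mc`` is the conditional
    mutual information I(W'; W | A) of the kernel under its stationary
    distribution, in bits.
    """

    kind: str
    w_next: np.ndarray
    w: np.ndarray
    a: np.ndarray
    kernel: np.ndarray            # alpha(w'|w,a), shape (nw, nw, na)
    p_a: np.ndarray
    p_w: np.ndarray               # stationary distribution of W
    analytic_mc: float
    seed: int


def kernel_conditional_mi(kernel: np.ndarray, p_w: np.ndarray, p_a: np.ndarray
                          ) -> float:
    """Exact I(W'; W | A) in bits for a kernel with W ~ p_w and A ~ p_a independent."""
    nw, _, na = kernel.shape
    p_wpa = np.einsum("w,a,pwa->pa", p_w, p_a, kernel)   # p(w', a)
    mc = 0.0
    for ai in range(na):
        for wi in range(nw):
            for wp in range(nw):
                p = p_w[wi] * p_a[ai] * kernel[wp, wi, ai]
                if p <= 0:
                    continue
                cond = kernel[wp, wi, ai]
                marg = p_wpa[wp, ai] / p_a[ai]
                mc += p * np.log2(cond / marg)
    return float(max(mc, 0.0))


def generate_discrete_benchmark(kind: str, nw: int = 4, na: int = 4,
                                length: int = 10000, seed: int = 0
                                ) -> DiscreteBenchmark:
    """Generate a benchmark process of the given kind.

    * ``independent`` -- w' depends only on a: analytic MC = 0.
    * ``copy_world`` -- w' = w with W uniform and A independent: analytic
      MC = H(W) = log2(nw).  The copy kernel has every state absorbing, so
      transition samples are drawn independently from the uniform stationary
      ensemble rather than as one (frozen) trajectory.
    * ``general`` -- random stochastic kernel (Dirichlet rows); analytic MC
      from the kernel and the chain's stationary distribution.
    """
    if nw < 2 or na < 2:
        raise ValueError("alphabet sizes must be >= 2")
    if length < 1000:
        raise ValueError("benchmark length must be >= 1000")
    rng = np.random.default_rng(seed)
    p_a = np.full(na, 1.0 / na)

    if kind == "independent":
        cond = rng.dirichlet(np.ones(nw), size=na)       # (na, nw) p(w'|a)
        kernel = np.broadcast_to(cond.T[:, None, :], (nw, nw, na)).copy()
    elif kind == "copy_world":
        kernel = np.zeros((nw, nw, na))
        for ai in range(na):
            kernel[:, :, ai] = np.eye(nw)
    elif kind == "general":
        kernel = rng.dirichlet(np.ones(nw), size=(nw, na)).transpose(2, 0, 1)
    else:
        raise ValueError(f"unknown benchmark kind {kind!r}")

    if kind == "copy_world":
        p_w = np.full(nw, 1.0 / nw)
        w = rng.integers(0, nw, size=length)
        a = rng.integers(0, na, size=length)
        w_next = w.copy()
        analytic = float(np.log2(nw))
    else:
        trans = np.einsum("pwa,a->pw", kernel, p_a)       # p(w'|w)
        vals, vecs = np.linalg.eig(trans)
        k = int(np.argmin(np.abs(vals - 1.0)))
        p_w = np.real(vecs[:, k])
        p_w = np.abs(p_w) / np.abs(p_w).sum()
        a = rng.integers(0, na, size=length)
        w_seq = np.empty(length + 1, dtype=np.int64)
        w_seq[0] = rng.integers(0, nw)
        unif = rng.random(length)
        cum = np.cumsum(kernel, axis=0)                   # over w'
        for t in range(length):
            w_seq[t + 1] = np.searchsorted(cum[:, w_seq[t], a[t]], unif[t])
        w, w_next = w_seq[:-1], w_seq[1:]
        analytic = kernel_conditional_mi(kernel, p_w, p_a)
        if kind == "independent":
            analytic = 0.0

    return DiscreteBenchmark(kind, w_next, w, a, kernel, p_a, p_w,
                             analytic, int(seed) if not isinstance(seed, np.random.Generator) else -1)
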