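"""Hill-type muscle--tendon dynamics: activation biochemistry and contraction mechanics.

Each of the six MTUs is a four-element Hill model: a contractile element (CE)
with Gaussian force--length and hyperbolic force--velocity characteristics, a
parallel elastic element (PEE), and a serial elastic tendon (SEE, quadratic in
strain) with a serial damping element.  Fiber velocity follows from the force
equilibrium between the CE+PEE assembly and the damped tendon,

    F_SEE(l_MTU - l_CE) + d_SE (l'_MTU - l'_CE)
        = a f_l(l_CE) g(l'_CE) F_max + F_PEE(l_CE),

which is solved in closed form (per hyperbolic branch the equilibrium is a
quadratic in l'_CE).

Activation is a Hatze-type first-order process: activity relaxes toward a
stationary value that saturates in the stimulation u and grows with fiber
length,

    da/dt = m (a_inf(u, l) - a),
    a_inf = (a_min + y) / (1 + y),   y = (k * u * l/l_opt)^nu .

The stationary activity has the closed-form inverse used when planning
equilibrium-point commands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MUSCLE_NAMES, ModelConfig, MuscleParams


@dataclass
class MuscleState:
    """Activity in [0, 1] and CE length (m), each a 6-vector."""

    a: np.ndarray
    l_ce: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.l_ce = np.asarray(self.l_ce, dtype=float)
        if (self.l_ce <= 0).any():
            raise ValueError("fiber lengths must be > 0")


class MuscleGroup:
    """Vectorized parameter arrays for the six configured muscles."""

    def __init__(self, cfg: ModelConfig):
        self.names = MUSCLE_NAMES
        ps = [cfg.muscles[n] for n in self.names]

        def arr(attr):
            return np.array([getattr(p, attr) for p in ps])

        self.f_max = arr("f_max")
        self.l_opt = arr("l_opt")
        self.l_slack = arr("l_slack")
        self.fl_width = arr("fl_width")
        self.v_max = arr("v_max")          # m/s
        self.a_hill = arr("a_hill")
        self.f_ecc = arr("f_ecc")
        self.eps_ref = arr("eps_ref")
        self.d_se = arr("d_se")            # N s/m
        self.pee_width = arr("pee_width")
        self.act_rate = arr("act_rate")
        self.act_exp = arr("act_exp")
        self.act_scale = arr("act_scale")
        self.a_min = arr("a_min")
        # eccentric hyperbola scale chosen to match the concentric slope at v=0
        self.v_ecc = (self.f_ecc - 1.0) / (1.0 + 1.0 / self.a_hill)


# ------------------------------------------------------------- characteristic curves

def force_length(l_ce: np.ndarray, g: MuscleGroup) -> np.ndarray:
    """Normalized active force--length curve, maximal (=1) at l_opt."""
    rel = (np.asarray(l_ce) / g.l_opt - 1.0) / g.fl_width
    return np.exp(-rel * rel)


def force_velocity(v_ce: np.ndarray, g: MuscleGroup) -> np.ndarray:
    """Normalized force--velocity curve g(v); shortening v < 0, g(0) = 1."""
    vn = np.asarray(v_ce) / g.v_max
    vn_c = np.minimum(vn, 0.0)
    con = np.clip((1.0 + vn_c) / (1.0 - vn_c / g.a_hill), 0.0, None)
    ecc = g.f_ecc - (g.f_ecc - 1.0) / (1.0 + np.maximum(vn, 0.0) / g.v_ecc)
    return np.where(vn < 0.0, con, ecc)


def tendon_force(l_see: np.ndarray, g: MuscleGroup) -> np.ndarray:
    """Quadratic-in-strain tendon force, 0 at/below slack, F_max at strain eps_ref."""
    eps = np.maximum(np.asarray(l_see) / g.l_slack - 1.0, 0.0)
    return g.f_max * (eps / g.eps_ref) ** 2


def parallel_force(l_ce: np.ndarray, g: MuscleGroup) -> np.ndarray:
    """Parallel elastic force, slack at/below the optimal length."""
    rel = np.maximum(np.asarray(l_ce) / g.l_opt - 1.0, 0.0)
    return g.f_max * (rel / g.pee_width) ** 2


# ------------------------------------------------------------------ activation

def stationary_activity(u: np.ndarray, l_ce: np.ndarray, g: MuscleGroup) -> np.ndarray:
    y = (g.act_scale * np.asarray(u) * np.asarray(l_ce) / g.l_opt) ** g.act_exp
    return (g.a_min + y) / (1.0 + y)


def stimulation_for_activity(a: np.ndarray, l_ce: np.ndarray, g: MuscleGroup) -> np.ndarray:
    """Closed-form inverse of the stationary activity (a in [a_min, 1))."""
    a = np.asarray(a, dtype=float)
    y = (a - g.a_min) / (1.0 - a)
    y = np.maximum(y, 0.0)
    return y ** (1.0 / g.act_exp) / (g.act_scale * np.asarray(l_ce) / g.l_opt)


def activation_rate(a: np.ndarray, u: np.ndarray, l_ce: np.ndarray,
                    g: MuscleGroup) -> np.ndarray:
    """da/dt of the Hatze-type activation ODE.  u outside [0, 1] is a hard error."""
    u = np.asarray(u, dtype=float)
    if (u < -1e-12).any() or (u > 1.0 + 1e-12).any():
        raise ValueError("stimulation u must lie in [0, 1]; clamping is the controller's job")
    return g.act_rate * (stationary_activity(u, l_ce, g) - np.asarray(a))


# ------------------------------------------------------------------ contraction

def contraction_dynamics(l_ce: np.ndarray, a: np.ndarray, l_mtu: np.ndarray,
                         l_mtu_dot: np.ndarray, g: MuscleGroup
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fiber velocity and forces from the CE/SEE force equilibrium.

    Returns ``(dl_CE/dt [m/s], F_CE [N], F_MTU [N])``.  F_CE is the fiber
    force (active + parallel elastic); F_MTU is the tendon force including
    serial damping, clamped at zero (a tendon cannot push).
    """
    l_ce = np.asarray(l_ce, dtype=float)
    a = np.asarray(a, dtype=float)
    f_see = tendon_force(l_mtu - l_ce, g)
    f_pee = parallel_force(l_ce, g)
    amp = a * force_length(l_ce, g) * g.f_max          # isometric active capacity
    d, vm = g.d_se, g.v_max
    b = f_see + d * l_mtu_dot - f_pee                  # force available to the CE

    # concentric branch: amp * (1+x)/(1-x/a_h) + d*vm*x = b, x = v/vm in (-1, 0]
    alpha = d * vm / g.a_hill
    beta = -(amp + b / g.a_hill + d * vm)
    gam = b - amp
    disc = np.maximum(beta * beta - 4.0 * alpha * gam, 0.0)
    x_con = (-beta - np.sqrt(disc)) / (2.0 * alpha)

    # eccentric branch via u = 1 + x/v_ecc > 1 (quadratic, positive root)
    a2 = d * vm * g.v_ecc
    b2 = amp * g.f_ecc - a2 - b
    c2 = -amp * (g.f_ecc - 1.0)
    disc2 = np.maximum(b2 * b2 - 4.0 * a2 * c2, 0.0)
    u_root = (-b2 + np.sqrt(disc2)) / (2.0 * a2)
    x_ecc = g.v_ecc * (u_root - 1.0)

    # fully yielding branch: active force floor 0, d*v = b
    x_yield = b / (d * vm)

    x = np.where(b >= amp, x_ecc, np.where(b <= -d * vm, x_yield, x_con))
    v_ce = x * vm

    f_ce_active = amp * force_velocity(v_ce, g)
    f_mtu = np.maximum(f_see + d * (l_mtu_dot - v_ce), 0.0)
    return v_ce, f_ce_active + f_pee, f_mtu


def isometric_fiber_length(a: np.ndarray, l_mtu: np.ndarray, g: MuscleGroup,
                           tol: float = 1e-10) -> np.ndarray:
    """Steady-state CE length for constant activity and an isometric MTU.

    Solves ``F_SEE(l_MTU - l_CE) = a f_l(l_CE) F_max + F_PEE(l_CE)`` per muscle
    by bisection (safeguarded; tolerance in N on the force residual translated
    to machine-level length accuracy).  If the tendon is slack over the whole
    admissible range the slack boundary is returned (zero-force equilibrium).
    """
    a = np.broadcast_to(np.asarray(a, dtype=float), g.f_max.shape).copy()
    l_mtu = np.broadcast_to(np.asarray(l_mtu, dtype=float), g.f_max.shape).copy()
    lo = 0.2 * g.l_opt
    hi = l_mtu - g.l_slack

    def resid(l):
        return (tendon_force(l_mtu - l, g)
                - a * force_length(l, g) * g.f_max - parallel_force(l, g))

    # bisection: resid is > 0 at short fiber (stretched tendon) and < 0 at the
    # slack boundary, so the root is bracketed whenever the tendon engages
    x0, x1 = lo.copy(), np.maximum(hi, lo + 1e-9)
    bad = (hi <= lo) | (resid(lo) <= 0)
    for _ in range(100):
        mid = 0.5 * (x0 + x1)
        r = resid(mid)
        takes_hi = r > 0
        x0 = np.where(takes_hi, mid, x0)
        x1 = np.where(takes_hi, x1, mid)
    res = 0.5 * (x0 + x1)
    res = np.where(bad, np.maximum(hi, lo), res)
    return res
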