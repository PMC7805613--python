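"""Rigid-body dynamics of the two-link sagittal arm, the hand-held rod, and muscle paths.

Generalized coordinates are ``q = (phi, psi)`` with ``phi`` the elbow flexion
angle and ``psi`` the shoulder flexion angle measured from the downward
vertical (see :mod:`neuromc.config` for the full convention).  The equations of
motion are the standard double-pendulum manipulator form

    M(q) qdd + C(q, qd) qd + G(q) = T + J(q)^T F_ext,

with a symmetric positive-definite mass matrix.  The rod is a point mass on a
linear spring--damper sliding along a fixed lab-frame axis attached to the
hand; its coupling force on the hand depends only on the rod state, so the
arm and rod accelerations decouple algebraically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import JOINTS, MUSCLE_NAMES, ModelConfig, RodParams, SegmentParams


@dataclass
class ArmConfiguration:
    """Joint angles (elbow phi, shoulder psi) and angular velocities, rad / rad s^-1."""

    q: np.ndarray
    qdot: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.qdot = np.asarray(self.qdot, dtype=float)
        if self.q.shape != (2,) or self.qdot.shape != (2,):
            raise ValueError("q and qdot must be length-2 (elbow, shoulder)")
        if not (np.isfinite(self.q).all() and np.isfinite(self.qdot).all()):
            raise ValueError("non-finite joint state")


@dataclass
class RodState:
    """Displacement (m) and velocity (m/s) of the rod mass relative to the hand."""

    x: float = 0.0
    v: float = 0.0


# --------------------------------------------------------------------- skeleton

def mass_matrix(q: np.ndarray, seg: SegmentParams) -> np.ndarray:
    """Inertia matrix in (elbow, shoulder) coordinate order."""
    phi = q[0]
    m2, l1, r2 = seg.fore_mass, seg.upper_length, seg.fore_com
    i1, i2 = seg.upper_inertia, seg.fore_inertia
    m1, r1 = seg.upper_mass, seg.upper_com
    c = np.cos(phi)
    m_ss = m1 * r1**2 + i1 + m2 * (l1**2 + r2**2 + 2 * l1 * r2 * c) + i2
    m_se = m2 * (r2**2 + l1 * r2 * c) + i2
    m_ee = m2 * r2**2 + i2
    return np.array([[m_ee, m_se], [m_se, m_ss]])


def _bias_forces(q: np.ndarray, qd: np.ndarray, seg: SegmentParams) -> np.ndarray:
    """Coriolis/centrifugal plus gravity generalized forces, (elbow, shoulder)."""
    phi, psi = q
    phid, psid = qd[0], qd[1]
    m2, l1, r2 = seg.fore_mass, seg.upper_length, seg.fore_com
    h = m2 * l1 * r2 * np.sin(phi)
    cor_e = h * psid**2
    cor_s = -h * phid**2 - 2 * h * psid * phid
    grav = gravity_torque(q, seg)
    return np.array([cor_e + grav[0], cor_s + grav[1]])


def gravity_torque(q: np.ndarray, seg: SegmentParams) -> np.ndarray:
    """Generalized gravity force G(q), (elbow, shoulder).  Zero for the hanging arm."""
    phi, psi = q
    g = seg.gravity
    g_e = seg.fore_mass * seg.fore_com * g * np.sin(psi + phi)
    g_s = (seg.upper_mass * seg.upper_com + seg.fore_mass * seg.upper_length) * g * np.sin(psi) + g_e
    return np.array([g_e, g_s])


def hand_position(q: np.ndarray, seg: SegmentParams) -> np.ndarray:
    phi, psi = q
    l1, l2 = seg.upper_length, seg.fore_length
    return np.array([l1 * np.sin(psi) + l2 * np.sin(psi + phi),
                     -(l1 * np.cos(psi) + l2 * np.cos(psi + phi))])


def hand_jacobian(q: np.ndarray, seg: SegmentParams) -> np.ndarray:
    """2x2 Jacobian d(hand)/d(q), columns ordered (elbow, shoulder)."""
    phi, psi = q
    l1, l2 = seg.upper_length, seg.fore_length
    ce, se = np.cos(psi + phi), np.sin(psi + phi)
    cs, ss = np.cos(psi), np.sin(psi)
    return np.array([[l2 * ce, l1 * cs + l2 * ce],
                     [l2 * se, l1 * ss + l2 * se]])


def hand_acceleration(q: np.ndarray, qd: np.ndarray, qdd: np.ndarray,
                      seg: SegmentParams) -> np.ndarray:
    phi, psi = q
    l1, l2 = seg.upper_length, seg.fore_length
    pe, pd = qd[1], qd[0]           # psi-dot, phi-dot
    we = pe + pd                    # elbow absolute angular velocity
    ae = qdd[1] + qdd[0]
    cs, ss = np.cos(psi), np.sin(psi)
    ce, se = np.cos(psi + phi), np.sin(psi + phi)
    ax = -l1 * ss * pe**2 + l1 * cs * qdd[1] - l2 * se * we**2 + l2 * ce * ae
    ay = l1 * cs * pe**2 + l1 * ss * qdd[1] + l2 * ce * we**2 + l2 * se * ae
    return np.array([ax, ay])


def arm_accelerations(config: ArmConfiguration, torques: np.ndarray,
                      rod: RodState | None, cfg: ModelConfig) -> np.ndarray:
    """Joint angular accelerations (elbow, shoulder) from the manipulator equation.

    When a rod is attached, the spring--damper reaction force on the hand is
    included via the hand Jacobian.  Raises on non-finite input.
    """
    q, qd = config.q, config.qdot
    torques = np.asarray(torques, dtype=float)
    if not (np.isfinite(q).all() and np.isfinite(qd).all() and np.isfinite(torques).all()):
        raise ValueError("non-finite input to arm_accelerations")
    seg = cfg.segments
    rhs = torques - _bias_forces(q, qd, seg) - seg.joint_damping * qd
    if rod is not None:
        f_hand = rod_reaction_force(rod, cfg.rod)
        rhs = rhs + hand_jacobian(q, seg).T @ f_hand
    m = mass_matrix(q, seg)
    return np.linalg.solve(m, rhs)


def mechanical_energy(config: ArmConfiguration, seg: SegmentParams) -> float:
    """Kinetic plus gravitational potential energy of the passive arm."""
    q, qd = config.q, config.qdot
    kin = 0.5 * qd @ mass_matrix(q, seg) @ qd
    phi, psi = q
    pot = -seg.gravity * ((seg.upper_mass * seg.upper_com + seg.fore_mass * seg.upper_length)
                          * np.cos(psi) + seg.fore_mass * seg.fore_com * np.cos(psi + phi))
    return float(kin + pot)


# -------------------------------------------------------------------------- rod

def rod_reaction_force(rod: RodState, p: RodParams) -> np.ndarray:
    """Force exerted by the rod's spring--damper on the hand (lab frame, N)."""
    axis = np.asarray(p.axis, dtype=float)
    return (p.stiffness * rod.x + p.damping * rod.v) * axis


def rod_accel(rod: RodState, hand_accel: np.ndarray | float, p: RodParams) -> float:
    """Acceleration of the rod mass relative to the hand attachment, m/s^2.

    ``m (a_hand . e + xdd) = -k x - c xd`` along the rod axis ``e``; the
    reaction on the hand is the opposite spring--damper force.
    """
    p.validate()
    axis = np.asarray(p.axis, dtype=float)
    a_h = np.asarray(hand_accel, dtype=float)
    drive = float(a_h @ axis) if a_h.shape == (2,) else float(a_h)
    return -(p.stiffness * rod.x + p.damping * rod.v) / p.mass - drive


# ----------------------------------------------------------------- muscle paths

class MusclePathModel:
    """Vectorized moment arms and MTU lengths for the six configured muscles."""

    def __init__(self, cfg: ModelConfig):
        self.names = MUSCLE_NAMES
        n = len(self.names)
        # per muscle x per joint (elbow, shoulder): r0 and center, 0 where unspanned
        self.r0 = np.zeros((n, 2))
        self.center = np.zeros((n, 2))
        self.gamma = np.zeros(n)
        self.l_ref = np.zeros(n)
        self.spans = np.zeros((n, 2), dtype=bool)
        for i, name in enumerate(self.names):
            path = cfg.muscle_paths[name]
            self.gamma[i] = path.gamma
            self.l_ref[i] = path.l_ref
            for joint, r, c in zip(path.joints, path.r0, path.center):
                j = JOINTS.index(joint)
                self.r0[i, j] = r
                self.center[i, j] = c
                self.spans[i, j] = True

    def moment_arms(self, q: np.ndarray) -> np.ndarray:
        """(6, 2) moment arms in m; column order (elbow, shoulder); 0 if unspanned."""
        arg = self.gamma[:, None] * (q[None, :] - self.center)
        r = self.r0 * np.cos(arg)
        return np.where(self.spans, r, 0.0)

    def mtu_lengths(self, q: np.ndarray) -> np.ndarray:
        """(6,) MTU lengths in m; d l / d theta_j = -moment arm (flexors shorten)."""
        arg = self.gamma[:, None] * (q[None, :] - self.center)
        with np.errstate(invalid="ignore"):
            seg = np.where(np.abs(self.gamma[:, None]) > 1e-12,
                           self.r0 * np.sin(arg) / np.where(
                               np.abs(self.gamma[:, None]) > 1e-12,
                               self.gamma[:, None], 1.0),
                           self.r0 * (q[None, :] - self.center))
        return self.l_ref - np.where(self.spans, seg, 0.0).sum(axis=1)

    def mtu_velocities(self, q: np.ndarray, qd: np.ndarray) -> np.ndarray:
        """(6,) MTU lengthening velocities, m/s."""
        return -(self.moment_arms(q) * qd[None, :]).sum(axis=1)


def muscle_kinematics(config: ArmConfiguration, paths: MusclePathModel
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Return (MTU lengths (6,), moment arms (6, 2)) at the given posture."""
    return paths.mtu_lengths(config.q), paths.moment_arms(config.q)


def joint_torques(f_mtu: np.ndarray, config: ArmConfiguration,
                  paths: MusclePathModel) -> np.ndarray:
    """Map the six MTU forces to joint torques, T_j = sum_i r_ij F_i (elbow, shoulder)."""
    f_mtu = np.asarray(f_mtu, dtype=float)
    if (f_mtu < 0).any():
        raise ValueError("muscle forces must be >= 0 (muscles pull)")
    return paths.moment_arms(config.q).T @ f_mtu
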