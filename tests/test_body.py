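"""Skeleton, rod and muscle-path mechanics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neuromc.body import (
    ArmConfiguration,
    MusclePathModel,
    RodState,
    arm_accelerations,
    gravity_torque,
    hand_acceleration,
    joint_torques,
    mass_matrix,
    mechanical_energy,
    muscle_kinematics,
    rod_accel,
)
from neuromc.config import ModelConfig

postures = st.tuples(st.floats(0.05, 2.5), st.floats(-0.7, 1.7)).map(np.array)


@pytest.fixture(scope="module")
def cfg0():
    c = ModelConfig.default()
    c.rod.enabled = False
    return c


def test_hanging_arm_is_gravity_equilibrium(cfg0):
    acc = arm_accelerations(ArmConfiguration(np.zeros(2), np.zeros(2)),
                            np.zeros(2), None, cfg0)
    assert np.allclose(acc, 0.0, atol=1e-12)


@given(q=postures)
def test_rest_without_gravity_stays_at_rest(q):
    c = ModelConfig.default()
    c.segments.gravity = 0.0
    acc = arm_accelerations(ArmConfiguration(q, np.zeros(2)), np.zeros(2), None, c)
    assert np.allclose(acc, 0.0, atol=1e-12)


@given(q=postures)
def test_mass_matrix_symmetric_positive_definite(q):
    m = mass_matrix(q, ModelConfig.default().segments)
    assert np.allclose(m, m.T)
    assert np.all(np.linalg.eigvalsh(m) > 0)


def test_nan_input_is_hard_error(cfg0):
    with pytest.raises(ValueError):
        arm_accelerations(ArmConfiguration(np.zeros(2), np.zeros(2)),
                          np.array([np.nan, 0.0]), None, cfg0)
    with pytest.raises(ValueError):
        ArmConfiguration(np.array([np.nan, 0.0]), np.zeros(2))


def test_passive_swing_conserves_energy(cfg0):
    """Unforced, undamped double pendulum: mechanical energy constant over 2 s."""
    c = ModelConfig.default()
    c.segments.joint_damping = 0.0
    seg = c.segments

    def deriv(y):
        conf = ArmConfiguration(y[:2], y[2:])
        return np.concatenate([y[2:], arm_accelerations(conf, np.zeros(2), None, c)])

    y = np.array([1.2, 0.8, 0.0, 0.0])
    e0 = mechanical_energy(ArmConfiguration(y[:2], y[2:]), seg)
    dt = 2e-4
    for _ in range(10000):
        k1 = deriv(y)
        k2 = deriv(y + 0.5 * dt * k1)
        k3 = deriv(y + 0.5 * dt * k2)
        k4 = deriv(y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    e1 = mechanical_energy(ArmConfiguration(y[:2], y[2:]), seg)
    assert abs(e1 - e0) < 1e-6 * max(1.0, abs(e0))


# ------------------------------------------------------------------ muscle paths

def test_elbow_flexor_shortens_with_flexion(cfg0):
    paths = MusclePathModel(cfg0)
    i = list(paths.names).index("elbow_flexor")
    angles = np.linspace(0.1, 2.5, 40)
    lengths = [paths.mtu_lengths(np.array([a, 0.3]))[i] for a in angles]
    assert np.all(np.diff(lengths) < 0)


def test_biarticular_spans_two_joints_monoarticular_one(cfg0):
    paths = MusclePathModel(cfg0)
    r = paths.moment_arms(np.array([1.0, 0.5]))
    spans = (np.abs(r) > 0).sum(axis=1)
    by_name = dict(zip(paths.names, spans))
    assert by_name["biarticular_flexor"] == 2
    assert by_name["biarticular_extensor"] == 2
    for name in ("shoulder_flexor", "shoulder_extensor", "elbow_flexor", "elbow_extensor"):
        assert by_name[name] == 1


@pytest.mark.parametrize("q", [np.array([0.4, 0.1]), np.array([1.5, 0.8]),
                               np.array([2.2, -0.3])])
def test_length_derivative_equals_negative_moment_arm(q, cfg0):
    paths = MusclePathModel(cfg0)
    _, arms = muscle_kinematics(ArmConfiguration(q, np.zeros(2)), paths)
    h = 1e-6
    for j in range(2):
        dq = np.zeros(2)
        dq[j] = h
        num = (paths.mtu_lengths(q + dq) - paths.mtu_lengths(q - dq)) / (2 * h)
        assert np.allclose(num, -arms[:, j], rtol=1e-6, atol=1e-12)


def test_torque_map_is_linear_and_signed(cfg0):
    paths = MusclePathModel(cfg0)
    conf = ArmConfiguration(np.array([1.2, 0.4]), np.zeros(2))
    assert np.allclose(joint_torques(np.zeros(6), conf, paths), 0.0)
    f1 = np.array([0, 0, 1.0, 0, 0, 0])          # elbow flexor only
    t1 = joint_torques(f1, conf, paths)
    arms = paths.moment_arms(conf.q)
    assert t1[0] == pytest.approx(arms[2, 0])
    assert t1[1] == 0.0
    fb = np.array([0, 0, 0, 0, 10.0, 0])         # biarticular flexor
    tb = joint_torques(fb, conf, paths)
    assert tb[0] != 0 and tb[1] != 0
    rng = np.random.default_rng(1)
    fa, fc = rng.uniform(0, 100, 6), rng.uniform(0, 100, 6)
    lhs = joint_torques(2.0 * fa + 0.5 * fc, conf, paths)
    rhs = 2.0 * joint_torques(fa, conf, paths) + 0.5 * joint_torques(fc, conf, paths)
    assert np.allclose(lhs, rhs)
    with pytest.raises(ValueError):
        joint_torques(np.array([-1.0, 0, 0, 0, 0, 0]), conf, paths)


def test_gravity_torque_zero_when_hanging(cfg0):
    assert np.allclose(gravity_torque(np.zeros(2), cfg0.segments), 0.0)


# -------------------------------------------------------------------------- rod

def test_rod_at_rest_with_stationary_hand(cfg0):
    assert rod_accel(RodState(0.0, 0.0), np.zeros(2), cfg0.rod) == 0.0


def test_rod_free_oscillation_frequency_matches_closed_form(cfg0):
    p = cfg0.rod
    f0 = np.sqrt(p.stiffness / p.mass) / (2 * np.pi)
    assert f0 == pytest.approx(3.8, abs=1e-9)      # defaults tuned to the CPG drive
    # undamped free response, FFT peak within one frequency bin of f0
    import dataclasses
    pu = dataclasses.replace(p, damping=0.0)
    dt, n = 1e-3, 4000
    x, v = 0.05, 0.0
    xs = np.empty(n)
    for i in range(n):
        # symplectic Euler is fine for a linear oscillator
        v += dt * rod_accel(RodState(x, v), 0.0, pu)
        x += dt * v
        xs[i] = x
    freqs = np.fft.rfftfreq(n, dt)
    peak = freqs[np.argmax(np.abs(np.fft.rfft(xs - xs.mean())))]
    assert abs(peak - f0) <= freqs[1]


@pytest.mark.parametrize("f_lo,f_hi", [(3.0, 3.8), (4.6, 3.8)])
def test_rod_response_peaks_at_resonance(f_lo, f_hi, cfg0):
    """Arm clamped: sinusoidal hand motion at 3.8 Hz beats 3.0 and 4.6 Hz."""
    p = cfg0.rod

    def steady_amp(f):
        dt, dur = 2e-4, 4.0
        n = int(dur / dt)
        x = v = 0.0
        amp_drive = 0.01
        amps = []
        for i in range(n):
            t = i * dt
            a_hand = -amp_drive * (2 * np.pi * f) ** 2 * np.sin(2 * np.pi * f * t)
            acc = rod_accel(RodState(x, v), np.array([0.0, a_hand]), p)
            v += dt * acc
            x += dt * v
            if t > dur - 1.0:
                amps.append(abs(x))
        return max(amps)

    assert steady_amp(f_hi) > steady_amp(f_lo)


def test_rod_invalid_params_rejected(cfg0):
    import dataclasses
    with pytest.raises(ValueError):
        rod_accel(RodState(0, 0), 0.0, dataclasses.replace(cfg0.rod, mass=-1.0))


def test_hand_acceleration_consistent_with_finite_differences(cfg0):
    from neuromc.body import hand_position
    seg = cfg0.segments
    q = np.array([1.1, 0.4])
    qd = np.array([0.7, -0.3])
    qdd = np.array([2.0, 1.0])
    h = 1e-5
    # second derivative of hand position along q(t) = q + qd t + qdd t^2/2
    def pos(t):
        return hand_position(q + qd * t + 0.5 * qdd * t * t, seg)
    num = (pos(h) - 2 * pos(0.0) + pos(-h)) / h**2
    assert np.allclose(hand_acceleration(q, qd, qdd, seg), num, rtol=1e-4)
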