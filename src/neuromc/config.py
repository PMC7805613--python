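"""Model configuration: segment, rod, muscle-path, muscle and controller parameters.

All defaults describe a generic adult male arm (upper arm + forearm/hand in the
sagittal plane) actuated by six lumped muscle--tendon units: four monoarticular
(shoulder flexor/extensor, elbow flexor/extensor) and two biarticular
(flexor/extensor spanning both joints).  Every value can be overridden from a
YAML file; ``ModelConfig.default()`` is the single source of defaults and
``neuromc config dump`` prints them.

Angle convention: flexion increases the joint angle.  The shoulder angle psi is
measured from the downward vertical (arm hanging gives psi = 0); the elbow
angle phi is the flexion of the forearm relative to the upper-arm axis (phi = 0
is a straight arm).  Gravity acts along -y in the sagittal plane.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

MUSCLE_NAMES = (
    "shoulder_flexor",
    "shoulder_extensor",
    "elbow_flexor",
    "elbow_extensor",
    "biarticular_flexor",
    "biarticular_extensor",
)

#: index order of the generalized coordinates everywhere in the package
JOINTS = ("elbow", "shoulder")


@dataclass
class SegmentParams:
    """Inertial parameters of the two arm segments and gravity."""

    upper_mass: float = 2.1        # kg
    upper_length: float = 0.31     # m
    upper_com: float = 0.135       # m, shoulder -> centre of mass
    upper_inertia: float = 0.017   # kg m^2 about the segment COM
    fore_mass: float = 1.7         # kg, forearm + hand
    fore_length: float = 0.34     # m, elbow -> hand
    fore_com: float = 0.155        # m, elbow -> centre of mass
    fore_inertia: float = 0.016    # kg m^2 about the segment COM
    gravity: float = 9.81          # m s^-2
    joint_damping: float = 0.05    # N m s rad^-1, passive tissue damping

    def validate(self) -> None:
        for name in ("upper_mass", "upper_length", "upper_com", "upper_inertia",
                     "fore_mass", "fore_length", "fore_com", "fore_inertia"):
            if getattr(self, name) <= 0:
                raise ValueError(f"segment parameter {name} must be > 0")
        if self.joint_damping < 0:
            raise ValueError("joint_damping must be >= 0")


@dataclass
class RodParams:
    """Hand-held vibrating rod: point mass on a linear spring--damper.

    The mass slides along a fixed axis (default: vertical).  Defaults give a
    free resonance of 3.8 Hz, matching the CPG drive used in the oscillation
    protocol, with a quality factor of about 20 so the rod keeps ringing for
    seconds after the drive stops.
    """

    enabled: bool = False
    mass: float = 0.1                     # kg
    stiffness: float = 0.1 * (2 * np.pi * 3.8) ** 2  # N/m -> f0 = 3.8 Hz
    damping: float = 0.1 * (2 * np.pi * 3.8) / 20.0  # N s/m -> Q ~ 20
    axis: tuple[float, float] = (0.0, 1.0)           # lab-frame unit axis

    def validate(self) -> None:
        if self.mass <= 0 or self.stiffness <= 0:
            raise ValueError("rod mass and stiffness must be > 0")
        if self.damping < 0:
            raise ValueError("rod damping must be >= 0")

    @property
    def resonance_hz(self) -> float:
        return float(np.sqrt(self.stiffness / self.mass) / (2 * np.pi))


@dataclass
class MusclePath:
    """Moment-arm model of one muscle over the joints it spans.

    The moment arm about joint j is ``r0 * cos(gamma * (theta_j - center))``
    (a constant-radius pulley with mild angle dependence; ``gamma = 0`` gives
    a constant arm).  MTU length follows from integrating the moment arm:
    ``l(q) = l_ref - sum_j (r0/gamma) * sin(gamma * (theta_j - center))``, so
    ``dl/dtheta_j = -r_j(theta_j)`` exactly.  Flexors have r0 > 0 (length
    shortens with flexion), extensors r0 < 0.
    """

    joints: tuple[str, ...]
    r0: tuple[float, ...]          # m, one entry per spanned joint
    center: tuple[float, ...]      # rad, angle of maximal moment arm
    gamma: float = 0.5             # rad^-1, wrapping curvature
    l_ref: float = 0.3             # m, MTU length at the center posture

    def validate(self, seg: SegmentParams) -> None:
        if len(self.joints) != len(self.r0) or len(self.joints) != len(self.center):
            raise ValueError("joints, r0 and center must have equal length")
        lmax = max(seg.upper_length, seg.fore_length)
        for r in self.r0:
            if r == 0 or abs(r) > lmax:
                raise ValueError("moment arm must be nonzero and shorter than a segment")


@dataclass
class MuscleParams:
    """Hill-type MTU parameters for one muscle (CE + PEE + SEE with serial damping)."""

    f_max: float                  # N, maximal isometric force at optimal length
    l_opt: float                  # m, optimal CE length
    l_slack: float                # m, tendon slack length
    fl_width: float = 0.45        # dimensionless Gaussian width of force--length
    v_max_rel: float = 10.0       # l_opt/s, maximal concentric velocity
    a_hill: float = 0.25          # Hill curvature (concentric)
    f_ecc: float = 1.5            # eccentric force plateau / F_max
    eps_ref: float = 0.04         # tendon strain at F_max
    d_se_rel: float = 0.30        # serial damping, fraction of F_max/v_max
    pee_width: float = 0.5        # PEE reaches F_max at l_opt*(1+pee_width)
    act_rate: float = 11.3        # 1/s, activation time constant (Hatze-type)
    act_exp: float = 3.0          # Hatze nonlinearity exponent nu
    act_scale: float = 3.0        # Hatze saturation scale
    a_min: float = 0.005          # resting activity floor

    def validate(self) -> None:
        if min(self.f_max, self.l_opt, self.l_slack, self.act_rate) <= 0:
            raise ValueError("f_max, l_opt, l_slack and act_rate must be > 0")
        if not 0 < self.a_min < 1:
            raise ValueError("a_min must lie in (0, 1)")

    @property
    def v_max(self) -> float:
        """Maximal concentric velocity in m/s."""
        return self.v_max_rel * self.l_opt

    @property
    def d_se(self) -> float:
        """Serial damping coefficient in N s/m."""
        return self.d_se_rel * self.f_max / self.v_max


@dataclass
class ControllerParams:
    """Hybrid equilibrium-point controller with delayed spindle feedback and a CPG.

    The total stimulation per muscle is
    ``u_i = {u_open_i + k_p * (l_CE_i(t - delta) - lambda_i)/l_opt_i + u_cpg_i}_0^1``
    (clamped once, to the full sum).  The feedback follows the muscle-spindle
    convention: a fiber stretched beyond its desired length ``lambda`` receives
    extra drive.  ``k_p`` is stimulation per normalized (l_opt) length error.
    """

    k_p: float = 0.2
    delay: float = 0.010           # s, short-latency reflex delay
    cpg_amp: float = 0.1           # stimulation amplitude of the CPG
    cpg_freq: float = 3.8          # Hz
    cpg_window: tuple[float, float] = (0.0, 4.0)  # s, excitation window
    co_activation: float = 0.12    # baseline activity used when planning EPs

    def validate(self) -> None:
        if self.delay <= 0:
            raise ValueError("feedback delay must be > 0")
        if self.cpg_amp < 0:
            raise ValueError("CPG amplitude must be >= 0")


@dataclass
class SimulationParams:
    dt: float = 5.0e-4             # s, fixed integrator step
    output_rate: float = 1000.0    # Hz, trace sampling rate

    def validate(self) -> None:
        if self.dt <= 0 or self.output_rate <= 0:
            raise ValueError("dt and output_rate must be > 0")
        if (1.0 / self.output_rate) % self.dt > 1e-12:
            # the output grid must be a subgrid of the integration grid
            ratio = 1.0 / (self.output_rate * self.dt)
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError("1/output_rate must be an integer multiple of dt")


#: joint working ranges (rad), used for EP feasibility checks
JOINT_RANGES = {"elbow": (0.05, 2.6), "shoulder": (-0.8, 1.8)}


def _default_paths() -> dict[str, MusclePath]:
    e_mid, s_mid = 1.3, 0.5
    return {
        "shoulder_flexor": MusclePath(("shoulder",), (0.040,), (s_mid,), 0.5, 0.21),
        "shoulder_extensor": MusclePath(("shoulder",), (-0.040,), (s_mid,), 0.5, 0.23),
        "elbow_flexor": MusclePath(("elbow",), (0.030,), (e_mid,), 0.5, 0.26),
        "elbow_extensor": MusclePath(("elbow",), (-0.025,), (e_mid,), 0.5, 0.29),
        "biarticular_flexor": MusclePath(
            ("shoulder", "elbow"), (0.030, 0.022), (s_mid, e_mid), 0.5, 0.38),
        "biarticular_extensor": MusclePath(
            ("shoulder", "elbow"), (-0.030, -0.022), (s_mid, e_mid), 0.5, 0.44),
    }


def _default_muscles() -> dict[str, MuscleParams]:
    return {
        "shoulder_flexor": MuscleParams(f_max=1000.0, l_opt=0.11, l_slack=0.10),
        "shoulder_extensor": MuscleParams(f_max=1200.0, l_opt=0.11, l_slack=0.12),
        "elbow_flexor": MuscleParams(f_max=1200.0, l_opt=0.09, l_slack=0.17),
        "elbow_extensor": MuscleParams(f_max=1400.0, l_opt=0.10, l_slack=0.19),
        "biarticular_flexor": MuscleParams(f_max=800.0, l_opt=0.13, l_slack=0.25),
        "biarticular_extensor": MuscleParams(f_max=800.0, l_opt=0.13, l_slack=0.31),
    }


@dataclass
class ModelConfig:
    """Complete model configuration (segments, rod, muscle paths, muscles, controller)."""

    segments: SegmentParams = field(default_factory=SegmentParams)
    rod: RodParams = field(default_factory=RodParams)
    muscle_paths: dict[str, MusclePath] = field(default_factory=_default_paths)
    muscles: dict[str, MuscleParams] = field(default_factory=_default_muscles)
    controller: ControllerParams = field(default_factory=ControllerParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)

    @classmethod
    def default(cls) -> "ModelConfig":
        return cls()

    def validate(self) -> None:
        self.segments.validate()
        self.rod.validate()
        self.controller.validate()
        self.simulation.validate()
        for name in MUSCLE_NAMES:
            if name not in self.muscles or name not in self.muscle_paths:
                raise ValueError(f"missing configuration for muscle {name!r}")
            self.muscles[name].validate()
            self.muscle_paths[name].validate(self.segments)

    # ------------------------------------------------------------------ YAML
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self) -> str:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, np.floating):
                return float(obj)
            return obj

        return yaml.safe_dump(_clean(self.to_dict()), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        cfg = cls.default()
        if "segments" in d:
            cfg.segments = SegmentParams(**d["segments"])
        if "rod" in d:
            rod = dict(d["rod"])
            if "axis" in rod:
                rod["axis"] = tuple(rod["axis"])
            cfg.rod = RodParams(**rod)
        if "controller" in d:
            ctl = dict(d["controller"])
            if "cpg_window" in ctl:
                ctl["cpg_window"] = tuple(ctl["cpg_window"])
            cfg.controller = ControllerParams(**ctl)
        if "simulation" in d:
            cfg.simulation = SimulationParams(**d["simulation"])
        for name, block in d.get("muscles", {}).items():
            cfg.muscles[name] = MuscleParams(**block)
        for name, block in d.get("muscle_paths", {}).items():
            block = dict(block)
            for key in ("joints", "r0", "center"):
                if key in block:
                    block[key] = tuple(block[key])
            cfg.muscle_paths[name] = MusclePath(**block)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(text) or {})
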