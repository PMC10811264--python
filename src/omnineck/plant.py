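"""Surrogate head-neck plant and maneuver pulse generation.

The plant is a deliberately simple rigid-body surrogate so that the
controllers can be exercised, tuned and rated at desk scale: one rigid head
(mass, inertia) coupled to a prescribed-motion T1 through a translational
spring-damper acting at the atlanto-occipital joint point, a rotational
spring-damper on head orientation, gravity, and point-to-point muscle
elements whose activations come from the controller.  It is *not* a
finite-element human body model; acceptance of closed-loop behavior against
it is property-based (excursion reduced, boundedness, convergence), never
numeric reproduction of volunteer corridors.

T1 follows the vehicle pulse through a first-order seat-compliance filter
(configurable pass-through), standing in for the seat/torso path that the
surrogate does not model.  Simulation runs in an inertial frame; head
channels are reported relative to T1 per the library CSV dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation as _R

from . import stp as stp_mod
from .controller import (
    ControllerConfig,
    ControllerGains,
    NeckController,
    SensedKinematics,
)
from .kinematics import FRAME_CONVENTION, Orientation

__all__ = [
    "HeadNeckPlant",
    "PulseSegment",
    "ManeuverPulse",
    "SimulationResult",
    "InstabilityError",
    "braking_pulse",
    "lane_change_pulse",
    "simulate",
]

GRAVITY = 9.81  # m/s^2, along +z (down)


class InstabilityError(RuntimeError):
    """Raised when the integration diverges; names the first bad step."""

    def __init__(self, step: int, time_s: float, reason: str):
        self.step = step
        self.time_s = time_s
        super().__init__(
            f"simulation diverged at step {step} (t = {time_s:.3f} s): {reason}"
        )


@dataclass(frozen=True)
class HeadNeckPlant:
    """Surrogate head-neck parameters (human-scale defaults, see README).

    Geometry is expressed in the library frame (x forward, y right, z
    down).  ``cog_offset_from_t1`` places the head CoG relative to T1
    (above = negative z, slightly anterior); ``joint_offset_from_cog``
    places the atlanto-occipital joint point, where the translational neck
    spring acts, relative to the head CoG.  The CoG sitting anterior of the
    joint gives the head its forward gravity bias.
    """

    head_mass: float = 4.5  # kg
    head_inertia: tuple[float, float, float] = (0.022, 0.025, 0.015)  # kg m^2
    cog_offset_from_t1: tuple[float, float, float] = (0.02, 0.0, -0.15)  # m
    joint_offset_from_cog: tuple[float, float, float] = (-0.02, 0.0, 0.12)  # m
    #: per-axis (x, y, z): the neck is far stiffer in axial compression
    #: than in antero-posterior / lateral shear
    trans_stiffness: tuple[float, float, float] = (2000.0, 2000.0, 50000.0)  # N/m
    trans_damping: tuple[float, float, float] = (150.0, 150.0, 800.0)  # N s/m
    rot_stiffness: float = 25.0  # N m/rad (must exceed m g |z-lever| for passive stability)
    rot_damping: float = 5.0  # N m s/rad
    seat_filter_tau: float = 0.05  # s; 0 = pass-through
    gravity: float = GRAVITY

    def __post_init__(self) -> None:
        if self.head_mass <= 0.0:
            raise ValueError("head mass must be positive")
        if min(self.head_inertia) <= 0.0:
            raise ValueError("head inertia must be positive definite")
        if min(self.trans_stiffness) < 0.0 or self.rot_stiffness < 0.0:
            raise ValueError("stiffnesses must be non-negative")


@dataclass(frozen=True)
class PulseSegment:
    shape: str  # "haversine" | "trapezoid"
    peak: float  # m/s^2, magnitude
    duration: float  # s
    sign: float  # +1 / -1

    def accel(self, t: float, ramp_fraction: float = 0.15) -> float:
        """Acceleration at local time t in [0, duration]."""
        if not 0.0 <= t <= self.duration or self.peak == 0.0:
            return 0.0
        if self.shape == "haversine":
            return self.sign * self.peak * np.sin(np.pi * t / self.duration) ** 2
        if self.shape == "trapezoid":
            ramp = ramp_fraction * self.duration
            if t < ramp:
                env = 0.5 * (1.0 - np.cos(np.pi * t / ramp))
            elif t > self.duration - ramp:
                env = 0.5 * (1.0 - np.cos(np.pi * (self.duration - t) / ramp))
            else:
                env = 1.0
            return self.sign * self.peak * env
        raise ValueError(f"unknown pulse shape {self.shape!r}")


@dataclass(frozen=True)
class ManeuverPulse:
    """Vehicle acceleration time-history for one maneuver.

    ``channel`` names the loaded axis; segments play back-to-back during
    the loading phase, which starts after ``settle_duration`` of gravity
    settling.
    """

    channel: str  # "x" | "y"
    segments: tuple[PulseSegment, ...]
    settle_duration: float  # s
    loading_duration: float  # s

    def __post_init__(self) -> None:
        if self.channel not in ("x", "y"):
            raise ValueError("pulse channel must be 'x' or 'y'")
        if self.loading_duration <= 0.0:
            raise ValueError("loading duration must be positive")
        if any(s.peak < 0.0 for s in self.segments):
            raise ValueError("segment peaks are magnitudes, >= 0")

    def accel(self, t_loading: float) -> float:
        """Vehicle acceleration on ``channel`` at time since loading onset."""
        if t_loading < 0.0:
            return 0.0
        offset = 0.0
        for seg in self.segments:
            if t_loading <= offset + seg.duration:
                return seg.accel(t_loading - offset)
            offset += seg.duration
        return 0.0

    @property
    def total_duration(self) -> float:
        return self.settle_duration + self.loading_duration

    def velocity_change(self) -> float:
        """Time integral of the pulse acceleration (trapezoid, 1 ms grid)."""
        t = np.arange(0.0, sum(s.duration for s in self.segments) + 1e-9, 1e-3)
        a = np.array([self.accel(ti) for ti in t])
        return float(np.trapezoid(a, t))


def braking_pulse(
    peak: float, duration: float, settle: float, loading: float | None = None
) -> ManeuverPulse:
    """Braking: a -x deceleration plateau with smooth haversine onset and
    release, reaching ``peak`` m/s^2 for ``duration`` s."""
    if peak < 0.0 or duration <= 0.0:
        raise ValueError("peak must be >= 0 and duration > 0")
    seg = PulseSegment("trapezoid", peak, duration, sign=-1.0)
    return ManeuverPulse(
        channel="x",
        segments=(seg,),
        settle_duration=settle,
        loading_duration=duration if loading is None else loading,
    )


def lane_change_pulse(
    peak: float, duration: float, settle: float, loading: float | None = None
) -> ManeuverPulse:
    """Lane change: biphasic lateral profile — a right-turn lobe (+y,
    toward the turn centre) followed by an equal left-turn lobe, each a
    haversine of half the total duration."""
    if peak < 0.0 or duration <= 0.0:
        raise ValueError("peak must be >= 0 and duration > 0")
    half = duration / 2.0
    segments = (
        PulseSegment("haversine", peak, half, sign=+1.0),
        PulseSegment("haversine", peak, half, sign=-1.0),
    )
    return ManeuverPulse(
        channel="y",
        segments=segments,
        settle_duration=settle,
        loading_duration=duration if loading is None else loading,
    )


@dataclass
class SimulationResult:
    """Sampled closed-loop simulation output (uniform timestep)."""

    time: np.ndarray  # s
    head_translation: np.ndarray  # (n, 3) m, head CoG relative to T1 reference
    head_rotation: np.ndarray  # (n, 3) rad, zyx-extracted (rx, ry, rz)
    activations: np.ndarray  # (n, n_channels) Na
    channels: list[tuple[str, str]]
    t1_position: np.ndarray  # (n, 3) m, prescribed
    pid_response: np.ndarray  # (n,) common drive u(t)
    saturated_ms: float
    events: list[str] = field(default_factory=list)
    header: dict = field(default_factory=dict)

    def channel_series(self, name: str) -> np.ndarray:
        names = ["head_tx", "head_ty", "head_tz", "head_rx", "head_ry", "head_rz"]
        if name not in names:
            raise KeyError(name)
        i = names.index(name)
        return self.head_translation[:, i] if i < 3 else self.head_rotation[:, i - 3]


def _skew_forces(
    plant: HeadNeckPlant,
    registry: stp_mod.MuscleRegistry,
    channels: Sequence[tuple[str, str]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-channel muscle geometry: attachment (head frame, rel CoG),
    origin (T1 frame, rel T1) and max force."""
    att, org, fmax = [], [], []
    for group, side in channels:
        g = registry.groups[group]
        if side == "left":
            g = g.mirrored()
        att.append(g.attachment)
        org.append(g.origin)
        fmax.append(g.max_force)
    return np.array(att), np.array(org), np.array(fmax)


def simulate(
    plant: HeadNeckPlant,
    config: ControllerConfig,
    gains: ControllerGains,
    stps: stp_mod.StpSet,
    pulse: ManeuverPulse,
    registry: stp_mod.MuscleRegistry | None = None,
    dt_ms: float = 1.0,
    initial_offset: Sequence[float] | None = None,
    initial_rotvec: Sequence[float] | None = None,
) -> SimulationResult:
    """Integrate the closed-loop surrogate through settling plus loading.

    Phases: gravity settling with T1 stationary (controller reference is
    captured at its end), then the loading phase in which T1 follows the
    seat-filtered vehicle pulse as prescribed motion.  Head rigid-body
    state advances by semi-implicit Euler; the orientation by the rotation
    exponential map.  Deterministic for a given configuration.
    """
    if dt_ms <= 0.0 or dt_ms > 1.0 + 1e-12:
        raise ValueError("dt must be positive and at most 1 ms")
    registry = registry if registry is not None else stp_mod.default_registry()

    dt = dt_ms / 1000.0
    n_steps = int(round(pulse.total_duration / dt))
    time = np.arange(n_steps + 1) * dt

    ctrl = NeckController(config, gains, stps)
    channels = ctrl.channels
    att_head, org_t1, fmax = _skew_forces(plant, registry, channels)

    m = plant.head_mass
    inertia = np.array(plant.head_inertia)
    cog0 = np.array(plant.cog_offset_from_t1)
    joint = np.array(plant.joint_offset_from_cog)
    anchor_t1 = cog0 + joint  # joint point in T1 frame at reference

    # State: head CoG position/velocity (world), orientation, angular velocity.
    t1 = np.zeros(3)
    t1_vel = np.zeros(3)
    seat_accel = 0.0
    pos = cog0.copy()
    if initial_offset is not None:
        pos = pos + np.asarray(initial_offset, dtype=float)
    vel = np.zeros(3)
    rot = np.eye(3)
    if initial_rotvec is not None:
        rot = _R.from_rotvec(np.asarray(initial_rotvec, dtype=float)).as_matrix()
    omega = np.zeros(3)
    axis_idx = 0 if pulse.channel == "x" else 1

    na = ctrl.state.active
    trans_out = np.zeros((n_steps + 1, 3))
    rot_out = np.zeros((n_steps + 1, 3))
    act_out = np.zeros((n_steps + 1, len(channels)))
    t1_out = np.zeros((n_steps + 1, 3))
    pid_out = np.zeros(n_steps + 1)
    events: list[str] = []

    grav = np.array([0.0, 0.0, m * plant.gravity])

    for i in range(n_steps + 1):
        t = time[i]
        t_ms = t * 1000.0

        # --- record current sample -------------------------------------
        trans_out[i] = (pos - t1) - cog0
        # zyx-extracted angles (R = Rz Ry Rx): report (rx, ry, rz)
        rz, ry, rx = _R.from_matrix(rot).as_euler("ZYX")
        rot_out[i] = (rx, ry, rz)
        act_out[i] = na
        t1_out[i] = t1
        pid_out[i] = ctrl.log.pid_response[-1] if ctrl.log.pid_response else 0.0

        if not np.all(np.isfinite(pos)) or not np.all(np.isfinite(rot)):
            raise InstabilityError(i, t, "non-finite state")
        angle = np.linalg.norm(_R.from_matrix(rot).as_rotvec())
        if angle > np.pi / 2.0:
            raise InstabilityError(i, t, f"head rotation {angle:.2f} rad > pi/2")
        if i == n_steps:
            break

        # --- controller -------------------------------------------------
        sensed = SensedKinematics(
            head_orientation=Orientation(rot),
            head_cog=pos.copy(),
            t1_pos=t1.copy(),
            t1_yaw=0.0,
        )
        if not ctrl.reference_captured and t >= pulse.settle_duration - 1e-12:
            ctrl.capture_reference(sensed)
            events.append(f"reference captured at t = {t:.3f} s")
        na = ctrl.step(t_ms, sensed)

        # --- forces and torques about the head CoG ----------------------
        force = grav.copy()
        torque = np.zeros(3)

        # translational neck spring-damper at the joint point
        r_joint = rot @ joint
        joint_world = pos + r_joint
        joint_vel = vel + np.cross(omega, r_joint)
        f_spring = -np.asarray(plant.trans_stiffness) * (joint_world - (t1 + anchor_t1))
        f_spring -= np.asarray(plant.trans_damping) * (joint_vel - t1_vel)
        force += f_spring
        torque += np.cross(r_joint, f_spring)

        # rotational spring-damper on head orientation
        rotvec = _R.from_matrix(rot).as_rotvec()
        torque += -plant.rot_stiffness * rotvec - plant.rot_damping * omega

        # muscles: pull from skull attachment toward the caudal origin
        att_world = pos + (rot @ att_head.T).T
        org_world = t1 + org_t1
        pull = org_world - att_world
        norm = np.linalg.norm(pull, axis=1, keepdims=True)
        norm[norm < 1e-9] = 1.0
        f_musc = (na * fmax)[:, None] * pull / norm
        force += f_musc.sum(axis=0)
        torque += np.cross(att_world - pos, f_musc).sum(axis=0)

        # --- semi-implicit Euler ----------------------------------------
        vel = vel + dt * force / m
        pos = pos + dt * vel
        omega = omega + dt * (torque - np.cross(omega, inertia * omega)) / inertia
        rot = _R.from_rotvec(omega * dt).as_matrix() @ rot

        # --- prescribed T1 motion (seat-filtered vehicle pulse) ---------
        a_cmd = pulse.accel(t - pulse.settle_duration)
        if plant.seat_filter_tau > 0.0:
            seat_accel += dt * (a_cmd - seat_accel) / plant.seat_filter_tau
        else:
            seat_accel = a_cmd
        t1_vel[axis_idx] += dt * seat_accel
        t1 = t1 + dt * t1_vel

    return SimulationResult(
        time=time,
        head_translation=trans_out,
        head_rotation=rot_out,
        activations=act_out,
        channels=channels,
        t1_position=t1_out,
        pid_response=pid_out,
        saturated_ms=ctrl.log.saturated_ms,
        events=events,
        header={
            "frame": FRAME_CONVENTION,
            "dt_ms": dt_ms,
            "settle_s": pulse.settle_duration,
            "loading_s": pulse.loading_duration,
            "delay_ms": config.delay_ms,
            "tau_excitation_ms": config.tau_excitation_ms,
            "tau_activation_ms": config.tau_activation_ms,
            "baseline_scale": config.baseline_scale,
            "mode": config.mode,
            "gains": {"kp": gains.kp, "ki": gains.ki, "kd": gains.kd},
        },
    )
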