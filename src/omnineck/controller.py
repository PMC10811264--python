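"""The neck-muscle feedback chain: delayed error -> PID -> saturation ->
spatial-tuning-pattern scaling -> baseline -> activation dynamics.

Both controller variants share this chain and differ only in the error
signal: the translational controller senses the angular deviation of the
T1-to-head link (direction = horizontal displacement azimuth), the
rotational controller senses the axis-angle rotation of the head relative
to a reference orientation (direction = rotation axis).  The PID produces
one common activity level; the spatial tuning patterns split it into
muscle-specific drives; two cascaded first-order stages model neural
excitation and activation dynamics.

Units: the PID operates on errors in radians against time in milliseconds,
so Kp is 1/rad, Ki is 1/(rad ms) and Kd is ms/rad.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kinematics as kin
from . import stp as stp_mod

__all__ = [
    "ControllerGains",
    "StandardFormGains",
    "ControllerConfig",
    "ActivationState",
    "ReferenceController",
    "REFERENCE_CONTROLLERS",
    "delay_signal",
    "pid_response",
    "standard_to_parallel",
    "parallel_to_standard",
    "ziegler_nichols_ki",
    "saturate",
    "distribute",
    "activation_dynamics_step",
    "NeckController",
    "SensedKinematics",
]


@dataclass(frozen=True)
class ControllerGains:
    """Parallel-form PID gains: u = Kp e + Ki int(e) + Kd de/dt."""

    kp: float  # 1/rad
    ki: float  # 1/(rad ms)
    kd: float  # ms/rad

    def __post_init__(self) -> None:
        if min(self.kp, self.ki, self.kd) < 0.0:
            raise ValueError("PID gains must be non-negative")


@dataclass(frozen=True)
class StandardFormGains:
    """Standard-form gains: u = Kp (e + (1/Ti) int(e) + Td de/dt)."""

    kp: float  # 1/rad
    ti: float  # ms
    td: float  # ms

    def __post_init__(self) -> None:
        if self.kp < 0.0 or self.td < 0.0:
            raise ValueError("Kp and Td must be non-negative")
        if self.ti <= 0.0:
            raise ValueError("Ti must be positive")


def standard_to_parallel(g: StandardFormGains) -> ControllerGains:
    """Ki = Kp/Ti, Kd = Kp*Td."""
    return ControllerGains(kp=g.kp, ki=g.kp / g.ti, kd=g.kp * g.td)


def parallel_to_standard(g: ControllerGains) -> StandardFormGains:
    """Inverse of :func:`standard_to_parallel`; undefined for Kp or Ki = 0."""
    if g.kp <= 0.0 or g.ki <= 0.0:
        raise ValueError("standard form undefined for Kp = 0 or Ki = 0")
    return StandardFormGains(kp=g.kp, ti=g.kp / g.ki, td=g.kd / g.kp)


def ziegler_nichols_ki(kp: float, kd: float) -> float:
    """Ziegler-Nichols step-response integral gain from (Kp, Kd).

    The step-response rules give Ti = 4 Td; with Td = Kd/Kp this collapses
    to Ki = Kp^2 / (4 Kd).  Used to derive a principled Ki ceiling for gain
    tuning from previously published controllers that shipped with Ki = 0.
    """
    if kp <= 0.0 or kd <= 0.0:
        raise ValueError("Ziegler-Nichols Ki requires Kp > 0 and Kd > 0")
    return kp * kp / (4.0 * kd)


@dataclass(frozen=True)
class ReferenceController:
    """A previously published neck-controller gain set (inputs to the
    Ziegler-Nichols Ki derivation and to the tuning Ki ceiling)."""

    model: str
    kp: float  # 1/rad
    kd: float  # ms/rad

    @property
    def theoretical_ki(self) -> float:
        return ziegler_nichols_ki(self.kp, self.kd)


#: Published reference controllers (model, Kp [1/rad], Kd [ms/rad]).
REFERENCE_CONTROLLERS: tuple[ReferenceController, ...] = (
    ReferenceController("SAFER HBM v10", 1.301, 470.0),
    ReferenceController("THUMS", 8.0, 300.0),
    ReferenceController("GHBMC", 3.0, 250.0),
    ReferenceController("GHBMC-2", 0.78, 483.27),
)


def delay_signal(
    times: np.ndarray, values: np.ndarray, t: float, tau: float
) -> float:
    """The error signal delayed by the neural transport delay tau.

    Returns ``e(t - tau)`` by linear interpolation between stored samples;
    before any history exists (t < tau) the delayed error is defined as 0,
    matching controllers that initialize from rest during gravity settling.
    Times in ms.
    """
    if tau < 0.0:
        raise ValueError("delay must be non-negative")
    t_query = t - tau
    if t_query < (times[0] if len(times) else 0.0):
        return 0.0
    return float(np.interp(t_query, times, values))


def pid_response(
    gains: ControllerGains, times: np.ndarray, errors: np.ndarray
) -> np.ndarray:
    """Parallel-form PID response over a sampled error history.

    Trapezoidal integral, backward-difference derivative (zero at the first
    sample).  Times in ms, errors in rad; the response is an activity
    fraction.
    """
    times = np.asarray(times, dtype=float)
    errors = np.asarray(errors, dtype=float)
    if times.shape != errors.shape:
        raise ValueError("times and errors must align")
    if not (np.all(np.isfinite(times)) and np.all(np.isfinite(errors))):
        raise ValueError("PID input must be finite")
    dt = np.diff(times)
    integral = np.concatenate(
        [[0.0], np.cumsum(0.5 * dt * (errors[1:] + errors[:-1]))]
    )
    derivative = np.zeros_like(errors)
    if len(errors) > 1:
        derivative[1:] = np.diff(errors) / dt
    return gains.kp * errors + gains.ki * integral + gains.kd * derivative


def saturate(u: float, ceiling: float = 1.0) -> float:
    """Clamp the common PID drive to [0, ceiling].

    Muscles pull only, so negative responses clamp to zero; directional
    antagonist recruitment is handled entirely by the spatial tuning
    pattern query, not by signed drive.
    """
    if not np.isfinite(u):
        raise ValueError("PID response must be finite")
    return float(min(max(u, 0.0), ceiling))


def distribute(
    u_sat: float, weights: np.ndarray, baseline: np.ndarray
) -> np.ndarray:
    """Muscle-specific drives: min(1, u_sat * w_i + b_i).

    The baseline term represents quiet-sitting activity and is present for
    the full duration, gravity settling included.  The cap is applied after
    adding the baseline (cap-last; a library choice, see the methods note).
    """
    return np.minimum(1.0, u_sat * np.asarray(weights) + np.asarray(baseline))


@dataclass
class ActivationState:
    """Per-channel neural excitation and active state Na, both in [0, 1]."""

    excitation: np.ndarray
    active: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "ActivationState":
        return cls(np.zeros(n), np.zeros(n))


def activation_dynamics_step(
    state: ActivationState,
    drive: np.ndarray,
    dt: float,
    tau_excitation: float,
    tau_activation: float,
) -> ActivationState:
    """Advance the two cascaded first-order activation stages one step.

    Each stage obeys dX/dt = (input - X)/tau and is integrated with the
    exponential-Euler update X += (1 - exp(-dt/tau)) (input - X), which is
    unconditionally stable and maps [0, 1] inputs to [0, 1] states.  A
    guard still rejects dt above half the smallest time constant, where the
    cascade would be badly under-resolved.  Times in ms.
    """
    if min(tau_excitation, tau_activation) <= 0.0:
        raise ValueError("time constants must be positive")
    if dt > 0.5 * min(tau_excitation, tau_activation):
        raise ValueError(
            "dt must not exceed half the smallest activation time constant"
        )
    a_e = 1.0 - np.exp(-dt / tau_excitation)
    a_a = 1.0 - np.exp(-dt / tau_activation)
    excitation = state.excitation + a_e * (np.asarray(drive) - state.excitation)
    active = state.active + a_a * (excitation - state.active)
    return ActivationState(excitation, active)


@dataclass(frozen=True)
class ControllerConfig:
    """Everything in the chain besides the PID gains.

    The neural delay and the two activation time constants are library
    defaults in the range used by published active neck-muscle models; they
    are not measured constants and every results header records the values
    actually used.
    """

    mode: str = "translational"  # "translational" | "rotational"
    delay_ms: float = 30.0
    tau_excitation_ms: float = 30.0
    tau_activation_ms: float = 15.0
    baseline_scale: float = 0.1
    saturation_ceiling: float = 1.0
    dt_ms: float = 1.0
    axial_knot: float = 0.5
    #: STP direction query uses the current (undelayed) kinematics by
    #: default; switchable to the delayed direction.
    delayed_direction: bool = False
    #: rotation-matrix convention for the rotational error
    intrinsic_euler: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("translational", "rotational"):
            raise ValueError(f"unknown controller mode {self.mode!r}")
        if self.delay_ms < 0.0 or self.dt_ms <= 0.0:
            raise ValueError("delay must be >= 0 and dt > 0")
        if not 0.0 < self.saturation_ceiling <= 1.0:
            raise ValueError("saturation ceiling must lie in (0, 1]")


@dataclass
class SensedKinematics:
    """What the controller senses at one instant (world frame)."""

    head_orientation: kin.Orientation
    head_cog: np.ndarray
    t1_pos: np.ndarray
    t1_yaw: float = 0.0


@dataclass
class ControllerLog:
    """Per-step diagnostics used by the tuning constraint and for debugging."""

    times_ms: list[float] = field(default_factory=list)
    error: list[float] = field(default_factory=list)
    delayed_error: list[float] = field(default_factory=list)
    pid_response: list[float] = field(default_factory=list)
    saturated_ms: float = 0.0

    @property
    def max_pid_response(self) -> float:
        return max(self.pid_response, default=0.0)


class NeckController:
    """The full feedback chain for one controller mode.

    Drive the controller by calling :meth:`capture_reference` once the
    posture to hold is reached (typically at the end of gravity settling)
    and then :meth:`step` every ``dt_ms``.  Before the reference is
    captured the error is zero and only baseline activity flows.
    """

    def __init__(
        self,
        config: ControllerConfig,
        gains: ControllerGains,
        stps: stp_mod.StpSet,
    ):
        self.config = config
        self.gains = gains
        self.stps = stps
        self._interp = stp_mod.StpInterpolator(stps)
        self.channels = self._interp.channels
        # Quiet-sitting baseline: scaled minimum of each channel's pattern.
        _, _, w = stps.weight_matrix()
        self.baseline = config.baseline_scale * w.min(axis=1)
        self.state = ActivationState(self.baseline.copy(), self.baseline.copy())
        self.log = ControllerLog()
        self._reference: SensedKinematics | None = None
        self._reference_link: np.ndarray | None = None
        self._err_times: list[float] = []
        self._err_values: list[float] = []
        self._dir_history: list[tuple[float, float, bool]] = []

    # -- reference ---------------------------------------------------------

    def capture_reference(self, sensed: SensedKinematics) -> None:
        """Freeze the posture the controller will try to return to."""
        self._reference = sensed
        link = np.asarray(sensed.head_cog) - np.asarray(sensed.t1_pos)
        yaw = kin.rotation_matrix_zyx(0.0, 0.0, -sensed.t1_yaw).matrix
        self._reference_link = yaw @ link

    @property
    def reference_captured(self) -> bool:
        return self._reference is not None

    # -- error computation -------------------------------------------------

    def _sense(self, sensed: SensedKinematics) -> tuple[float, float, float, bool]:
        """Return (error_rad, bend_azimuth, axial_component, degenerate)."""
        if self._reference is None:
            return 0.0, 0.0, 0.0, True
        if self.config.mode == "rotational":
            aa = kin.rotational_error(
                sensed.head_orientation, self._reference.head_orientation
            )
            if aa.degenerate:
                return aa.angle, 0.0, 0.0, True
            azimuth, axial = stp_mod.direction_from_axis(aa.axis)
            return aa.angle, azimuth, axial, False
        err = kin.translational_error(
            sensed.head_cog, sensed.t1_pos, sensed.t1_yaw, self._reference_link
        )
        if err.deviation_angle < kin.DEGENERATE_ANGLE:
            return err.deviation_angle, 0.0, 0.0, True
        return err.deviation_angle, err.azimuth, 0.0, False

    # -- main step ---------------------------------------------------------

    def step(self, t_ms: float, sensed: SensedKinematics) -> np.ndarray:
        """Advance the chain one timestep; returns the Na vector."""
        cfg = self.config
        error, azimuth, axial, degenerate = self._sense(sensed)

        self._err_times.append(t_ms)
        self._err_values.append(error)
        self._dir_history.append((azimuth, axial, degenerate))

        # Uniform-grid linear interpolation of e(t - tau); the history is
        # sampled every dt_ms, so this is delay_signal() in O(1).
        pos = (t_ms - cfg.delay_ms - self._err_times[0]) / cfg.dt_ms
        if pos < 0.0:
            e_del = 0.0
        else:
            i0 = min(int(pos), len(self._err_values) - 1)
            i1 = min(i0 + 1, len(self._err_values) - 1)
            frac = pos - i0
            e_del = (1.0 - frac) * self._err_values[i0] + frac * self._err_values[i1]

        # Incremental parallel PID on the delayed error stream.
        if len(self._err_times) == 1:
            self._integral = 0.0
            self._prev_delayed = e_del
            derivative = 0.0
        else:
            dt = self._err_times[-1] - self._err_times[-2]
            self._integral += 0.5 * dt * (self._prev_delayed + e_del)
            derivative = (e_del - self._prev_delayed) / dt
            self._prev_delayed = e_del
        u = self.gains.kp * e_del + self.gains.ki * self._integral + self.gains.kd * derivative

        u_sat = saturate(u, cfg.saturation_ceiling)
        if u > cfg.saturation_ceiling:
            self.log.saturated_ms += cfg.dt_ms

        if cfg.delayed_direction:
            azimuth, axial, degenerate = self._delayed_direction(t_ms)
        if degenerate:
            weights = np.zeros(len(self.channels))
        else:
            weights = self._interp.query(azimuth, axial, cfg.axial_knot)

        drive = distribute(u_sat, weights, self.baseline)
        self.state = activation_dynamics_step(
            self.state, drive, cfg.dt_ms, cfg.tau_excitation_ms, cfg.tau_activation_ms
        )

        self.log.times_ms.append(t_ms)
        self.log.error.append(error)
        self.log.delayed_error.append(e_del)
        self.log.pid_response.append(u)
        return self.state.active

    def _delayed_direction(self, t_ms: float) -> tuple[float, float, bool]:
        t_query = t_ms - self.config.delay_ms
        if t_query < self._err_times[0]:
            return 0.0, 0.0, True
        idx = int(np.searchsorted(self._err_times, t_query, side="right")) - 1
        return self._dir_history[max(idx, 0)]
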