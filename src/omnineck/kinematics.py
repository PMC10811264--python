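"""Rotation algebra, frame conventions and controller error signals.

Frame convention (fixed for the whole library, SAE-style):

* ``x``: vehicle forward
* ``y``: lateral, to the occupant's right
* ``z``: vertical, downward
* right-handed; positive rotation about ``y`` tips the nose up (extension),
  so head flexion is a rotation about ``-y``; positive rotation about ``z``
  turns the chin to the right (right axial rotation); positive rotation
  about ``x`` drops the right ear (right lateral bending).

All angles are radians inside the library; degrees appear only at I/O
boundaries.  Time-series CSV files use channels ``head_tx, head_ty, head_tz``
(metres) and ``head_rx, head_ry, head_rz`` (radians) with a mandatory header
and a ``time`` column in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FRAME_CONVENTION",
    "Orientation",
    "AxisAngle",
    "TranslationalError",
    "DegenerateGeometryError",
    "rotation_matrix_zyx",
    "axis_angle_from_matrix",
    "matrix_from_axis_angle",
    "rotational_error",
    "translational_error",
]

#: Human-readable statement of the frame convention, embedded in I/O headers.
FRAME_CONVENTION = "x=vehicle-forward, y=right, z=down, right-handed; angles in rad"

#: Below this angle (rad) a rotation is treated as degenerate: the axis is
#: undefined and the documented default (0, 0, 1) is returned with a flag.
DEGENERATE_ANGLE = 1e-9

_ORTHONORMALITY_TOL = 1e-8


class DegenerateGeometryError(ValueError):
    """Raised when a geometric quantity (e.g. a zero-length link) is undefined."""


@dataclass(frozen=True)
class Orientation:
    """A proper rotation matrix (3x3, orthonormal columns, det = +1)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3) or not np.all(np.isfinite(m)):
            raise ValueError("orientation requires a finite 3x3 matrix")
        if not np.allclose(m.T @ m, np.eye(3), atol=_ORTHONORMALITY_TOL):
            raise ValueError("orientation matrix is not orthonormal")
        if np.linalg.det(m) < 0.0:
            raise ValueError("orientation matrix is a reflection (det < 0)")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "Orientation":
        return cls(np.eye(3))

    def compose(self, other: "Orientation") -> "Orientation":
        return Orientation(self.matrix @ other.matrix)


@dataclass(frozen=True)
class AxisAngle:
    """Axis-angle representation: unit axis ``v`` and angle ``theta`` in [0, pi].

    ``degenerate`` flags a near-zero rotation whose axis is undefined; the
    axis then holds the documented default (0, 0, 1) and downstream load
    sharing must emit zero directional drive.
    """

    axis: np.ndarray
    angle: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.axis, dtype=float)
        if v.shape != (3,):
            raise ValueError("axis must be a 3-vector")
        if not (0.0 <= self.angle <= np.pi + 1e-12):
            raise ValueError("angle must lie in [0, pi]")
        if not self.degenerate and abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ValueError("axis must be a unit vector for non-degenerate rotations")
        object.__setattr__(self, "axis", v)


@dataclass(frozen=True)
class TranslationalError:
    """Link-deviation error of the translational controller.

    ``deviation_angle`` (rad, >= 0) is the angle between the current and the
    reference T1-to-head link; ``azimuth`` (rad, in (-pi, pi]) is the
    horizontal-plane direction of the head displacement relative to the
    reference, in the T1-local (yaw-following) frame: 0 = forward,
    +pi/2 = to the occupant's right.
    """

    deviation_angle: float
    azimuth: float

    def __post_init__(self) -> None:
        if self.deviation_angle < 0.0:
            raise ValueError("deviation_angle must be non-negative")
        if not (-np.pi < self.azimuth <= np.pi + 1e-12):
            raise ValueError("azimuth must lie in (-pi, pi]")


def _elemental(axis: str, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    if axis == "x":
        return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    if axis == "y":
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    if axis == "z":
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    raise ValueError(axis)


def rotation_matrix_zyx(
    rx: float, ry: float, rz: float, *, intrinsic: bool = True
) -> Orientation:
    """Build an orientation from successive rotations around z, then y, then x.

    The default is the intrinsic z-y'-x'' interpretation, whose matrix is the
    product ``Rz(rz) @ Ry(ry) @ Rx(rx)``.  With ``intrinsic=False`` the same
    sequence is read as extrinsic rotations about the fixed axes,
    ``Rx(rx) @ Ry(ry) @ Rz(rz)``.  The maneuvers of interest involve small
    combined angles, for which the two conventions nearly coincide; the switch
    exists because published controller descriptions rarely pin this down.
    """
    angles = (rx, ry, rz)
    if not all(np.isfinite(a) for a in angles):
        raise ValueError("rotation angles must be finite")
    rzm, rym, rxm = _elemental("z", rz), _elemental("y", ry), _elemental("x", rx)
    if intrinsic:
        return Orientation(rzm @ rym @ rxm)
    return Orientation(rxm @ rym @ rzm)


def matrix_from_axis_angle(aa: AxisAngle) -> Orientation:
    """Rodrigues' rotation formula: R = I + sin(t) K + (1 - cos(t)) K^2."""
    if aa.degenerate or aa.angle < DEGENERATE_ANGLE:
        return Orientation.identity()
    v = aa.axis / np.linalg.norm(aa.axis)
    k = np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])
    m = np.eye(3) + np.sin(aa.angle) * k + (1.0 - np.cos(aa.angle)) * (k @ k)
    return Orientation(m)


def axis_angle_from_matrix(orientation: Orientation) -> AxisAngle:
    """Extract the axis-angle representation of a rotation matrix.

    The angle comes from the trace, ``theta = arccos((tr R - 1) / 2)``.  For
    intermediate angles the axis is read from the skew-symmetric part of R.
    Near ``theta = pi`` the sine-based formula degenerates, so the axis is
    instead taken from the dominant column of ``(R + I) / 2``; near
    ``theta = 0`` the axis is undefined and the result is flagged degenerate
    with the default axis (0, 0, 1).
    """
    m = orientation.matrix
    cos_theta = np.clip((np.trace(m) - 1.0) / 2.0, -1.0, 1.0)
    theta = float(np.arccos(cos_theta))

    if theta < DEGENERATE_ANGLE:
        return AxisAngle(np.array([0.0, 0.0, 1.0]), 0.0, degenerate=True)

    if np.pi - theta > 1e-6:
        axis = np.array(
            [m[2, 1] - m[1, 2], m[0, 2] - m[2, 0], m[1, 0] - m[0, 1]]
        ) / (2.0 * np.sin(theta))
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            # trace noise on a near-identity matrix: no resolvable axis
            return AxisAngle(np.array([0.0, 0.0, 1.0]), 0.0, degenerate=True)
        return AxisAngle(axis / norm, theta)

    # theta ~ pi: (R + I) / 2 = v v^T + O(pi - theta); its largest-diagonal
    # column is parallel to the axis and numerically well conditioned.
    b = (m + np.eye(3)) / 2.0
    j = int(np.argmax(np.diag(b)))
    axis = b[:, j] / np.linalg.norm(b[:, j])
    # Fix the sign using the skew part where it is non-zero; at exactly pi the
    # sign is arbitrary (R(v, pi) == R(-v, pi)).
    skew = np.array([m[2, 1] - m[1, 2], m[0, 2] - m[2, 0], m[1, 0] - m[0, 1]])
    if np.dot(skew, axis) < 0.0:
        axis = -axis
    return AxisAngle(axis, theta)


def rotational_error(current: Orientation, reference: Orientation) -> AxisAngle:
    """Axis-angle of the relative rotation taking the reference to the current
    head orientation, expressed in the reference frame.

    The angle is the scalar error fed to the PID controller; the axis drives
    the intermuscular load sharing.
    """
    relative = Orientation(reference.matrix.T @ current.matrix)
    return axis_angle_from_matrix(relative)


def translational_error(
    head_cog: np.ndarray,
    t1_pos: np.ndarray,
    t1_yaw: float,
    reference_link: np.ndarray,
) -> TranslationalError:
    """Link-deviation error of the translational controller.

    The current T1-to-head link and the reference link are both expressed in
    a frame that follows T1 in rotations about the global z axis (yaw); the
    deviation angle is the angle between them.  The azimuth is the
    horizontal-plane direction of the head displacement relative to the
    reference link in that T1-local frame (0 = forward, +pi/2 = right).
    """
    head_cog = np.asarray(head_cog, dtype=float)
    t1_pos = np.asarray(t1_pos, dtype=float)
    reference_link = np.asarray(reference_link, dtype=float)
    ref_norm = np.linalg.norm(reference_link)
    if ref_norm <= 0.0:
        raise DegenerateGeometryError("reference link has zero length")

    link = head_cog - t1_pos
    link_norm = np.linalg.norm(link)
    if link_norm <= 0.0:
        raise DegenerateGeometryError("current T1-to-head link has zero length")

    # Rotate world vectors into the yaw-following T1 frame.
    yaw = _elemental("z", -t1_yaw)
    link_local = yaw @ link
    ref_local = reference_link  # captured in the T1-local frame at reference time

    cos_dev = np.clip(
        np.dot(link_local, ref_local) / (link_norm * ref_norm), -1.0, 1.0
    )
    deviation = float(np.arccos(cos_dev))

    delta = link_local - ref_local
    if np.hypot(delta[0], delta[1]) < 1e-12:
        azimuth = 0.0
    else:
        azimuth = float(np.arctan2(delta[1], delta[0]))
    return TranslationalError(deviation_angle=deviation, azimuth=azimuth)
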