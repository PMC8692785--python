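"""Rotation math for the two-axis ankle complex.

The ankle is modelled as two oblique, body-fixed hinge axes: a talocrural
axis fixed in the tibia (dorsiflexion +) and a subtalar axis fixed in the
talus (supination +).  Composite tibia-to-calcaneus rotations are resolved
post hoc to the non-orthogonal joint coordinate system (JCS) recommended by
the International Society of Biomechanics for the ankle complex:
dorsiflexion about a tibia-fixed axis, inversion about a floating axis, and
internal rotation about the calcaneus y-axis.

Frame convention (right limb): X anterior, Y superior, Z lateral.  Angles
cross the public API in degrees; radians are internal to the rotation math.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "AxisSet",
    "JointAngles",
    "JCSAngles",
    "MomentProjection",
    "GimbalLockError",
    "axis_from_inclinations",
    "rotation_about_axis",
    "compose_ankle_orientation",
    "jcs_compose",
    "jcs_decompose",
    "project_moment",
    "supination_for_inversion",
]

_UNIT_TOL = 1e-9
_GIMBAL_TOL = 1e-8


class GimbalLockError(ValueError):
    """JCS decomposition is singular (|inversion| at 90 degrees)."""


def _as_unit(v: Iterable[float], name: str = "axis") -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,) or not np.all(np.isfinite(a)):
        raise ValueError(f"{name} must be a finite 3-vector, got {v!r}")
    n = float(np.linalg.norm(a))
    if abs(n - 1.0) > _UNIT_TOL:
        raise ValueError(f"{name} must be unit length (norm {n:.3e})")
    return a


def axis_from_inclinations(superior_deg: float, medial_deg: float,
                           side: str = "right") -> np.ndarray:
    """Unit joint axis from its inclination to the anterior foot direction.

    ``superior_deg`` tilts the axis up out of the transverse plane and
    ``medial_deg`` swings it toward the midline.  For a right limb medial is
    the -Z direction; a left limb mirrors the Z component.
    """
    if not (math.isfinite(superior_deg) and math.isfinite(medial_deg)):
        raise ValueError("inclination angles must be finite")
    if abs(superior_deg) > 90.0:
        raise ValueError("superior inclination must satisfy |angle| <= 90 deg")
    if side not in ("right", "left"):
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")
    s = math.radians(superior_deg)
    m = math.radians(medial_deg)
    z = -math.cos(s) * math.sin(m)
    if side == "left":
        z = -z
    return np.array([math.cos(s) * math.cos(m), math.sin(s), z])


#: Inclination of the generic subtalar axis: 38 deg superior, 9 deg medial
#: to the anterior direction of the foot.
SUBTALAR_SUPERIOR_DEG = 38.0
SUBTALAR_MEDIAL_DEG = 9.0


@dataclass(frozen=True)
class AxisSet:
    """Anatomic joint axes and JCS conventions for one ankle.

    ``talocrural_axis`` lives in the tibia frame, ``subtalar_axis`` in the
    talus frame.  The talocrural axis defaults to pure mediolateral; its
    obliquity is configurable.  ``jcs_e1`` selects the JCS dorsiflexion
    axis: ``"talocrural"`` (the anatomic axis, the default) or
    ``"mediolateral"`` (a pure tibia Z axis, for convention studies).
    """

    talocrural_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    subtalar_axis: np.ndarray = field(
        default_factory=lambda: axis_from_inclinations(
            SUBTALAR_SUPERIOR_DEG, SUBTALAR_MEDIAL_DEG, "right"))
    side: str = "right"
    jcs_e1: str = "talocrural"

    def __post_init__(self):
        object.__setattr__(self, "talocrural_axis",
                           _as_unit(self.talocrural_axis, "talocrural_axis"))
        object.__setattr__(self, "subtalar_axis",
                           _as_unit(self.subtalar_axis, "subtalar_axis"))
        if self.side not in ("right", "left"):
            raise ValueError(f"side must be 'right' or 'left', got {self.side!r}")
        if self.jcs_e1 not in ("talocrural", "mediolateral"):
            raise ValueError("jcs_e1 must be 'talocrural' or 'mediolateral'")

    @property
    def e1_axis(self) -> np.ndarray:
        """JCS dorsiflexion axis in the tibia frame."""
        if self.jcs_e1 == "talocrural":
            return self.talocrural_axis
        return np.array([0.0, 0.0, 1.0])

    def to_dict(self) -> dict:
        return {
            "talocrural_axis": [float(c) for c in self.talocrural_axis],
            "subtalar_axis": [float(c) for c in self.subtalar_axis],
            "side": self.side,
            "jcs_e1": self.jcs_e1,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AxisSet":
        return cls(talocrural_axis=np.asarray(d["talocrural_axis"], float),
                   subtalar_axis=np.asarray(d["subtalar_axis"], float),
                   side=d.get("side", "right"),
                   jcs_e1=d.get("jcs_e1", "talocrural"))


@dataclass(frozen=True)
class JointAngles:
    """Anatomic joint angles in degrees.

    ``talocrural_deg``: dorsiflexion (+) / plantarflexion (-).
    ``subtalar_deg``: supination (+) / pronation (-).
    """

    talocrural_deg: float
    subtalar_deg: float

    def __post_init__(self):
        if not (math.isfinite(self.talocrural_deg)
                and math.isfinite(self.subtalar_deg)):
            raise ValueError("joint angles must be finite")


@dataclass(frozen=True)
class JCSAngles:
    """Ankle-complex JCS angles in degrees (dorsiflexion +, inversion +,
    internal rotation +)."""

    dorsiflexion_deg: float
    inversion_deg: float
    internal_rotation_deg: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dorsiflexion_deg, self.inversion_deg,
                self.internal_rotation_deg)


@dataclass(frozen=True)
class MomentProjection:
    """A ground-frame moment vector with its scalar projections (N m) onto
    named anatomic and JCS axes."""

    moment_vector: np.ndarray
    projections: Mapping[str, float]


def rotation_about_axis(axis: Iterable[float], angle_deg: float) -> np.ndarray:
    """Proper rotation matrix for a right-handed rotation about a unit axis
    (Rodrigues formula)."""
    k = np.asarray(axis, dtype=float)
    n = float(np.linalg.norm(k))
    if not np.all(np.isfinite(k)) or n < _UNIT_TOL:
        raise ValueError("rotation axis must be a finite non-zero vector")
    if abs(n - 1.0) > _UNIT_TOL:
        raise ValueError(f"rotation axis must be unit length (norm {n:.3e})")
    if not math.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    th = math.radians(angle_deg)
    K = np.array([[0.0, -k[2], k[1]],
                  [k[2], 0.0, -k[0]],
                  [-k[1], k[0], 0.0]])
    return np.eye(3) + math.sin(th) * K + (1.0 - math.cos(th)) * (K @ K)


def compose_ankle_orientation(joint_angles: JointAngles,
                              axis_set: AxisSet) -> np.ndarray:
    """Orientation of the calcaneus frame in the tibia frame.

    The talus rotates about the tibia-fixed talocrural axis first, then the
    calcaneus rotates about the talus-fixed subtalar axis:
    ``R = R_tc @ R_st`` (the subtalar axis components are expressed in the
    intermediate talus frame, so it composes on the right).
    """
    r_tc = rotation_about_axis(axis_set.talocrural_axis,
                               joint_angles.talocrural_deg)
    r_st = rotation_about_axis(axis_set.subtalar_axis,
                               joint_angles.subtalar_deg)
    return r_tc @ r_st


def _jcs_basis(axis_set: AxisSet) -> np.ndarray:
    """Orthonormal basis (columns) whose Z is the JCS dorsiflexion axis.

    With the default mediolateral e1 this is the identity; for an oblique
    e1 the anterior direction is re-orthogonalised against it.  The same
    basis is attached to the calcaneus so that the neutral pose decomposes
    to zero angles.
    """
    e1 = axis_set.e1_axis
    x = np.array([1.0, 0.0, 0.0])
    x = x - np.dot(x, e1) * e1
    nx = np.linalg.norm(x)
    if nx < 1e-9:  # e1 (nearly) anterior: fall back to superior reference
        x = np.array([0.0, 1.0, 0.0])
        x = x - np.dot(x, e1) * e1
        nx = np.linalg.norm(x)
    x = x / nx
    y = np.cross(e1, x)
    return np.column_stack([x, y, e1])


def jcs_compose(angles: JCSAngles, axis_set: AxisSet) -> np.ndarray:
    """Tibia-to-calcaneus rotation realising the given JCS angles
    (intrinsic Z-X'-Y'' sequence in the JCS-aligned basis)."""
    a, b, c = (math.radians(v) for v in angles.as_tuple())
    if axis_set.side == "left":
        b, c = -b, -c
    t = _jcs_basis(axis_set)
    ca, sa = math.cos(a), math.sin(a)
    cb, sb = math.cos(b), math.sin(b)
    cc, sc = math.cos(c), math.sin(c)
    rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cb, -sb], [0.0, sb, cb]])
    ry = np.array([[cc, 0.0, sc], [0.0, 1.0, 0.0], [-sc, 0.0, cc]])
    return t @ (rz @ rx @ ry) @ t.T


def jcs_decompose(R: np.ndarray, axis_set: AxisSet) -> JCSAngles:
    """Resolve a tibia-to-calcaneus rotation into ankle-complex JCS angles.

    The sequence is dorsiflexion (+) about the tibia-fixed e1 axis,
    inversion (+) about the floating axis, internal rotation (+) about the
    calcaneus y-axis.  Raises :class:`GimbalLockError` when the inversion
    angle reaches 90 degrees and the first/third axes align.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-8 or np.linalg.det(R) < 0:
        raise ValueError("matrix is not a proper rotation")
    t = _jcs_basis(axis_set)
    m = t.T @ R @ t
    # m = Rz(a) @ Rx(b) @ Ry(c):  m[2,1] = sin b,
    # m[2,0] = -cos b sin c, m[2,2] = cos b cos c,
    # m[0,1] = -sin a cos b, m[1,1] = cos a cos b.
    sb = min(1.0, max(-1.0, m[2, 1]))
    cb = math.sqrt(max(0.0, 1.0 - sb * sb))
    if cb < _GIMBAL_TOL:
        raise GimbalLockError(
            "JCS decomposition singular: inversion at +/-90 deg")
    b = math.asin(sb)
    c = math.atan2(-m[2, 0], m[2, 2])
    a = math.atan2(-m[0, 1], m[1, 1])
    if axis_set.side == "left":
        b, c = -b, -c
    return JCSAngles(math.degrees(a), math.degrees(b), math.degrees(c))


def project_moment(moment_vector: Iterable[float],
                   axis_unit_vector: Iterable[float]) -> float:
    """Orthogonal projection (dot product) of a moment onto a unit axis;
    the sign follows the right-hand rule about the axis."""
    m = np.asarray(moment_vector, dtype=float)
    if m.shape != (3,) or not np.all(np.isfinite(m)):
        raise ValueError("moment must be a finite 3-vector")
    a = _as_unit(axis_unit_vector, "projection axis")
    return float(np.dot(m, a))


def project_moment_set(moment_vector: Iterable[float], axis_set: AxisSet,
                       talocrural_world: np.ndarray,
                       subtalar_world: np.ndarray,
                       R: np.ndarray) -> MomentProjection:
    """Project a ground-frame moment onto the anatomic axes and the three
    JCS axes for the pose ``R`` (calcaneus in tibia/ground frame)."""
    t = _jcs_basis(axis_set)
    e1 = t[:, 2]
    e3 = R @ t[:, 1]  # calcaneus y axis, world frame
    e2 = np.cross(e3, e1)
    n2 = np.linalg.norm(e2)
    if n2 < _GIMBAL_TOL:
        raise GimbalLockError("floating axis undefined at gimbal lock")
    e2 = e2 / n2
    m = np.asarray(moment_vector, dtype=float)
    proj = {
        "talocrural": project_moment(m, talocrural_world),
        "subtalar": project_moment(m, subtalar_world),
        "jcs_sagittal": project_moment(m, e1),
        "jcs_frontal": project_moment(m, e2),
        "jcs_transverse": project_moment(m, e3 / np.linalg.norm(e3)),
    }
    return MomentProjection(moment_vector=m, projections=proj)


def supination_for_inversion(target_inversion_deg: float,
                             plantarflexion_deg: float,
                             axis_set: AxisSet | None = None,
                             bracket: tuple[float, float] = (0.5, 89.0),
                             ) -> float:
    """Subtalar supination (deg) that, combined with the given talocrural
    plantarflexion, yields the target JCS inversion angle.

    Used for cross-convention bookkeeping: e.g. cadaveric ligament-failure
    thresholds are reported as JCS inversion, while the simulation's primary
    outcome is anatomic supination about the oblique subtalar axis.
    """
    from scipy.optimize import brentq

    axes = axis_set if axis_set is not None else AxisSet()

    def f(theta: float) -> float:
        ja = JointAngles(talocrural_deg=-plantarflexion_deg,
                         subtalar_deg=theta)
        return (jcs_decompose(compose_ankle_orientation(ja, axes), axes)
                .inversion_deg - target_inversion_deg)

    return float(brentq(f, *bracket, xtol=1e-10))
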