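"""Rigid-body transform algebra for six-degree-of-freedom setup corrections.

Conventions, fixed package-wide:

* Right-handed room coordinate system; rotation angles are in degrees,
  positive counter-clockwise when looking down the axis toward the origin
  (an IEC-61217-like convention).
* The 6D parameterization is ``(tx, ty, tz, rx, ry, rz)``: translations in
  mm, rotations in degrees, composed about *fixed* room axes as
  ``R = Rz(rz) @ Ry(ry) @ Rx(rx)`` (extrinsic x-y-z).  ``rx`` is pitch
  about the couch-lateral axis, ``ry`` yaw about the couch-vertical axis,
  ``rz`` roll about the couch-longitudinal axis.  Setup rotations in this
  application are a few degrees at most, so the choice of composition
  order is second-order, but one order must be pinned for reproducibility.
* Every :class:`RigidTransform` carries an explicit ``reference_point``
  ``c``; the mapping is ``p -> R @ (p - c) + c + t``.  Clinical 6D couch
  corrections are expressed about the machine isocenter, so the reference
  point matters whenever the rotation is non-trivial.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import DegenerateOrientationError, InvalidArgumentError

__all__ = [
    "EulerAngles6D",
    "RigidTransform",
    "euler_to_transform",
    "transform_to_euler",
    "compose",
    "rereference",
]

#: Tolerance for orthogonality / unit-determinant checks on rotations.
ORTHO_TOL = 1e-9

#: Serialization tag for the package-wide Euler convention.
CONVENTION = "zyx-fixed-deg"

#: Gimbal-lock guard: refuse Euler decomposition when |yaw| is within this
#: many degrees of 90.  Never triggered in the +/-3 degree setup regime.
GIMBAL_GUARD_DEG = 1e-6


def _as_vector3(v, name: str = "vector") -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(-1)
    if a.shape != (3,):
        raise InvalidArgumentError(f"{name} must have 3 components, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InvalidArgumentError(f"{name} has non-finite components: {a}")
    return a


@dataclass(frozen=True)
class EulerAngles6D:
    """A 6D setup correction: translations in mm, rotations in degrees.

    ``rx``/``ry``/``rz`` are pitch/yaw/roll about the couch lateral,
    vertical and longitudinal axes.  Valid only in the ``|angle| < 90``
    regime where the Euler parameterization is bijective.
    """

    tx: float
    ty: float
    tz: float
    rx: float
    ry: float
    rz: float

    def __post_init__(self) -> None:
        vals = (self.tx, self.ty, self.tz, self.rx, self.ry, self.rz)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidArgumentError(f"non-finite 6D parameters: {vals}")
        # |yaw| = 90 is the gimbal singularity of the z-y-x decomposition;
        # pitch/roll may reach a quarter turn.
        if abs(self.ry) >= 90.0:
            raise InvalidArgumentError(f"|ry| must be < 90 degrees, got {self.ry}")
        for name in ("rx", "rz"):
            if abs(getattr(self, name)) > 90.0:
                raise InvalidArgumentError(
                    f"|{name}| must be <= 90 degrees, got {getattr(self, name)}"
                )

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz], dtype=float)

    @property
    def rotation_degrees(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz], dtype=float)

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.tx, self.ty, self.tz, self.rx, self.ry, self.rz)


def _check_rotation(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3) or not np.all(np.isfinite(r)):
        raise InvalidArgumentError("rotation must be a finite 3x3 matrix")
    if np.max(np.abs(r.T @ r - np.eye(3))) > 1e-8:
        raise InvalidArgumentError("rotation matrix is not orthogonal")
    if abs(np.linalg.det(r) - 1.0) > 1e-8:
        raise InvalidArgumentError("rotation matrix determinant is not +1 (reflection?)")
    return r


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``p -> R @ (p - c) + c + t``.

    Parameters
    ----------
    rotation : (3, 3) ndarray
        Proper orthogonal matrix (``R^T R = I``, ``det R = +1``).
    translation : (3,) ndarray
        Translation ``t`` in mm, applied after rotating about ``c``.
    reference_point : (3,) ndarray
        The point ``c`` about which the rotation is expressed; default
        origin.  Use :func:`rereference` to move it without changing the
        mapping.
    """

    rotation: np.ndarray
    translation: np.ndarray
    reference_point: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        object.__setattr__(self, "translation", _as_vector3(self.translation, "translation"))
        object.__setattr__(
            self, "reference_point", _as_vector3(self.reference_point, "reference_point")
        )

    # -- construction -----------------------------------------------------

    @classmethod
    def identity(cls, reference_point=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), reference_point)

    # -- mapping ----------------------------------------------------------

    def apply(self, points) -> np.ndarray:
        """Apply the transform to a point ``(3,)`` or point array ``(n, 3)``."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        if p.shape[1] != 3:
            raise InvalidArgumentError(f"points must be (n, 3), got {p.shape}")
        c = self.reference_point
        out = (p - c) @ self.rotation.T + c + self.translation
        return out[0] if single else out

    def inverse(self) -> "RigidTransform":
        """The transform undoing this one, about the same reference point."""
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation, self.reference_point)

    # -- interchange ------------------------------------------------------

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix of the mapping (reference point folded in)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        c = self.reference_point
        m[:3, 3] = self.translation + c - self.rotation @ c
        return m

    def to_json_dict(self) -> dict:
        ang = transform_to_euler(self)
        return {
            "tx": ang.tx, "ty": ang.ty, "tz": ang.tz,
            "rx": ang.rx, "ry": ang.ry, "rz": ang.rz,
            "ref": [float(x) for x in self.reference_point],
            "convention": CONVENTION,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=2)

    @classmethod
    def from_json_dict(cls, d: dict) -> "RigidTransform":
        conv = d.get("convention", CONVENTION)
        if conv != CONVENTION:
            raise InvalidArgumentError(f"unsupported transform convention: {conv!r}")
        ang = EulerAngles6D(d["tx"], d["ty"], d["tz"], d["rx"], d["ry"], d["rz"])
        return euler_to_transform(ang, d.get("ref", (0.0, 0.0, 0.0)))

    @classmethod
    def from_json(cls, s: str) -> "RigidTransform":
        return cls.from_json_dict(json.loads(s))

    def matrix_text(self) -> str:
        """Plain-text 4x4 homogeneous matrix (one row per line)."""
        return "\n".join(" ".join(f"{v:.12g}" for v in row) for row in self.matrix())


def euler_to_transform(angles: EulerAngles6D, reference_point=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Build a rigid transform from 6D parameters about ``reference_point``.

    The rotation is ``R = Rz(rz) @ Ry(ry) @ Rx(rx)`` (fixed axes); the
    translation is applied after rotating about the reference point.
    """
    if not isinstance(angles, EulerAngles6D):
        angles = EulerAngles6D(*angles)
    # scipy's lowercase 'xyz' is the extrinsic (fixed-axes) convention:
    # rotate about room x, then room y, then room z == Rz @ Ry @ Rx.
    r = Rotation.from_euler("xyz", angles.rotation_degrees, degrees=True).as_matrix()
    return RigidTransform(r, angles.translation, reference_point)


def transform_to_euler(t: RigidTransform) -> EulerAngles6D:
    """Decompose a transform into 6D parameters (degrees, fixed-axes z-y-x).

    Raises
    ------
    DegenerateOrientationError
        If the yaw angle is within ``GIMBAL_GUARD_DEG`` of +/-90 degrees,
        where the decomposition is ill-conditioned.
    """
    r = t.rotation
    sy = float(np.clip(-r[2, 0], -1.0, 1.0))
    ry = math.degrees(math.asin(sy))
    if 90.0 - abs(ry) < GIMBAL_GUARD_DEG:
        raise DegenerateOrientationError(
            f"yaw {ry:.9f} deg is within {GIMBAL_GUARD_DEG} deg of gimbal lock"
        )
    rx = math.degrees(math.atan2(r[2, 1], r[2, 2]))
    rz = math.degrees(math.atan2(r[1, 0], r[0, 0]))
    tx, ty, tz = t.translation
    return EulerAngles6D(tx, ty, tz, rx, ry, rz)


def compose(outer: RigidTransform, inner: RigidTransform) -> RigidTransform:
    """The transform applying ``inner`` first, then ``outer``.

    Both operands must be expressed about the same reference point (use
    :func:`rereference` first if not); the result shares it.
    """
    if np.max(np.abs(outer.reference_point - inner.reference_point)) > 1e-9:
        raise InvalidArgumentError(
            "compose requires transforms about the same reference point; "
            f"got {outer.reference_point} vs {inner.reference_point}"
        )
    r = outer.rotation @ inner.rotation
    tvec = outer.rotation @ inner.translation + outer.translation
    return RigidTransform(r, tvec, outer.reference_point)


def rereference(t: RigidTransform, new_reference) -> RigidTransform:
    """Express the same mapping about a different reference point.

    The rotation is unchanged; the translation absorbs the shift:
    ``t' = t - (I - R) @ (c' - c)``, which leaves the image of every
    point identical.
    """
    c_new = _as_vector3(new_reference, "new_reference")
    shift = c_new - t.reference_point
    t_new = t.translation - (shift - t.rotation @ shift)
    return RigidTransform(t.rotation, t_new, c_new)
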