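"""Coordinate frames and rotation utilities.

Two right-handed Cartesian frames share the linac isocenter as origin:

``IEC``
    Machine-centric (IEC 61217 patient support convention): +X to the
    patient's right, +Y toward the gantry, +Z up.  Room geometry — tube
    focal points, panel centers, renderer matrices — lives here.

``HFS``
    Patient-centric for a head-first supine scan: +X right, +Y down
    (posterior), +Z toward the head.  DICOM-derived data (CT volume,
    RT Plan isocenter) lives here.

Matching the axis semantics gives the fixed linear map

    IEC (x, y, z)  ->  HFS (x, -z, y)

i.e. "up" in the room is "minus down" on the patient and the room's
"toward gantry" is the patient's "toward head".  Only the HFS patient
orientation is supported; other scan orientations require an additional
conversion and are rejected explicitly by the DICOM reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import FrameError, GeometryError

IEC = "IEC"
HFS = "HFS"

#: Linear map taking IEC components to HFS components (a proper rotation).
IEC_TO_HFS_MATRIX = np.array(
    [
        [1.0, 0.0, 0.0],
        [0.0, 0.0, -1.0],
        [0.0, 1.0, 0.0],
    ]
)

HFS_TO_IEC_MATRIX = IEC_TO_HFS_MATRIX.T

_UNIT_TOL = 1e-12
_ORTHO_TOL = 1e-10


@dataclass(frozen=True)
class Vec3:
    """A 3-vector in mm (or dimensionless for unit directions) with a frame tag.

    Frame bookkeeping is deliberately strict: arithmetic between vectors
    tagged with different frames raises :class:`~stereodrr.errors.FrameError`
    instead of silently producing garbage geometry.
    """

    v: np.ndarray
    frame: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.v, dtype=float)
        if arr.shape != (3,):
            raise ValueError(f"Vec3 needs shape (3,), got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("Vec3 components must be finite")
        if self.frame not in (IEC, HFS):
            raise FrameError(f"unknown frame tag {self.frame!r}")
        object.__setattr__(self, "v", arr)

    # -- frame-checked arithmetic -------------------------------------
    def _check(self, other: "Vec3") -> None:
        if not isinstance(other, Vec3):
            raise TypeError("expected Vec3")
        if other.frame != self.frame:
            raise FrameError(
                f"cannot combine {self.frame} vector with {other.frame} vector"
            )

    def __add__(self, other: "Vec3") -> "Vec3":
        self._check(other)
        return Vec3(self.v + other.v, self.frame)

    def __sub__(self, other: "Vec3") -> "Vec3":
        self._check(other)
        return Vec3(self.v - other.v, self.frame)

    def __mul__(self, s: float) -> "Vec3":
        return Vec3(self.v * float(s), self.frame)

    __rmul__ = __mul__

    def __neg__(self) -> "Vec3":
        return Vec3(-self.v, self.frame)

    def dot(self, other: "Vec3") -> float:
        self._check(other)
        return float(self.v @ other.v)

    def cross(self, other: "Vec3") -> "Vec3":
        self._check(other)
        return Vec3(np.cross(self.v, other.v), self.frame)

    def norm(self) -> float:
        return float(np.linalg.norm(self.v))

    def unit(self) -> "Vec3":
        n = self.norm()
        if n < _UNIT_TOL:
            raise GeometryError("cannot normalize a (near-)zero vector")
        return Vec3(self.v / n, self.frame)

    def is_unit(self, tol: float = 1e-12) -> bool:
        return abs(self.norm() - 1.0) <= tol

    @property
    def x(self) -> float:
        return float(self.v[0])

    @property
    def y(self) -> float:
        return float(self.v[1])

    @property
    def z(self) -> float:
        return float(self.v[2])


def vec3(x: float, y: float, z: float, frame: str) -> Vec3:
    """Convenience constructor for a frame-tagged vector."""
    return Vec3(np.array([x, y, z], dtype=float), frame)


def iec_to_hfs(v: Vec3) -> Vec3:
    """Convert a machine-centric (IEC) vector to patient-centric HFS.

    ``(x, y, z)_IEC -> (x, -z, y)_HFS``.
    """
    if v.frame != IEC:
        raise FrameError(f"iec_to_hfs expects an IEC vector, got {v.frame}")
    return Vec3(IEC_TO_HFS_MATRIX @ v.v, HFS)


def hfs_to_iec(v: Vec3) -> Vec3:
    """Exact inverse of :func:`iec_to_hfs`."""
    if v.frame != HFS:
        raise FrameError(f"hfs_to_iec expects an HFS vector, got {v.frame}")
    return Vec3(HFS_TO_IEC_MATRIX @ v.v, IEC)


def is_rotation(m: np.ndarray, tol: float = _ORTHO_TOL) -> bool:
    """True when ``m`` is a proper rotation: orthonormal with det +1."""
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        return False
    return (
        np.allclose(m.T @ m, np.eye(3), atol=tol)
        and abs(np.linalg.det(m) - 1.0) <= tol
    )


def rot_axis_angle(axis: np.ndarray | Vec3, angle: float) -> np.ndarray:
    """Rotation matrix about a unit ``axis`` by ``angle`` radians.

    Counterclockwise (right-hand rule) when viewed from the axis tip,
    matching the convention used for the room's rotation operators.
    """
    a = axis.v if isinstance(axis, Vec3) else np.asarray(axis, dtype=float)
    if a.shape != (3,):
        raise ValueError("axis must be a 3-vector")
    n = np.linalg.norm(a)
    if n < _UNIT_TOL:
        raise GeometryError("degenerate (zero-length) rotation axis")
    if abs(n - 1.0) > 1e-8:
        raise GeometryError(f"rotation axis must be unit length, |axis|={n}")
    if not np.isfinite(angle):
        raise ValueError("rotation angle must be finite")
    return Rotation.from_rotvec(a * float(angle)).as_matrix()


def rot_x(angle: float) -> np.ndarray:
    """Counterclockwise rotation about +X by ``angle`` radians."""
    return rot_axis_angle(np.array([1.0, 0.0, 0.0]), angle)


def rot_y(angle: float) -> np.ndarray:
    return rot_axis_angle(np.array([0.0, 1.0, 0.0]), angle)


def rot_z(angle: float) -> np.ndarray:
    return rot_axis_angle(np.array([0.0, 0.0, 1.0]), angle)
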