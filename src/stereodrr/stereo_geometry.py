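"""First-principles stereoscopic imager geometry from four in-room measurements.

The dual-imager system has floor-mounted kV tubes and ceiling-mounted flat
panels.  Four numbers pin down the whole geometry:

* ``SID`` — source-to-image distance (tube focal point to panel center), mm
* ``SOD`` — source-to-object distance (tube focal point to isocenter), mm
* ``theta`` — incline of the oblique plane (the plane spanned by both
  central beamlines) with respect to the floor, rad
* ``phi`` — crossing angle between the two central beamlines, rad

All vectors here are machine-centric (IEC): +X right, +Y toward gantry,
+Z up.  Imager 1 has its tube on the -X side (panel on +X); imager 2 is
the mirror image through the X=0 plane.

The central beamline of imager 1 is

    d1 = normalize( R_X(pi/2 - theta) @ (tan(phi/2), 0, 1)^T )

which by construction satisfies angle(d1, d2) = phi and places the plane
span(d1, d2) at dihedral angle theta with the floor.  The tube focal point
solves 0 = t + SOD*d, the panel center is c = t + SID*d, and the in-plane
panel axes follow from rotating the beamline about its (quarter-turned)
floor projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .coords import IEC, Vec3, rot_axis_angle, rot_x, rot_z, vec3
from .errors import GeometryError

_EPS = 1e-12

#: Plausible room measurements for a floor/ceiling stereoscopic kV system.
#: The true clinical values are vendor-documented and not public; these give
#: SID/SOD = 2, i.e. the ~10 cm field of view at isocenter of a 200 mm panel.
#: Non-authoritative — always prefer a real configuration file.
DEFAULT_SID_MM = 1800.0
DEFAULT_SOD_MM = 900.0
DEFAULT_THETA_RAD = math.radians(40.0)
DEFAULT_PHI_RAD = math.radians(62.0)


@dataclass(frozen=True)
class RoomGeometry:
    """The four in-room measurements defining the stereo system."""

    sid: float = DEFAULT_SID_MM
    sod: float = DEFAULT_SOD_MM
    theta: float = DEFAULT_THETA_RAD
    phi: float = DEFAULT_PHI_RAD

    def __post_init__(self) -> None:
        if not (self.sid > 0 and self.sod > 0):
            raise GeometryError("SID and SOD must be positive (mm)")
        if not self.sid > self.sod:
            raise GeometryError(
                f"SID ({self.sid}) must exceed SOD ({self.sod}): the panel "
                "sits beyond the isocenter along the beam"
            )
        if not (0.0 < self.theta < math.pi / 2):
            raise GeometryError("theta must lie strictly in (0, pi/2)")
        if not (0.0 < self.phi < math.pi):
            raise GeometryError("phi must lie strictly in (0, pi)")


@dataclass(frozen=True)
class ImagerFrame:
    """One imager's complete geometry: focal point, beamline, panel frame.

    ``p_x``, ``p_y`` span the panel plane and ``{p_x, p_y, d}`` is a
    right-handed orthonormal triad (p_x x p_y = d); the central beamline is
    orthogonal to the panel by construction.
    """

    imager: int
    t: Vec3  # tube focal point, IEC mm
    d: Vec3  # central beamline direction, IEC unit
    c: Vec3  # panel center, IEC mm
    p_x: Vec3  # panel in-plane x axis, IEC unit
    p_y: Vec3  # panel in-plane y axis, IEC unit

    def __post_init__(self) -> None:
        if self.imager not in (1, 2):
            raise GeometryError("imager index must be 1 or 2")
        for v in (self.t, self.d, self.c, self.p_x, self.p_y):
            if v.frame != IEC:
                raise GeometryError("ImagerFrame vectors must be IEC-tagged")
        triad = np.stack([self.p_x.v, self.p_y.v, self.d.v])
        if not np.allclose(triad @ triad.T, np.eye(3), atol=1e-10):
            raise GeometryError("{p_x, p_y, d} must be orthonormal")
        if not np.allclose(np.cross(self.p_x.v, self.p_y.v), self.d.v, atol=1e-10):
            raise GeometryError("panel triad must be right-handed (p_x x p_y = d)")

    @property
    def sid(self) -> float:
        """Source-to-image distance recovered from the frame, mm."""
        return (self.c - self.t).norm()

    @property
    def sod(self) -> float:
        """Source-to-object distance recovered from the frame, mm."""
        return self.t.norm()


def central_beam_direction(theta: float, phi: float, imager: int) -> Vec3:
    """Unit central-beamline direction for one imager (IEC).

    Satisfies angle(d1, d2) = phi, dihedral(span(d1, d2), floor) = theta and
    d_Z > 0 (the beam proceeds diagonally upward from the floor tube).
    Imager 2 is imager 1 mirrored through the X = 0 plane.
    """
    if imager not in (1, 2):
        raise GeometryError("imager index must be 1 or 2")
    if not (0.0 < theta < math.pi / 2):
        raise GeometryError("theta must lie strictly in (0, pi/2)")
    if not (0.0 < phi < math.pi):
        raise GeometryError("phi must lie strictly in (0, pi)")
    v = rot_x(math.pi / 2 - theta) @ np.array([math.tan(phi / 2), 0.0, 1.0])
    v /= np.linalg.norm(v)
    if imager == 2:
        v = v * np.array([-1.0, 1.0, 1.0])
    return Vec3(v, IEC)


def focal_point(d: Vec3, sod: float) -> Vec3:
    """Tube focal point t solving 0 = t + SOD*d, i.e. t = -SOD*d (IEC mm)."""
    if sod <= 0:
        raise GeometryError("SOD must be positive")
    if not d.is_unit(1e-9):
        raise GeometryError("beam direction must be a unit vector")
    return (-sod) * d


def panel_center(t: Vec3, d: Vec3, sid: float) -> Vec3:
    """Flat-panel center c = t + SID*d (IEC mm)."""
    if sid <= 0:
        raise GeometryError("SID must be positive")
    if not d.is_unit(1e-9):
        raise GeometryError("beam direction must be a unit vector")
    return t + sid * d


def panel_axes(d: Vec3) -> tuple[Vec3, Vec3]:
    """In-plane panel axes (p_x, p_y) for beam direction ``d``.

    Construction: project d onto the floor and renormalize, quarter-turn the
    projection about +Z, then rotate d a quarter turn about that axis to get
    p_y; finally p_x = p_y x d closes the right-handed triad.  A (near-)
    vertical beam has no floor projection and is rejected.
    """
    if not d.is_unit(1e-9):
        raise GeometryError("beam direction must be a unit vector")
    floor = np.array([d.x, d.y, 0.0])
    n = np.linalg.norm(floor)
    if n < 1e-9:
        raise GeometryError(
            "vertical beam: floor projection degenerates, panel axes undefined"
        )
    d_prime = rot_z(math.pi / 2) @ (floor / n)
    p_y = Vec3(rot_axis_angle(d_prime, math.pi / 2) @ d.v, IEC)
    p_x = p_y.cross(d)
    # d' is orthogonal to d, so the Rodrigues quarter turn reduces to a
    # cross product; guard against accumulated error.
    assert np.allclose(p_y.v, np.cross(d_prime, d.v), atol=1e-10)
    return p_x.unit(), p_y.unit()


def imager_frame(room: RoomGeometry, imager: int) -> ImagerFrame:
    """Full :class:`ImagerFrame` for one imager of a :class:`RoomGeometry`."""
    d = central_beam_direction(room.theta, room.phi, imager)
    t = focal_point(d, room.sod)
    c = panel_center(t, d, room.sid)
    p_x, p_y = panel_axes(d)
    return ImagerFrame(imager=imager, t=t, d=d, c=c, p_x=p_x, p_y=p_y)


def stereo_frames(room: RoomGeometry) -> tuple[ImagerFrame, ImagerFrame]:
    """Both imager frames of the stereo pair."""
    return imager_frame(room, 1), imager_frame(room, 2)


def crossing_angle(d1: Vec3, d2: Vec3) -> float:
    """Angle between the two central beamlines, rad."""
    return float(np.arccos(np.clip(d1.dot(d2), -1.0, 1.0)))


def oblique_plane_angle(d1: Vec3, d2: Vec3) -> float:
    """Dihedral angle between span(d1, d2) and the floor (Z = 0), rad."""
    n = np.cross(d1.v, d2.v)
    nn = np.linalg.norm(n)
    if nn < _EPS:
        raise GeometryError("beamlines are parallel; oblique plane undefined")
    cos_to_floor_normal = abs(n[2]) / nn
    return float(np.arccos(np.clip(cos_to_floor_normal, -1.0, 1.0)))
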