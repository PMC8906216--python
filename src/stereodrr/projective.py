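"""Projective operator stack: renderer-matrix composition and decomposition.

A renderer matrix encodes the full pinhole imaging chain for one imager as
a product of linear operators on real projective 3-space,

    M = S_NDC . S_det . P . R . T

with T the camera translation to the tube focal point, R the homogenized
transposed panel direction cosines, P the projectional calibration (focal
length SID), S_det the mm-to-pixel detector scaling with corner shifts
(cx, cy), and optionally S_NDC the normalized-device-coordinate scaling.
After the projection, the third and fourth rows of the 4x4 product carry
the same (homogeneous) information, so the matrix is stored as 3x4 with
the homogeneous row third.

Going the other way, the left 3x3 block of a stored (denormalized) matrix
factors by RQ decomposition into the upper-triangular detector-scaled
projection P_det times the orthogonal rotation Q, from which SID, (cx, cy),
the focal point and the direction cosines are read out; the DRR origin
(world position of the image's upper-left corner) then follows in patient
(HFS) coordinates.

Pixel-shift convention: a point at camera coordinates (x, y, z) lands at
pixel u = SID*x/(z*sx) + cx, so the central beamline strikes pixel (cx, cy)
and a *centered* W x H image has cx = W/2, cy = H/2; the image's upper-left
corner sits at detector-plane position (-cx*sx, -cy*sy) mm relative to the
panel center, which is exactly the corner term in the DRR-origin formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .coords import HFS, IEC, IEC_TO_HFS_MATRIX, Vec3, is_rotation
from .errors import DecompositionError, GeometryError
from .stereo_geometry import ImagerFrame

_ISO_H = np.array([0.0, 0.0, 0.0, 1.0])  # homogeneous linac isocenter


@dataclass(frozen=True)
class DetectorModel:
    """Flat-panel detector sampling model.

    The standard panel has a 200 x 200 mm^2 field of view read out at
    512 x 512 pixels after 2x2 binning, giving sx = sy = 200/512
    = 0.390625 mm/pix; unbinned data halve the spacings.  ``cx, cy`` are
    the pixel shifts of the projection center (see module docstring);
    ``cx = W/2, cy = H/2`` centers the image on the central beamline.
    """

    sx: float = 200.0 / 512.0
    sy: float = 200.0 / 512.0
    cx: float = 256.0
    cy: float = 256.0
    width: int = 512
    height: int = 512
    binning: int = 2

    def __post_init__(self) -> None:
        if self.sx <= 0 or self.sy <= 0:
            raise GeometryError("pixel spacings must be positive")
        if self.width <= 0 or self.height <= 0:
            raise GeometryError("detector dimensions must be positive")
        if self.binning not in (1, 2):
            raise GeometryError("binning must be 1 or 2")

    @classmethod
    def standard(cls, fov_mm: float = 200.0, pixels: int = 512,
                 binning: int = 2) -> "DetectorModel":
        """Centered detector for a given panel FOV and (binned) resolution.

        ``binning=2`` is the clinical standard; ``binning=1`` halves the
        pixel spacing for the same stored resolution.
        """
        s = fov_mm / pixels / (2 // binning)
        return cls(sx=s, sy=s, cx=pixels / 2.0, cy=pixels / 2.0,
                   width=pixels, height=pixels, binning=binning)

    def scaled(self, pixels: int) -> "DetectorModel":
        """Same physical panel resampled to ``pixels`` x ``pixels``."""
        f = self.width / pixels
        return DetectorModel(sx=self.sx * f, sy=self.sy * f,
                             cx=self.cx / f, cy=self.cy / f,
                             width=pixels, height=pixels, binning=self.binning)


@dataclass(frozen=True)
class RendererMatrix:
    """A 3x4 projective renderer matrix (row-major), IEC convention."""

    m: np.ndarray
    imager: int = 1
    normalized: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.m, dtype=float)
        if arr.shape != (3, 4):
            raise GeometryError(f"renderer matrix must be 3x4, got {arr.shape}")
        if np.linalg.matrix_rank(arr) < 3:
            raise DecompositionError("renderer matrix must have rank 3")
        object.__setattr__(self, "m", arr)

    def wc_fixed(self) -> "RendererMatrix":
        """Scale by the sign of the homogeneous row applied to the isocenter.

        Enforces the wc condition: rendered points (in particular the
        isocenter) must have positive homogeneous coordinate, i.e. sit on
        the viewing side of the camera.
        """
        w = float(self.m[2] @ _ISO_H)
        if w == 0.0:
            raise DecompositionError(
                "isocenter maps to zero homogeneous coordinate; wc sign undefined"
            )
        s = 1.0 if w > 0 else -1.0
        return RendererMatrix(self.m * s, self.imager, self.normalized)


@dataclass(frozen=True)
class DecomposedGeometry:
    """Imaging geometry extracted from a renderer matrix, in HFS coordinates.

    ``direction`` columns are (p_x, p_y, d); ``drr_origin`` is the world
    position of the image's upper-left corner on the panel plane.
    ``det_q`` reports the determinant of the orthogonal RQ factor: -1 flags
    a residual reflection (left-handed detector axes) instead of silently
    absorbing it.
    """

    sid: float
    cx: float
    cy: float
    focal_point: np.ndarray  # (3,) HFS mm
    direction: np.ndarray  # (3,3), columns p_x, p_y, d in HFS
    drr_origin: np.ndarray  # (3,) HFS mm
    det_q: float = 1.0

    def __post_init__(self) -> None:
        fp = np.asarray(self.focal_point, dtype=float).reshape(3)
        D = np.asarray(self.direction, dtype=float)
        og = np.asarray(self.drr_origin, dtype=float).reshape(3)
        if self.sid <= 0:
            raise GeometryError("decomposed SID must be positive")
        if not np.allclose(D.T @ D, np.eye(3), atol=1e-8):
            raise GeometryError("direction cosines must be orthonormal")
        object.__setattr__(self, "focal_point", fp)
        object.__setattr__(self, "direction", D)
        object.__setattr__(self, "drr_origin", og)

    @classmethod
    def from_imager_frame(cls, frame: ImagerFrame,
                          det: DetectorModel) -> "DecomposedGeometry":
        """First-principles geometry: no matrices involved.

        The DRR origin is placed directly at the physical upper-left panel
        corner c - cx*sx*p_x - cy*sy*p_y, converted to HFS.  Serves as the
        independent counterpart to matrix decomposition.
        """
        C = IEC_TO_HFS_MATRIX
        t = C @ frame.t.v
        D = C @ np.column_stack([frame.p_x.v, frame.p_y.v, frame.d.v])
        corner = C @ (
            frame.c.v - det.cx * det.sx * frame.p_x.v - det.cy * det.sy * frame.p_y.v
        )
        return cls(sid=frame.sid, cx=det.cx, cy=det.cy, focal_point=t,
                   direction=D, drr_origin=corner, det_q=1.0)


# ----------------------------------------------------------------------
# Elementary operators (4x4 on P3)
# ----------------------------------------------------------------------

def translation_matrix(t: Vec3 | np.ndarray) -> np.ndarray:
    """Camera translation T sending the focal point ``t`` to the origin."""
    tv = t.v if isinstance(t, Vec3) else np.asarray(t, dtype=float)
    T = np.eye(4)
    T[:3, 3] = -tv
    return T


def rotation_matrix_homogeneous(p_x: Vec3, p_y: Vec3, d: Vec3) -> np.ndarray:
    """Homogenized transposed direction cosines: rows p_x, p_y, d.

    After R the camera looks along +z (the central beamline).
    """
    B = np.stack([p_x.v, p_y.v, d.v])
    if not is_rotation(B.T):
        raise GeometryError("panel triad must be right-handed orthonormal")
    R = np.eye(4)
    R[:3, :3] = B
    return R


def calibration_matrix(sid: float) -> np.ndarray:
    """Projectional calibration P: pinhole projection with focal length SID."""
    if sid <= 0:
        raise GeometryError("SID must be positive")
    P = np.zeros((4, 4))
    P[0, 0] = P[1, 1] = P[2, 2] = sid
    P[3, 2] = 1.0
    return P


def detector_scaling(det: DetectorModel) -> np.ndarray:
    """Detector scaling S_det: image-plane mm to pixels plus corner shifts."""
    S = np.array(
        [
            [1.0 / det.sx, 0.0, 0.0, det.cx],
            [0.0, 1.0 / det.sy, 0.0, det.cy],
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return S


def ndc_scaling(width: int, height: int, sid: float) -> np.ndarray:
    """Simplified NDC scaling S_NDC mapping pixels [0,W]x[0,H] to [-1,1]^2."""
    if width <= 0 or height <= 0 or sid <= 0:
        raise GeometryError("width, height and SID must be positive")
    return np.array(
        [
            [2.0 / width, 0.0, 0.0, -1.0],
            [0.0, 2.0 / height, 0.0, -1.0],
            [0.0, 0.0, 1.0 / sid, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def localization(frame: ImagerFrame) -> np.ndarray:
    """Localization L = R . T: rigid camera placement for one imager."""
    return rotation_matrix_homogeneous(frame.p_x, frame.p_y, frame.d) @ \
        translation_matrix(frame.t)


# ----------------------------------------------------------------------
# Composition / decomposition
# ----------------------------------------------------------------------

def compose_renderer_matrix(frame: ImagerFrame, det: DetectorModel,
                            normalized: bool = False) -> RendererMatrix:
    """Build the stored 3x4 renderer matrix from explicit geometry.

    ``normalized=False`` (the vendor's stored form) drops S_NDC; the
    homogeneous row — identical to the projection row up to the projective
    scale — becomes the third row of the 3x4 result.  The wc sign fix is
    applied so the isocenter has positive homogeneous coordinate.
    """
    sid = frame.sid
    M4 = detector_scaling(det) @ calibration_matrix(sid) @ localization(frame)
    if normalized:
        M4 = ndc_scaling(det.width, det.height, sid) @ M4
        if not np.allclose(M4[2], M4[3], atol=1e-9 * max(1.0, abs(sid))):
            raise GeometryError(
                "normalized stack must have identical third and fourth rows"
            )
        M3 = M4[:3]
    else:
        # rows 3 and 4 are projectively equal (row3 = SID * row4); keep the
        # homogeneous row, matching the vendor's stored denormalized form
        M3 = np.vstack([M4[0], M4[1], M4[3]])
    return RendererMatrix(M3, frame.imager, normalized).wc_fixed()


def rq_decompose(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """RQ factorization A = R_upper . Q with positive diagonal on R_upper.

    Implemented as QR of the exchange-conjugated matrix: with J the
    anti-diagonal exchange, qr((J A)^T) yields the factors after
    re-conjugation.  The triangular/orthogonal sign ambiguity is resolved
    by flipping matched (row of Q, column of R) pairs so diag(R) > 0 — the
    physical entries SID/sx, SID/sy and the homogeneous scale are positive.
    det(Q) may legitimately be -1 (a reflection); callers decide what that
    means.
    """
    A = np.asarray(a, dtype=float)
    if A.shape != (3, 3):
        raise DecompositionError("RQ decomposition expects a 3x3 matrix")
    scale = np.linalg.norm(A)
    if scale == 0 or np.linalg.matrix_rank(A) < 3:
        raise DecompositionError("matrix is singular; RQ decomposition fails")
    J = np.fliplr(np.eye(3))
    q1, r1 = np.linalg.qr((J @ A).T)
    R = J @ r1.T @ J
    Q = J @ q1.T
    sign = np.sign(np.diag(R))
    sign[sign == 0] = 1.0
    R = R * sign[np.newaxis, :]
    Q = Q * sign[:, np.newaxis]
    if np.any(np.diag(R) <= scale * 1e-13):
        raise DecompositionError("near-singular matrix in RQ decomposition")
    return R, Q


def decompose_renderer_matrix(M: RendererMatrix | np.ndarray, sx: float,
                              sy: float) -> DecomposedGeometry:
    """Extract imaging geometry from a stored (denormalized) renderer matrix.

    Steps: wc sign fix; RQ-factor the left 3x3 block into the detector-scaled
    projection P_det and rotation Q; normalize P_det by its (3,3) entry (the
    stored homogeneous scale); read SID = P_det(1,1)*sx, cx = P_det(1,3),
    cy = P_det(2,3); solve the triangular system for the focal point from the
    fourth column; convert to HFS and place the DRR origin.
    """
    if not isinstance(M, RendererMatrix):
        M = RendererMatrix(np.asarray(M, dtype=float))
    if sx <= 0 or sy <= 0:
        raise GeometryError("pixel spacings must be positive")
    M = M.wc_fixed()
    A = M.m[:, :3]
    Pdet, Q = rq_decompose(A)
    lam = Pdet[2, 2]
    if abs(lam) < 1e-12 * np.linalg.norm(Pdet):
        raise DecompositionError("inconsistent scaling: P_det(3,3) is ~0")
    K = Pdet / lam
    sid = K[0, 0] * sx
    cx = K[0, 2]
    cy = K[1, 2]
    if sid <= 0:
        raise DecompositionError("extracted SID is non-positive")
    cond = K[0, 0] / max(abs(K[2, 2]), 1e-300)
    if cond > 1e6:
        warnings.warn(
            f"ill-conditioned focal-point solve (cond ~ {cond:.2e})",
            RuntimeWarning, stacklevel=2,
        )
    # fourth column is K @ (-t.p_x, -t.p_y, -t.d) = -K Q t, scaled by lam
    u = np.linalg.solve(K, M.m[:, 3] / lam)
    t_iec = -(Q.T @ u)
    # handedness surfaced via det_q, never silently absorbed
    det_q = float(np.sign(np.linalg.det(Q)))
    # D = Q^T: columns p_x, p_y, d (IEC); convert to HFS
    C = IEC_TO_HFS_MATRIX
    D_hfs = C @ Q.T
    t_hfs = C @ t_iec
    sigma = drr_origin(t_hfs, D_hfs, cx, cy, sx, sy, sid)
    return DecomposedGeometry(sid=sid, cx=cx, cy=cy, focal_point=t_hfs,
                              direction=D_hfs, drr_origin=sigma, det_q=det_q)


def drr_origin(t: np.ndarray | Vec3, D: np.ndarray, cx: float, cy: float,
               sx: float, sy: float, sid: float) -> np.ndarray:
    """World position (HFS mm) of the image's upper-left corner.

    sigma = t + D @ (-cx*sx, -cy*sy, SID)^T — the focal point pushed SID
    along the beam and pulled back to the corner within the panel plane.
    """
    tv = t.v if isinstance(t, Vec3) else np.asarray(t, dtype=float)
    D = np.asarray(D, dtype=float)
    if not np.allclose(D.T @ D, np.eye(3), atol=1e-8):
        raise GeometryError("direction cosines must be orthonormal")
    return tv + D @ np.array([-cx * sx, -cy * sy, sid])
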