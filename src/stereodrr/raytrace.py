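"""Siddon–Jacobs ray tracing and DRR rendering.

A DRR pixel value is the radiological path — the line integral of linear
attenuation along the ray from the tube focal point to that pixel's
position on the flat panel.  The Siddon–Jacobs traversal computes the
integral exactly for a piecewise-constant voxel volume: the ray parameter
values at every voxel-plane crossing are merged and sorted, and each
traversed voxel contributes its attenuation times the intersection chord
length.  No interpolation is involved, unlike intensity-threshold tracers
that merely sum voxels along the ray.

Path lengths are computed in mm and converted to cm inside the integral to
match attenuation coefficients in cm^-1.

6D couch corrections are applied to the sampling rays (inverse-transforming
source and pixel targets), never by resampling the volume — exact and
interpolation-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .coords import IEC_TO_HFS_MATRIX
from .errors import GeometryError
from .exactrac_io import (CTVolume, SixDOF, hu_to_mu, six_dof_transform,
                          HU_THRESHOLD, MU_WATER_CM)
from .projective import DecomposedGeometry, DetectorModel

_MERGE_TOL = 1e-12  # ray-parameter tolerance for coincident plane crossings
_MM_TO_CM = 0.1


@dataclass(frozen=True)
class AttenuationVolume:
    """Linear attenuation volume (cm^-1) with CT-style geometry metadata."""

    mu: np.ndarray  # [z, y, x], cm^-1
    spacing: tuple[float, float, float]  # (sx, sy, sz) mm
    origin: np.ndarray  # HFS mm, center of voxel [0, 0, 0]
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        if mu.ndim != 3:
            raise GeometryError("attenuation array must be 3-D")
        if np.any(mu < 0):
            raise GeometryError("attenuation coefficients must be >= 0")
        sp = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in sp):
            raise GeometryError("spacing must be positive")
        D = np.asarray(self.direction, dtype=float)
        if not np.allclose(D.T @ D, np.eye(3), atol=1e-8):
            raise GeometryError("direction cosines must be orthonormal")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin",
                           np.asarray(self.origin, dtype=float).reshape(3))
        object.__setattr__(self, "direction", D)

    @classmethod
    def from_ct(cls, ct: CTVolume, mu_water: float = MU_WATER_CM,
                threshold: float = HU_THRESHOLD) -> "AttenuationVolume":
        """Map a (isocenter-centered) CT volume to attenuation."""
        return cls(mu=hu_to_mu(ct.voxels, mu_water, threshold),
                   spacing=ct.spacing, origin=ct.origin,
                   direction=ct.direction)


@dataclass(frozen=True)
class DRRImage:
    """A rendered radiograph plus the geometry that produced it.

    ``mode='raw'`` holds radiological paths (dimensionless, >= 0);
    ``mode='display'`` holds values mapped to [0, 1] by
    :func:`intensity_map` (the vendor's display mapping is proprietary, so
    any display mapping here is explicitly non-authoritative).
    """

    pixels: np.ndarray  # (H, W)
    spacing: tuple[float, float]  # (sx, sy) mm/pix
    geometry: DecomposedGeometry | None = None
    mode: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise GeometryError("DRR pixel array must be 2-D")
        if self.mode == "raw" and np.any(px < 0):
            raise GeometryError("raw radiological paths must be >= 0")
        if self.mode not in ("raw", "display"):
            raise GeometryError(f"unknown DRR mode {self.mode!r}")
        object.__setattr__(self, "pixels", px)


def pixel_position(geom: DecomposedGeometry, i: float, j: float,
                   sx: float, sy: float) -> np.ndarray:
    """World position (HFS mm) of pixel (i, j), pixel-center convention.

    sigma + (i + 1/2) sx p_x + (j + 1/2) sy p_y, with p_x, p_y the first
    two columns of the direction cosines.  Fractional and out-of-panel
    indices are permitted (extrapolation along the panel plane).
    """
    D = geom.direction
    return (geom.drr_origin
            + (i + 0.5) * sx * D[:, 0]
            + (j + 0.5) * sy * D[:, 1])


def _local_frame(vol: AttenuationVolume):
    """Precomputed axis-aligned traversal data in the volume's local frame."""
    nz, ny, nx = vol.mu.shape
    n = np.array([nx, ny, nz])
    sp = np.array(vol.spacing)
    lo = -0.5 * sp  # min corner: voxel [0,0,0] center sits at local 0
    hi = lo + n * sp
    planes = [lo[a] + sp[a] * np.arange(n[a] + 1) for a in range(3)]
    return n, sp, lo, hi, planes


def _to_local(p: np.ndarray, vol: AttenuationVolume) -> np.ndarray:
    return (np.atleast_2d(p) - vol.origin) @ vol.direction


def _siddon_local(a0: np.ndarray, a1: np.ndarray, mu: np.ndarray,
                  n, sp, lo, hi, planes) -> float:
    d = a1 - a0
    length = np.linalg.norm(d)
    if length < 1e-12:
        raise GeometryError("zero-length ray")
    amin, amax = 0.0, 1.0
    for ax in range(3):
        if abs(d[ax]) < 1e-12:
            if not (lo[ax] <= a0[ax] <= hi[ax]):
                return 0.0
        else:
            t1 = (lo[ax] - a0[ax]) / d[ax]
            t2 = (hi[ax] - a0[ax]) / d[ax]
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > amin:
                amin = t1
            if t2 < amax:
                amax = t2
    if amax - amin <= _MERGE_TOL:
        return 0.0
    parts = [np.array([amin, amax])]
    for ax in range(3):
        if abs(d[ax]) > 1e-12:
            a = (planes[ax] - a0[ax]) / d[ax]
            parts.append(a[(a > amin) & (a < amax)])
    alphas = np.sort(np.concatenate(parts))
    keep = np.empty(alphas.shape, dtype=bool)
    keep[0] = True
    # merge coincident crossings so shared voxel corners count once
    np.greater(np.diff(alphas), _MERGE_TOL, out=keep[1:])
    alphas = alphas[keep]
    if alphas.size < 2:
        return 0.0
    mids = 0.5 * (alphas[1:] + alphas[:-1])
    seg_mm = np.diff(alphas) * length
    pts = a0[np.newaxis, :] + mids[:, np.newaxis] * d[np.newaxis, :]
    idx = np.floor((pts - lo) / sp).astype(np.int64)
    np.clip(idx, 0, n - 1, out=idx)
    vals = mu[idx[:, 2], idx[:, 1], idx[:, 0]]
    return float(np.sum(vals * seg_mm) * _MM_TO_CM)


def siddon_path(source: np.ndarray, target: np.ndarray,
                vol: AttenuationVolume) -> float:
    """Radiological path (dimensionless) along the segment source->target.

    Exact for piecewise-constant volumes; 0 when the segment misses the
    volume entirely.
    """
    frame = _local_frame(vol)
    a0 = _to_local(np.asarray(source, dtype=float), vol)[0]
    a1 = _to_local(np.asarray(target, dtype=float), vol)[0]
    return _siddon_local(a0, a1, vol.mu, *frame)


def render_drr(vol: AttenuationVolume, geom: DecomposedGeometry,
               det: DetectorModel, sd: SixDOF | None = None) -> DRRImage:
    """Render a full DRR: one Siddon ray per detector pixel.

    The volume must already be centered on the isocenter.  A non-identity
    6D correction (R, tau) — patient motion about the isocenter, IEC —
    is applied by inverse-transforming the source and every pixel target,
    so rendering the moved patient never resamples the volume.  Rendering
    is deterministic: identical inputs give bit-identical images.
    """
    H, W = det.height, det.width
    D = geom.direction
    ii = (np.arange(W) + 0.5) * det.sx
    jj = (np.arange(H) + 0.5) * det.sy
    targets = (geom.drr_origin[np.newaxis, np.newaxis, :]
               + ii[np.newaxis, :, np.newaxis] * D[:, 0]
               + jj[:, np.newaxis, np.newaxis] * D[:, 1])
    source = geom.focal_point.copy()
    if sd is not None and not sd.is_identity:
        R_iec, tau_iec = six_dof_transform(sd)
        C = IEC_TO_HFS_MATRIX
        R_h = C @ R_iec @ C.T
        tau_h = C @ tau_iec.v
        # DRR of the moved patient == DRR of the static patient with the
        # camera moved by the inverse transform
        source = R_h.T @ (source - tau_h)
        targets = (targets - tau_h) @ R_h
    lo, hi = _volume_extent(vol)
    flat = targets.reshape(-1, 3)
    if np.any(np.all((flat >= lo) & (flat <= hi), axis=1)):
        warnings.warn("detector plane intersects the volume",
                      UserWarning, stacklevel=2)
    frame = _local_frame(vol)
    a0 = _to_local(source, vol)[0]
    a_targets = _to_local(flat, vol).reshape(H, W, 3)
    image = np.empty((H, W), dtype=float)
    for j in range(H):
        for i in range(W):
            image[j, i] = _siddon_local(a0, a_targets[j, i], vol.mu, *frame)
    return DRRImage(pixels=image, spacing=(det.sx, det.sy), geometry=geom,
                    mode="raw", meta={"six_dof": sd})


def _volume_extent(vol: AttenuationVolume) -> tuple[np.ndarray, np.ndarray]:
    nz, ny, nx = vol.mu.shape
    sp = np.array(vol.spacing)
    ext = vol.direction @ (np.array([nx, ny, nz]) * sp - sp)
    lo = np.minimum(vol.origin, vol.origin + ext) - 0.5 * sp
    hi = np.maximum(vol.origin, vol.origin + ext) + 0.5 * sp
    return lo, hi


def intensity_map(img: DRRImage, mode: str = "exp",
                  window: tuple[float, float] | None = None) -> DRRImage:
    """Monotone display mapping of raw radiological paths to [0, 1].

    * ``exp`` — transmission exp(-p) (dense anatomy dark);
    * ``negate_log`` — 1 - p/max(p) (linear inverted paths);
    * ``linear`` — windowed paths (p - lo)/(hi - lo), clipped.

    The treatment workstation's display mapping is proprietary, so none of
    these claims vendor fidelity; the chosen mode is recorded in metadata.
    """
    if img.mode != "raw":
        raise GeometryError("intensity_map expects a raw-mode DRR")
    p = img.pixels
    if mode == "exp":
        disp = np.exp(-p)
    elif mode == "negate_log":
        m = p.max()
        disp = 1.0 - (p / m if m > 0 else p)
    elif mode == "linear":
        if window is None:
            window = (0.0, float(p.max()))
        lo, hi = window
        if hi == lo:
            raise GeometryError("degenerate display window (lo == hi)")
        disp = np.clip((p - lo) / (hi - lo), 0.0, 1.0)
    else:
        raise GeometryError(f"unknown intensity mapping {mode!r}")
    meta = dict(img.meta)
    meta.update({"mapping": mode, "window": window})
    return DRRImage(pixels=disp, spacing=img.spacing, geometry=img.geometry,
                    mode="display", meta=meta)
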