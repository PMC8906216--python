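"""Vendor configuration, DICOM CT / RT Plan input, and 6D couch corrections.

The stereo system writes an INI-style configuration file per imaged subject.
Its ``[FlatPanel]`` section carries the keys ``MLinToFlat1`` and
``MLinToFlat2``, each a comma-separated string of 13 numbers: a leading
zero (to be discarded) followed by the 12 entries of the 3x4 renderer
matrix in row-major order, expressed in IEC coordinates.

CT data arrive as a DICOM series plus an RT Plan carrying the isocenter in
patient (HFS) coordinates; subtracting the isocenter from the volume origin
moves the CT isocenter onto the linac isocenter, the shared origin of the
IEC and HFS frames.  CT numbers map to linear attenuation via a linear
correspondence anchored at water, with everything below a minimum HU
threshold neglected (bony-anatomy replication).
"""

from __future__ import annotations

import configparser
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom

from .coords import (HFS, IEC, IEC_TO_HFS_MATRIX, Vec3, rot_x, rot_y, rot_z,
                     vec3)
from .errors import ConfigError, DicomError, GeometryError
from .projective import RendererMatrix

FLATPANEL_SECTION = "FlatPanel"
MLINTOFLAT_KEYS = ("MLinToFlat1", "MLinToFlat2")

#: Linear attenuation coefficient of water at an effective beam energy of
#: 70 keV as used for DRR replication (cm^-1).  Note this is an effective
#: rendering constant, not the physical narrow-beam value (~0.19 cm^-1);
#: see docs/methods.md.
MU_WATER_CM = 0.029

#: Minimum CT number contributing to radiological paths (HU, inclusive).
HU_THRESHOLD = 100.0


@dataclass(frozen=True)
class ExacTracConfig:
    """Parsed vendor configuration: one renderer matrix per flat panel."""

    ml_in_to_flat_1: RendererMatrix
    ml_in_to_flat_2: RendererMatrix
    source_path: Path | None = None
    raw_tokens: dict = field(default_factory=dict)

    def matrix(self, imager: int) -> RendererMatrix:
        if imager == 1:
            return self.ml_in_to_flat_1
        if imager == 2:
            return self.ml_in_to_flat_2
        raise GeometryError("imager index must be 1 or 2")


@dataclass(frozen=True)
class CTVolume:
    """A CT volume in HFS patient coordinates.

    ``voxels`` is indexed ``[z, y, x]`` (slice, row, column) in Hounsfield
    units; ``spacing`` is (sx, sy, sz) mm; ``origin`` is the world position
    of the center of voxel [0, 0, 0]; ``direction`` maps voxel axis steps
    to world axes (identity for an axial HFS series).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise DicomError("CT voxel array must be 3-D")
        sp = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in sp):
            raise DicomError("voxel spacing must be positive on all axes")
        D = np.asarray(self.direction, dtype=float)
        if not np.allclose(D.T @ D, np.eye(3), atol=1e-8):
            raise DicomError("direction cosines must be orthonormal")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin",
                           np.asarray(self.origin, dtype=float).reshape(3))
        object.__setattr__(self, "direction", D)

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.voxels.shape
        return nx, ny, nz

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """World-aligned voxel-center bounding box (axial volumes)."""
        nx, ny, nz = self.shape_xyz
        extent = (np.array([nx, ny, nz]) - 1) * np.array(self.spacing)
        return self.origin, self.origin + self.direction @ extent


@dataclass(frozen=True)
class SixDOF:
    """A 6D couch correction: translations in mm, rotations in degrees.

    The transform acts on the patient about the isocenter in IEC
    coordinates; the all-zero instance is the identity.
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    pitch: float = 0.0
    yaw: float = 0.0
    roll: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tx", "ty", "tz", "pitch", "yaw", "roll"):
            if not np.isfinite(getattr(self, name)):
                raise GeometryError(f"SixDOF.{name} must be finite")

    @property
    def is_identity(self) -> bool:
        return all(
            getattr(self, n) == 0.0
            for n in ("tx", "ty", "tz", "pitch", "yaw", "roll")
        )


# ----------------------------------------------------------------------
# Configuration file
# ----------------------------------------------------------------------

def parse_mlintoflat(raw: str) -> np.ndarray:
    """Parse one MLinToFlat value string into a 3x4 matrix.

    Exactly 13 comma-separated numbers; the first is a placeholder zero and
    is discarded (with a warning if nonzero); the remaining 12 fill the
    matrix in row-major order.
    """
    tokens = [t.strip() for t in str(raw).split(",")]
    if len(tokens) != 13:
        raise ConfigError(
            f"MLinToFlat value must hold 13 comma-separated numbers, "
            f"got {len(tokens)}"
        )
    try:
        values = [float(t) for t in tokens]
    except ValueError as exc:
        raise ConfigError(f"non-numeric token in MLinToFlat value: {exc}") from exc
    if values[0] != 0.0:
        warnings.warn(
            f"leading MLinToFlat token expected to be 0, got {values[0]!r}; "
            "discarding it anyway",
            UserWarning, stacklevel=2,
        )
    return np.array(values[1:], dtype=float).reshape(3, 4)


def read_config(path: str | Path) -> ExacTracConfig:
    """Read a vendor-style INI configuration file.

    Requires a ``[FlatPanel]`` section with both case-sensitive
    ``MLinToFlat1`` / ``MLinToFlat2`` keys; unknown sections and keys are
    ignored.  Tolerates surrounding whitespace and CRLF line endings.
    """
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"configuration file not found: {path}")
    parser = configparser.ConfigParser(interpolation=None, strict=False)
    parser.optionxform = str  # keys are case-sensitive
    try:
        parser.read_string(path.read_text())
    except configparser.Error as exc:
        raise ConfigError(f"malformed configuration file {path}: {exc}") from exc
    if not parser.has_section(FLATPANEL_SECTION):
        raise ConfigError(f"missing [{FLATPANEL_SECTION}] section in {path}")
    matrices = {}
    raw_tokens = {}
    for imager, key in enumerate(MLINTOFLAT_KEYS, start=1):
        if not parser.has_option(FLATPANEL_SECTION, key):
            raise ConfigError(
                f"missing key {key!r} in [{FLATPANEL_SECTION}] of {path}"
            )
        raw = parser.get(FLATPANEL_SECTION, key)
        raw_tokens[key] = raw
        matrices[imager] = RendererMatrix(parse_mlintoflat(raw), imager=imager,
                                          normalized=False)
    return ExacTracConfig(ml_in_to_flat_1=matrices[1],
                          ml_in_to_flat_2=matrices[2],
                          source_path=path, raw_tokens=raw_tokens)


# ----------------------------------------------------------------------
# DICOM input
# ----------------------------------------------------------------------

_AXIAL_IOP = np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0])


def read_ct_series(directory: str | Path) -> CTVolume:
    """Import one axial HFS CT series from a directory of DICOM slices.

    Slices are sorted by position along the slice normal regardless of file
    order; rescale slope/intercept are applied to yield Hounsfield units.
    Mixed series, non-uniform slice spacing (beyond 1e-3 mm) and non-HFS /
    non-axial orientations are rejected.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise DicomError(f"not a directory: {directory}")
    datasets = []
    for f in sorted(directory.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if getattr(ds, "Modality", None) == "CT":
            datasets.append(ds)
    if not datasets:
        raise DicomError(f"no CT slices found in {directory}")
    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) > 1:
        raise DicomError(f"mixed CT series in {directory}: {sorted(uids)}")
    for ds in datasets:
        iop = np.asarray([float(v) for v in ds.ImageOrientationPatient])
        if not np.allclose(iop, _AXIAL_IOP, atol=1e-6):
            raise DicomError(
                "unsupported orientation: only axial head-first supine "
                f"series are handled (ImageOrientationPatient={iop.tolist()})"
            )
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.any(dz <= 0):
            raise DicomError("duplicate or non-increasing slice positions")
        if np.ptp(dz) > 1e-3:
            raise DicomError(
                f"non-uniform slice spacing (range {np.ptp(dz):.6f} mm); "
                "a slice may be missing"
            )
        sz = float(np.mean(dz))
    else:
        sz = float(getattr(datasets[0], "SliceThickness", 1.0))
    ps = [float(v) for v in datasets[0].PixelSpacing]  # (row=y, col=x)
    for ds in datasets[1:]:
        if not np.allclose([float(v) for v in ds.PixelSpacing], ps, atol=1e-9):
            raise DicomError("in-plane pixel spacing differs between slices")
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    voxels = np.stack(slices, axis=0)
    origin = np.array([float(v) for v in datasets[0].ImagePositionPatient])
    return CTVolume(voxels=voxels, spacing=(ps[1], ps[0], sz), origin=origin)


def read_isocenter(rtplan_path: str | Path) -> Vec3:
    """Isocenter position (HFS mm) from an RT Plan DICOM.

    All beams must agree on a single isocenter within 1e-6 mm; conflicting
    values raise an ambiguity error listing them.
    """
    ds = pydicom.dcmread(rtplan_path)
    positions = []
    for seq_name in ("BeamSequence", "IonBeamSequence"):
        for beam in getattr(ds, seq_name, []):
            for cp in getattr(beam, "ControlPointSequence", []):
                iso = getattr(cp, "IsocenterPosition", None)
                if iso is not None:
                    positions.append(np.array([float(v) for v in iso]))
                    break
    if not positions:
        raise DicomError(f"no isocenter found in RT Plan {rtplan_path}")
    ref = positions[0]
    for p in positions[1:]:
        if np.max(np.abs(p - ref)) > 1e-6:
            raise DicomError(
                "ambiguous isocenter: beams disagree "
                f"({[p.tolist() for p in positions]})"
            )
    return Vec3(ref, HFS)


def center_volume(vol: CTVolume, iso: Vec3) -> CTVolume:
    """Translate the volume so the plan isocenter lands on the origin.

    Only the origin changes (voxels and spacing are untouched); the world
    point formerly at ``iso`` becomes (0, 0, 0) — the linac isocenter and
    shared IEC/HFS origin.
    """
    if iso.frame != HFS:
        raise GeometryError("isocenter must be given in HFS coordinates")
    lo, hi = vol.bounding_box()
    if np.any(iso.v < np.minimum(lo, hi)) or np.any(iso.v > np.maximum(lo, hi)):
        warnings.warn(
            f"isocenter {iso.v.tolist()} lies outside the CT bounding box",
            UserWarning, stacklevel=2,
        )
    return CTVolume(voxels=vol.voxels, spacing=vol.spacing,
                    origin=vol.origin - iso.v, direction=vol.direction)


# ----------------------------------------------------------------------
# Attenuation mapping and 6D corrections
# ----------------------------------------------------------------------

def hu_to_mu(hu, mu_water: float = MU_WATER_CM,
             threshold: float = HU_THRESHOLD):
    """Linear attenuation (cm^-1) from CT number.

    mu = mu_water * (1 + HU/1000) for HU >= threshold (inclusive), else 0:
    tissue below the threshold is neglected in radiological paths.  The
    slope follows from the HU definition; the anchor is water at the
    effective beam energy.
    """
    if mu_water <= 0:
        raise GeometryError("mu_water must be positive")
    hu = np.asarray(hu, dtype=float)
    mu = np.where(hu >= threshold, mu_water * (1.0 + hu / 1000.0), 0.0)
    return float(mu) if mu.ndim == 0 else mu


_AXIS_ROT = {"x": rot_x, "y": rot_y, "z": rot_z}
_ANGLE_FOR_AXIS = {"x": "pitch", "z": "yaw", "y": "roll"}


def six_dof_transform(sd: SixDOF, order: str = "zyx"
                      ) -> tuple[np.ndarray, Vec3]:
    """Rigid transform (R, tau) in IEC coordinates for a 6D correction.

    ``order`` names the axes of the matrix product left to right; the
    default "zyx" gives R = R_Z(yaw) @ R_Y(roll) @ R_X(pitch) (intrinsic
    yaw-roll-pitch about the isocenter).  The vendor's exact convention is
    not public, hence the parameter.
    """
    if sorted(order) != ["x", "y", "z"]:
        raise GeometryError(f"order must be a permutation of 'xyz', got {order!r}")
    R = np.eye(3)
    for axis in order:
        angle = np.radians(getattr(sd, _ANGLE_FOR_AXIS[axis]))
        R = R @ _AXIS_ROT[axis](angle)
    return R, vec3(sd.tx, sd.ty, sd.tz, IEC)


def rigid_inverse(R: np.ndarray, tau: Vec3) -> tuple[np.ndarray, Vec3]:
    """Inverse of the rigid transform x -> R x + tau."""
    Rt = np.asarray(R, dtype=float).T
    return Rt, Vec3(-(Rt @ tau.v), tau.frame)
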