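# Methods

## Coordinate frames

Two right-handed frames share the linac isocenter as origin. The
machine-centric IEC frame has +X to the patient's right, +Y toward the
gantry, +Z up; renderer matrices and room geometry live here. The
patient-centric HFS frame (head-first supine) has +X right, +Y down,
+Z toward the head; DICOM-derived data live here. Matching those axis
semantics fixes the conversion to the proper rotation
(x, y, z)_IEC → (x, −z, y)_HFS, which is locked by unit tests and,
end-to-end, by the dual-pathway rendering comparison. Only HFS scans are
supported; the DICOM reader rejects any other `ImageOrientationPatient`
explicitly rather than guessing a conversion.

All lengths are mm, all angles are radians internally (the CLI accepts
degrees). Attenuation is kept in cm⁻¹ as conventionally quoted; the ray
tracer converts path lengths mm → cm (factor 0.1) inside the integral.

## Stereo geometry from four measurements

The central beamline of imager 1 is
d₁ = normalize(R_X(π/2 − θ)·(tan(φ/2), 0, 1)ᵀ); imager 2 is its mirror
through the X = 0 plane. This construction is *defined* by its contract —
the angle between d₁ and d₂ equals φ, the plane they span meets the floor
at dihedral angle θ, and both beams climb (d_Z > 0) — and that contract,
not the formula, is what the test suite asserts across θ ∈ [10°, 80°],
φ ∈ [20°, 160°] (to 1e-9 rad). Focal points and panel centers follow from
t = −SOD·d and c = t + SID·d.

Panel axes: the beamline's floor projection is renormalized, quarter-turned
about +Z (counterclockwise seen from above), and the beamline is rotated a
quarter turn about that axis (Rodrigues) to give p_y; p_x = p_y × d closes
a right-handed orthonormal triad. Because the rotation axis is orthogonal
to d, p_y equals the plain cross product of axis and beam — asserted as an
internal cross-check. Degenerate inputs (vertical beams, angles at the
domain boundary, renormalization of vectors shorter than ~1e-9) raise
instead of being silently patched.

The package ships default room values SID = 1800 mm, SOD = 900 mm,
θ = 40°, φ = 62°. The true clinical values are vendor-documented and not
public; the defaults were chosen once so that the 200 mm panel maps to the
system's advertised ~10 cm field of view at isocenter (magnification
SID/SOD = 2). They are explicitly non-authoritative: any real analysis
should start from a real configuration file.

## Projective stack and its inversion

The renderer matrix is M = S_NDC·S_det·P·R·T on real projective 3-space.
In the stored (denormalized) form S_NDC is dropped and the homogeneous
row — projectively equal to the projection row — is kept as the third row
of the 3×4 matrix. The wc condition (rendered points must have positive
homogeneous coordinate) is enforced by multiplying the stored matrix by
the sign of its third row applied to the homogeneous isocenter
(0, 0, 0, 1); every extraction is therefore invariant under arbitrary
nonzero rescaling of the matrix.

Decomposition RQ-factors the left 3×3 block into an upper-triangular
detector-scaled projection P_det and an orthogonal Q. RQ is implemented
as QR of the exchange-conjugated matrix with a positive-diagonal sign
convention (the physical diagonal entries SID/s_x, SID/s_y and the
homogeneous scale are positive); sign flips are applied to matched
row/column pairs so the product is untouched. det Q = −1 (a residual
reflection, i.e. left-handed detector axes) is *reported* as a handedness
flag, never silently absorbed. After dividing P_det by its (3,3) entry:
SID = P_det(1,1)·s_x, c_x = P_det(1,3), c_y = P_det(2,3); the focal point
solves the triangular system relating the matrix's fourth column to
−P_det·Q·t (a conditioning warning fires above 1e6); the direction
cosines are D = Qᵀ, converted with t to HFS.

### Pixel-shift sign convention

With S_det as used here, a point at camera coordinates (x, y, z) lands at
pixel u = SID·x/(z·s_x) + c_x, so the central beamline strikes pixel
(c_x, c_y) and a centered W×H image has c_x = W/2, c_y = H/2 (the package
default). The DRR origin σ = t + D·(−c_x s_x, −c_y s_y, SID)ᵀ is then the
physical upper-left panel corner, and pixel (i, j) sits at
σ + (i+½)s_x p_x + (j+½)s_y p_y (pixel-center sampling). The corner/center
convention and the sign of c_x are exactly the kind of thing that is easy
to get wrong silently, so they are pinned by two independent pathways (see
Validation) rather than by assertion: the first-principles pathway places
σ directly from the physical panel corner without any matrix algebra, and
both pathways must project a phantom to the same sub-0.1-pixel centroids.

Whether a vendor matrix could encode mirrored detector axes is unknown;
the handedness flag surfaces that case instead of guessing.

## CT input and attenuation

DICOM CT series are read with pydicom: slices of a single series are
sorted by position along the slice normal (file order is irrelevant),
rescale slope/intercept applied to give HU, uniform slice spacing enforced
to 1e-3 mm (a missing slice is an error, not an interpolation
opportunity). The RT Plan supplies the isocenter; beams disagreeing by
more than 1e-6 mm raise an ambiguity error listing the values. Subtracting
the isocenter from the volume origin moves the CT isocenter onto the
shared IEC/HFS origin; voxel data are never touched.

HU map to linear attenuation by μ = μ_water·(1 + HU/1000) at or above an
inclusive 100 HU threshold and exactly 0 below it — the bony-anatomy
replication regime, where soft tissue is deliberately neglected. The slope
follows from the definition of the Hounsfield scale once the water anchor
is fixed. The default anchor, μ_water = 0.029 cm⁻¹ at an effective 70 keV,
is kept for fidelity to the replicated rendering pipeline even though it
is far below the physical narrow-beam value (~0.19 cm⁻¹); treat it as an
effective display constant, and pass a physical value if quantitative
transmission matters. Both anchor and threshold are parameters.

## Ray tracing

Radiological paths use exact Siddon–Jacobs traversal: all ray-parameter
values where the segment crosses a voxel plane are collected, clipped to
the volume slab, sorted, and merged (crossings closer than 1e-12 in ray
parameter collapse, so shared voxel corners count once); each interval
contributes its chord length times the attenuation of the voxel containing
its midpoint. This is exact for piecewise-constant volumes — unlike
intensity-threshold tracers that sum voxel values along a ray — and is the
package's canonical output. Rays run from the focal point to each pixel
center; rendering is deterministic.

6D couch corrections (translations in mm, pitch/yaw/roll in degrees,
about the isocenter, in IEC) are applied by inverse-transforming the
source and pixel targets, never by resampling the volume — exact and
interpolation-free. The rotation convention defaults to the matrix product
R_Z(yaw)·R_Y(roll)·R_X(pitch); the vendor's actual order and signs are not
public, so the order is a documented, configurable guess.

Display mappings (exp(−p) transmission, inverted-linear, windowed linear)
are provided for convenience and marked non-authoritative: the treatment
workstation's intensity mapping is proprietary, and raw paths are the
quantity all tests reason about.

## Synthetic phantom and what the tests do (and do not) show

The spine phantom is a water-equivalent ellipsoid (0 HU, mild seeded
Gaussian texture of 15 HU — far below the rendering threshold) in air,
containing five 800 HU box inserts of 15×15×10 mm at 25 mm pitch along the
patient axis, with the plan isocenter at the middle insert. Insert edges
align with voxel boundaries at the default 2.5 mm grid, so discretized
insert volumes are exact — the volume-fraction test is sharp. The
repeating inserts exist so vertebral-level misalignment scenarios can be
exercised by ±25 mm 6D shifts. The phantom is written as a fully
standards-conformant CT series (rescale intercept −1024, so HU round-trip
bit-exactly) plus a minimal RT Plan, and the configuration writer
serializes composed renderer matrices in the vendor's 13-token format.

Validation is two-pathway: the same scene is rendered (a) from
first-principles geometry built directly from room measurements and the
physical panel corner, and (b) from geometry recovered by parsing and
RQ-decomposing the synthetic configuration. Insert-projection centroids
must agree within 0.1 px (they agree to ~1e-13), and a 6D shift δ along
the panel x axis must move the projection by δ·(SID/SOD)/s_x px within
0.5 px. Default problem sizes — 64³ voxels at 2.5 mm, 128² DRRs — keep the
whole suite fast while leaving dozens of voxels per insert and >10 px of
magnified shift.

What this does *not* show: agreement with the vendor's actual DRRs
(clinical reference images are proprietary; published comparisons of this
reconstruction approach report ~1 mm mean landmark displacement), detector
physics (scatter, beam hardening, noise, polyenergetic spectra are out of
scope), or sub-pixel fidelity of the corner-vs-center sampling convention
against the vendor (any disagreement is bounded by half a pixel,
~0.2 mm at the panel).

## Numerical choices

- Renormalization guard 1e-12; inputs nearer to degenerate raise.
- RQ positive-diagonal convention; singularity rejected at 1e-13 of the
  matrix norm.
- Siddon crossing-merge tolerance 1e-12 of the ray parameter; ray-slab
  clipping uses half-open voxel intervals via interval midpoints.
- Landmark statistics: sample SD (n−1; zero for n = 1), quartiles by
  linear interpolation between order statistics (IQR differences between
  quartile conventions are far below any tolerance used here); Euclidean
  mm displacements, with per-axis signed differences available by plain
  subtraction for diagnostics.
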