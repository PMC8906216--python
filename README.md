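# stereodrr

Offline generation of digitally reconstructed radiographs (DRRs) for
floor/ceiling-mounted stereoscopic kV image-guidance systems of the
ExacTrac type, used in image-guided radiotherapy (IGRT).

Such systems match treatment-time X-ray projections against DRRs rendered
from the planning CT, but do not export DRRs for *simulated* couch
positions — which is exactly what IGRT research on positioning-error
detection needs (e.g. training sets of deliberately misaligned vertebral
bodies). `stereodrr` closes that gap: it reconstructs the system's exact
projection geometry either from four in-room measurements or from the
renderer matrices stored in the vendor configuration file, and renders
DRRs from DICOM CT data with true radiological-path ray tracing, including
arbitrary 6D (translation + pitch/yaw/roll) couch corrections.

## The model

Each imager is a pinhole camera: an X-ray tube focal point **t** below the
floor and a flat-panel detector above, its central beamline **d** passing
through the linac isocenter (the shared origin of the machine-centric IEC
frame and the patient-centric head-first-supine HFS frame). The whole
stereo pair is fixed by four numbers — SID, SOD, the oblique-plane incline
θ and the beamline crossing angle φ:

    d₁ = normalize( R_X(π/2 − θ) · (tan(φ/2), 0, 1)ᵀ ),   d₂ = d₁ with X ↦ −X
    t  = −SOD · d,     c = t + SID · d

with the in-plane panel axes p_x, p_y completing a right-handed
orthonormal triad with d. The full imaging chain is a product of linear
operators on projective 3-space,

    M = S_NDC · S_det · P · R · T,

(camera translation T, rotation R, pinhole calibration P with focal length
SID, detector scaling S_det with pixel spacings s_x, s_y and pixel shifts
c_x, c_y, optional NDC scaling), stored as a 3×4 *renderer matrix* per
imager. Conversely, RQ decomposition of a stored matrix's left 3×3 block
recovers the detector-scaled projection (upper triangular, yielding SID,
c_x, c_y) and the rotation Q (the direction cosines); the focal point
follows from a triangular solve and the DRR origin σ — the world position
of the image's upper-left corner — from

    σ = t + D · (−c_x s_x, −c_y s_y, SID)ᵀ.

DRR pixels are radiological paths ∫ μ dl computed with exact Siddon–Jacobs
voxel traversal (per-voxel intersection lengths, no interpolation), with
CT numbers mapped to attenuation by μ = μ_water (1 + HU/1000) above an
inclusive 100 HU threshold and neglected below it.

A built-in digital phantom (DICOM CT series + RT Plan + synthetic
configuration file generated from known geometry) makes the entire
pipeline testable without any clinical data.

## Worked example

Compute both imager geometries from in-room measurements (angles in
degrees on the command line):

```
$ stereodrr from-measurements --sid 1800 --sod 900 --theta 40 --phi 62
{
  "imagers": [
    {
      "imager": 1,
      "focal_point_mm": [-463.534, 590.965, -495.879],
      "beam_direction": [0.51504, -0.65663, 0.55098],
      "panel_center_mm": [463.534, -590.965, 495.879],
      ...
```

The tube sits 900 mm from the isocenter on the −X side, the beam climbs
at 33.4° from the floor, and the panel center is diametrically opposite at
SID − SOD = 900 mm. Generate a synthetic phantom and render both DRRs
through the configuration-file pathway:

```
$ stereodrr phantom --out phantom
$ stereodrr decompose --config phantom/config.ini --imager 1
{
  "sid_mm": 1800.0000000000005,
  "cx_pix": 255.99999999999972,
  "focal_point_mm": [-463.534, 495.879, 590.965],
  ...
}
$ stereodrr from-config --config phantom/config.ini --ct phantom/ct \
      --rtplan phantom/rtplan.dcm --size 128 --out drr
wrote DRRs for both imagers to drr
```

The decomposed SID (1800 mm) and pixel shifts (256 = W/2, a centered
detector) recover the generating geometry to 13 significant digits; the
focal point is the IEC value re-expressed in HFS patient coordinates.
`drr/` then holds, per imager, the raw radiological-path image (`.npy`),
a 16-bit display PNG and a JSON sidecar with the full geometry.

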