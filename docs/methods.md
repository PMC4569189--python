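# Methods

## Coordinate model

All geometry lives in an orthonormal AC-PC frame with the midcommissural
point (MCP) as origin.  The anterior axis is `unit(AC − PC)`; the lateral
axis is the component of a user-supplied midsagittal normal orthogonal to
it; the vertical axis is their cross product, oriented superior.  How the
midline was fixed is an input choice, not something the package infers:
the normal can come from landmark annotation or from an image affine.

Internally the lateral component is signed (positive right).  Reported LAT
values are unsigned magnitudes with the hemisphere carried as a label,
because bilateral cohorts pool left and right leads into a single LAT
column; mirroring a point across the midsagittal plane therefore flips the
hemisphere label and leaves (LAT, AP, VERT) unchanged.  VERT is negative
inferior to the AC-PC plane.  World units are mm throughout; voxel→world
conversion uses the NIfTI affine with 0-based voxel indices.

## Lead reconstruction

A lead is reconstructed from its tip T (most distal artifact point on
postoperative CT) and a dorsal shaft point S; any dorsal point on the lead
line gives the same reconstruction.  Contact centers of the model 3389
follow from the fixed geometry: center of contact *i* at
`T + (t₀ + 0.75 + 2i)·u` mm, with pitch 2 mm (1.5 mm contact + 0.5 mm gap)
and `t₀` the distal-tip offset.  **`t₀ = 1.5 mm` is a packaged assumption**
(the nominal 3389 distal tip length); it is a configurable geometry
parameter, and no cohort-level result here depends on its exact value.

Stimulation configurations are parsed from clinical labels: monopolar
`"c+ k-"` (case anode, contact k active) and adjacent bipolar `"k-m+"`.
Contact numbers are reduced modulo 4 because implanted pulse generators
address leads in channel blocks of four (0–3, 4–7, 8–11, 12–15); this also
covers tables that number a second device's leads from 4 or 12.  For an
adjacent bipolar pair the active point is the arithmetic midpoint of the
two contact centers ("geometric center"); a literal coordinate-wise
geometric mean is not translation-invariant and cannot be the intended
operation.  Non-adjacent pairs are rejected rather than guessed at.

## Boundary points and contact indices

At the axial (AC-PC) plane through the active contact, A and P are the
anterior/posterior extremes of the mask; M/L and V/D are the boundary
crossings of the lateral and vertical lines through the contact.  Both
"horizontal" and "vertical" lines are taken axis-aligned in the AC-PC
frame (the ML line in the axial plane, the VD line along the frame's
vertical axis); the convention is recorded per run via the frame used.
The index denominators are always the full boundary segments (|AP|, |ML|,
|VD|).

Numerics, chosen for 1 mm isotropic masks:

* Rays are sampled at 0.1 mm; a boundary crossing is localized by linear
  interpolation between the last foreground and first background sample.
  A binary mask quantizes the true surface by up to half a voxel — that
  error belongs to the mask, not the sampling — so oracle comparisons are
  made at one voxel diagonal.
* The anterior/posterior extreme of a smooth structure is flat in the
  lateral direction, which makes a single argmax line laterally unstable
  on a voxelized mask.  The extreme AP value is kept, and its lateral
  position is averaged over all crossings within half a voxel of the
  extreme.
* On non-convex slices, the ML/VD lines use the foreground run containing
  the contact, falling back to the nearest run — matching the visual
  convention of bounding the structure around the contact.
* Indices are *signed projection parameters* and are reported unclamped:
  a value outside [0, 1] flags a contact beyond the structure's span
  instead of silently truncating it.

Anatomical labels (`GPi`, `GPi/GPe`, `IC/GPi`, `outside`) formalize a
visual convention: inside the GPi and ≥ δ from its boundary → `GPi`;
within δ of the GPi–GPe or GPi–IC interface → the border label.  The
default δ = 0.65 mm is about half the lead diameter, i.e. a contact whose
surface touches the interface; no numeric rule is published for the
visual labels, so δ is exposed as a parameter.  Distances are computed
against the union of voxel cubes (exact for rigid affines), and missing
neighbor masks restrict the reachable labels, which the result records.

## Targeting rules and errors

Atlas coordinates follow the standard rules: AP = 2 mm if the AC-PC
length is under 25 mm, else 3 mm; VERT = −1.5 mm (midpoint of the stated
1–2 mm inferior); LAT is mapped linearly from 20 mm at third-ventricle
width ≤ 2 mm to 22 mm at ≥ 10 mm, clamped.  The ventricle-width→LAT map
is not published numerically; the linear map (and every other constant)
is exposed in a configurable rule object, and no cohort-level acceptance
depends on its exact shape.

The targeting error intersects the lead line with the axial plane at the
intended target's VERT and reports |ΔAP|, |ΔLAT| and their norm.  The
closest-lead distance is taken to the *contact-bearing segment* of the
lead (not the contact centers only): published sub-millimetre VERT
distances between targets and leads are only consistent with a continuous
closest point.  Where a table caption describes target-vs-target
differences but the surrounding text describes target-vs-lead distances,
the text's reading is implemented.

## Cohort statistics

Means are reported with sample SDs (n−1).  Display rounding is half away
from zero, one decimal for mm/years, integer percentages — presentation
only; full precision is kept in the returned tables.  Group contrasts use
the two-sided unpaired pooled-variance t-test even where pairing exists,
mirroring how such cohorts are reported; a paired alternative would be a
different analysis, deliberately not the default.  Normality is
pre-checked with a one-sample KS test against a normal with estimated
moments at α = 0.05 and travels with the result as metadata.  Subgroup
sample sizes count leads (26), not patients (13), matching the n columns
of per-lead tables.  Degenerate (zero-variance) comparisons are reported
as `test-undefined` rather than raised.

## Synthetic cohorts

The generator emulates the *geometry and bookkeeping* of a bilateral
GPi-DBS cohort, not pallidal morphology or image contrast:

* **Targets.**  Direct targets are drawn per disease group from the
  published means/SDs; atlas targets apply the atlas rules to sampled
  third-ventricle widths (wider in PD, reflecting the older subgroup) and
  AC-PC lengths.
* **Implantation.**  Leads run through the direct target along oblique
  trajectories (≈10° lateral, ≈25° anterior tilt, entry near the coronal
  suture), displaced in the axial plane by per-axis Gaussian noise
  `σ = implant_sigma` and jittered 0.5 mm in depth.  The in-plane error
  is then Rayleigh with mean `σ·sqrt(π/2)`; the default σ = 0.85 mm puts
  the mean error at ≈ 1.07 mm, the scale reported for this surgical
  technique.  σ = 0 reproduces the plan exactly.
* **Anatomy.**  Each GPi is an ellipsoid with semi-axes (6, 10, 5) mm
  along (LAT, AP, VERT), an anterior-lateral yaw of ≈ 20°, centered near
  (17.5, 4.2, −1.4) mm from the MCP so that typical direct targets fall
  in its posteroventral portion — synthetic conventions chosen to place
  the cohort's mean indices near the published values, not anatomical
  claims.  An abutting GPe shell and a medial internal-capsule slab
  complete the mask set at 1 mm isotropic resolution.  When a sampled
  contact would fall too close to the sampled surface, the ellipsoid is
  translated so the contact sits at a fixed interior depth — direct
  targets are, by construction, chosen inside the visualized structure —
  which leaves the configured target moments untouched.
* **Ground truth.**  Every lead carries its true contact centers, the
  analytic (closed-form) boundary points and indices of its ellipsoid,
  and the mask-based indices of the true contact.  Recovery is judged
  against the mask-based truth: the mask is the pipeline's actual input,
  and a binary mask's half-voxel surface quantization is not an error of
  the method under test.  Agreement with the analytic shape is checked
  separately at one voxel diagonal.
* **Determinism.**  One seed determines the cohort; per-patient
  substreams are derived deterministically, so any patient's anatomy can
  be regenerated in isolation.

What passing these tests shows — and what it does not: the pipeline's
geometry is exact at σ = 0 and degrades gracefully under noise on
convex, well-separated synthetic structures.  Real pallidal masks are
non-ellipsoidal, manually segmented, and subject to fusion error between
CT and MRI; none of that is modelled here.

## Problem sizes

The default synthetic cohort matches the study scale (13 patients, 26
leads).  Oracle comparisons use 500 random contacts across ~50 sampled
shapes, 300 random lead/target pairs, and 1000 Monte-Carlo replicates
for the subgroup-power check — sizes at which every sampling-based
check is stable across seeds while the whole suite runs in seconds.

## Known limitations

* Tip/shaft points are inputs; CT artifact detection, image fusion and
  AC/PC detection are out of scope.
* Voxel masks only; no mesh-based boundary models.
* The distal-tip offset `t₀` of the contact array is an assumption (see
  above); absolute contact depths shift with it.
* The index construction assumes the structure has usable extent at the
  contact's axial level; contacts outside the slab raise rather than
  extrapolate.
* No volume-of-tissue-activated modelling and no clinical outcome data.
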