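# Methods

## Coordinate conventions

All patient-frame quantities are RAS+ millimetres (x→Right, y→Anterior,
z→Superior). Voxel indices are 0-based and bounding boxes half-open
`[lower, upper)`, so crops compose unambiguously; cropping rewrites only
the affine translation, which preserves the patient coordinate of every
retained voxel exactly. NIfTI files are read through the sform (qform as
fallback; a warning is logged when the two disagree beyond 1e-3). Fractional
voxel coordinates are allowed in all transforms; nearest-neighbour sampling
is used only where integer labels are resampled (the oracle backend). A
documented RAS↔LPS helper covers the DICOM patient convention; no other
scanner dialect is interpreted, and every JSON export tags its frame
explicitly rather than guessing what a scanner host expects.

## Plane prescription model

A 2D PC slice quantifies through-plane flow, so the slice normal must be
the vessel axis. Given start/mid/end keypoints of a vessel segmentation,
the prescription is: normal = unit(end − start), center = mid. The in-plane
(read/phase) directions are geometrically irrelevant to which slice is
acquired; they are fixed by a deterministic convention — read =
normalize(a × normal) with `a` the canonical patient axis least parallel to
the normal (ties resolved in x→y→z order), phase = normal × read — purely so
that outputs are reproducible and right-handed. Vessels shorter than 3 mm
(configurable) are rejected as degenerate: at the working resolution such a
direction estimate is noise. Default geometric protocol: FOV 300 × 300 mm,
slice thickness 5 mm, matching a typical fetal 2D PC acquisition.

### Keypoints from a label map

Tubular structures (UV, DAo, spine) are reduced by principal-component
analysis of the labeled voxels' patient coordinates. The start/end
keypoints are the points *on the first principal axis* at the minimal and
maximal voxel projections, so the start→end direction coincides with the
principal axis. The naive alternative — the single voxels with extreme
projections — is unstable: on a tube end-cap many voxels tie to within a
voxel of the extreme projection and the winner can sit anywhere on the cap
rim, tilting the axis estimate by several degrees at 1.5 mm resolution.
The mid keypoint is the centroid of voxels whose projection lies within
half a voxel spacing of the median projection (the single nearest voxel if
the slab is empty); the median tolerates uneven voxel density along the
vessel and the slab centroid cancels cross-sectional quantization. Start is
reported as the inferior (smaller-z) endpoint; the choice is cosmetic since
slice orientation is axis-unsigned. Structures with fewer than 3 voxels or
with a first/second principal-extent ratio below 1.5 are rejected: a
near-isotropic blob has no meaningful axis.

Centers of mass are unweighted means of labeled voxel centers mapped to
patient coordinates, and equal the exhaustive per-voxel average by
construction.

### Spine-surrogate DAo planning

When the DAo segmentation is unreliable, its plane orientation can be
taken from the thoracic spine, which runs parallel to the DAo at the lung
level. The positioning rule is: center on the DAo center of mass when any
DAo label exists, otherwise on the spine midpoint displaced 15 mm along
patient-anterior — an anatomical prior for the aorta's position just
anterior to the vertebral column. The exact in-vivo positioning rule used
clinically is not published; this rule reproduces vessel-centered
positioning whenever the DAo is segmented and degrades gracefully
otherwise, and is flagged as a package design choice.

A geometric fact worth recording: for a circular-arc centerline, the chord
(and the principal axis of the swept tube) is exactly parallel to the
tangent at the arc-length midpoint. Vessel-mode planning from principal-
axis keypoints is therefore unbiased under the phantom's arc-shaped DAo at
any curvature — measured errors stay rasterization-dominated (≲0.4°) —
whereas the spine surrogate pays the full tangent rotation, angular error
= κ·L/2 exactly (verified against the analytic value in the tests). The
surrogate is a stability/accuracy trade, not a free lunch.

## Localization

The body backend output is binarized, reduced to its largest 26-connected
component, and internally hole-filled (standard morphology; vessels and
bone inside the body are darker/brighter than soft tissue and must not
punch holes in the mask). The thorax box projects mask voxels on the mask's
first principal axis and keeps the fractional band [0.25, 0.75] of the
projection extent, padded by 10 mm (converted to voxels per axis, rounded
up) and clipped to the grid. The band and margin are a package decision —
"focus on the thorax" has no published geometric definition — validated by
the property that all six landmark structures fall inside the default box
across random fetal lies. The box is voxel-axis-aligned; a patient-axis-
aligned alternative would track the fetal lie but complicate resampling,
and the downstream stages only need containment.

## Segmentation backends

The trained localization/landmark networks are behind a callable seam.
Provided backends: an *oracle* answering from stored ground-truth labels
(nearest-neighbour resampled onto the query grid, optionally eroded/
dilated per label or rigidly jittered by a configurable magnitude, to
emulate network error), a global-threshold backend (Otsu default) with the
same morphological cleanup, and an external-command hook that writes the
query volume to NIfTI, invokes a user executable with input/output paths
as its two trailing arguments, and reads the result back. The hook is the
integration point for any trained model.

## Synthetic thorax phantom

The phantom supplies what desk-scale validation needs: exact geometric
ground truth under arbitrary rigid pose. Canonical anatomy (body-centered
frame, long axis z): an ellipsoidal body (semi-axes 38 × 45 × 58 mm,
≈415 mL); a DAo tube (radius 3 mm, length 40 mm) whose centerline is a
circular arc with curvature κ (default 0 = straight) just anterior to the
spine tube (radius 5 mm, length 44 mm, straight, parallel to the straight
DAo); an oblique straight UV (radius 3 mm, length 30 mm) in the upper
abdomen; a 4 mm-radius sphere at the DAo's inferior (diaphragm) end; two
5 mm lung-apex spheres; and a 4.5 mm-thick elliptical heart–liver slab.
Tubes are rasterized with flat end caps (finite cylinder / torus-sector
tests), so detected endpoints are comparable to the centerline endpoints
rather than displaced by a cap radius. Structures are painted first-wins
(UV, DAo, DAo-D, spine, AP-L, H-L), so labels are disjoint by construction.

The whole fetus is posed by a rigid rotation (xyz Euler angles) plus
translation; rasterization evaluates canonical geometry at inversely
transformed voxel centers, while ground truth (centerlines, keypoints,
midpoint tangents, body volume) is transformed analytically — pose
equivariance of the truth is exact, and any equivariance failure in the
pipeline is attributable to rasterization.

Intensities are per-tissue-class means (background 30, body 100, blood
190, spine 45, lungs 60, interface 130, arbitrary units) corrupted by
Rician noise — magnitude of a complex Gaussian, the correct model for
low-SNR magnitude MR — with σ = 8 by default, emulating a low-field
acquisition. Default grid: 96³ at 1.5 mm isotropic, keeping one phantom
generation near a second so that multi-phantom test sweeps stay cheap.

What the phantom does **not** emulate: bSSFP contrast physics and banding,
cardiac and maternal motion, partial-volume blur, anisotropic voxels,
anatomical variability (vessel tortuosity beyond a circular arc, situs
variants), and multi-fetal pregnancies. Passing parameter-recovery tests
therefore demonstrates the *geometric* correctness of the planning chain
given adequate segmentations — not the performance of any segmentation
network on real scans, which is exactly the part kept behind the backend
seam.

## Evaluation metrics

Dice 2|A∩B|/(|A|+|B|) and IoU |A∩B|/|A∪B| (identity IoU = D/(2−D)), with
the both-empty case defined as 1 (two raters agreeing a structure is
absent agree); center-of-mass distance in patient mm. Planning quality
against phantom truth: angular error arccos|n·t| ∈ [0°, 90°] (axes are
sign-invariant), center offset ‖true mid − center‖, and its out-of-plane
component |(true mid − center)·n| — the part that actually moves the slice
off the vessel. The 0–2 position/orientation reviewer score is retained as
a data type for ingesting human ratings; it is never computed.

## Hemodynamic analysis

EFW [g] = fetal volume [mL] × 1.031 + 120, stored in kg (the intercept and
slope are only dimensionally coherent in grams). Indexed flow = Q/EFW
(mL/kg/min), kept unrounded internally; the reporting convention rounds
half-up to integers. Reference-range bounds are treated as inclusive.
Paired automated/manual comparison: Δ = (manual − automated)/manual × 100
on unrounded indexed values — this direction convention reproduces every
published paired difference in the packaged cohort table, and computing on
rounded values misses them by up to 0.2, so both choices are fixed
accordingly. Within a (case, vessel) cell every automated scan pairs with
every manual scan. One known data wrinkle: one published row (case 6, DAo,
manual; 729 mL/min at 2.52 kg) prints an indexed value of 290 where the
quotient computes to 289.29 → 289, most plausibly because the published
value was derived from an unrounded fetal weight; the packaged table
preserves the printed value and the test suite documents the single
off-by-one disagreement.

## Numerical and degenerate-input choices

- Affines must be invertible (checked at construction); voxel↔patient
  round-trips are exact to <1e−6 mm.
- PCA uses SVD of centered coordinates; axis sign is irrelevant downstream.
  Median ties and the in-plane-basis tie (normal equidistant from two
  canonical axes) resolve deterministically.
- Empty backend output, absent landmarks, isotropic blobs, and coincident
  keypoints raise typed errors; in the pipeline a per-vessel failure skips
  that vessel with a recorded reason while the other vessel proceeds, and
  only localization/landmark failure fails the run globally.
- All randomness (phantom noise, jitter directions) flows from explicit
  integer seeds; identical configuration ⇒ byte-identical output.

## Known limitations

Planning accuracy is validated on synthetic geometry only; no trained
segmentation model, scanner integration, gating, or PC flow extraction is
included (flows enter as scalars). The thorax-band rule assumes a roughly
fetus-shaped mask; pathological anatomies (e.g. congenital heart disease
with displaced vessels) would need different landmark priors, and the
spine-surrogate's parallelism assumption fails exactly where the DAo is
most abnormal. Timings recorded in reports are informational and never
asserted.
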