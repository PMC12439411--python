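# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `vetbrain`, in the order the pipeline runs.

## Coordinate conventions

All affine arithmetic happens in a single world frame: RAS+ millimetres.
DICOM patient coordinates (LPS) are converted on ingest by negating the x
and y components of positions and direction cosines. "LAS orientation"
is expressed as axis codes over that frame: voxel axes increasing toward
the patient's Left, Anterior, Superior. Voxel index (0,0,0) maps to the
*center* of the first voxel (NIfTI convention); grids are half-open.
Oblique acquisitions are snapped to the nearest canonical axes during
reorientation; only singular affines are rejected.

## Ingestion

Slices are grouped by SeriesInstanceUID and sorted by the projection of
their position onto the slice normal (the cross product of the row and
column direction cosines). The plane label comes from the arg-max
absolute component of the normal — superior → TRA, anterior → DOR,
left/right → SAG — with exact ties broken in the order TRA > DOR > SAG.
Slice spacing is taken from the median inter-slice distance rather than
the SliceThickness tag, because gaps and overlaps are common in practice;
gaps deviating more than 1% from uniform are rejected as inconsistent.
When several series map to the same plane, the one with the most slices
is kept and the rest logged. No resampling happens at ingest: every
voxel's world position equals the DICOM Image Position/Orientation
mapping exactly.

## Canonical reconstruction

The reference plane is TRA when available, otherwise DOR, then SAG. It
is cropped to the bounding box of voxels above the volume minimum
("black space" removal; zero-background is the operational definition of
black) and resampled to a `side`³ (default 128³) cube with **one global
scale** — the largest world extent divided by `side` — so anatomical
proportions are preserved and no axis is stretched. Images are
interpolated linearly (the interpolation order of the original resampling
is not documented anywhere; linear is the assumption), masks
nearest-neighbour so they stay binary.

Other planes are resampled onto the exact canonical affine and compared
to the reference:

* **center offset** — Euclidean distance between intensity-weighted
  foreground centroids in world mm;
* **overlap fraction** — `|F_cand ∩ F_ref| / min(|F_cand|, |F_ref|)`.
  The min-denominator keeps the 30% threshold interpretable when fields
  of view differ widely (the denominator choice is otherwise arbitrary).

Foreground for this check is voxels above the 60th percentile of nonzero
intensities — the same convention as the bias-correction mask, so one
foreground notion serves both. A plane is flagged when the offset
*strictly exceeds* 10 mm or the overlap falls *strictly below* 0.30.
Flagged planes are excluded from fusion and get their own single-plane
reconstruction and mask at prediction time; they are never silently
re-registered. Note the centroid offset is measured after resampling to
the canonical field of view, so anatomy pushed partly outside the FOV
yields an *underestimate* of the true displacement — the estimate can
only shrink, never inflate, so flagging stays conservative in the right
direction.

Before fusion each surviving plane is min-max rescaled to [0, 1] over its
foreground: a voxelwise maximum across scanners is meaningless on raw
vendor scales, and rescaling makes "maximum intensity" well-defined. The
rescale parameters per plane are stored in the study provenance together
with every plane's original affine and shape, so masks can be realigned
to the original slices and intensity bands can be traced through the
pipeline.

## Harmonization

Test-time order is fixed: N4 bias-field correction first, then per-case
z-score normalization. N4 internals (B-spline mesh, histogram sharpening)
are delegated to SimpleITK with the two normative parameters — shrink
factor 10 and a fitting mask at the 60th percentile of foreground
intensity — since only the contract matters: a smooth, strictly positive
multiplicative field, estimated on the shrunk image inside the mask, is
divided out.

Z-scoring computes mean and standard deviation over the *foreground* and
maps the whole volume through the same affine transform. Foreground is
"everything except the constant background value", where the background
is detected as the modal voxel value when it occupies over 1% of the
grid. On raw cropped volumes this reduces to "nonzero voxels" (background
zeros would otherwise dominate the statistics), but unlike a literal
nonzero rule it is stable under affine intensity maps — after z-scoring
the background becomes a nonzero constant, the modal-value rule still
finds it, and repeated z-scoring is an exact no-op.

## Augmentation

Each augmentation draws K uniformly from {1, 2, 3}, fits a K-component
Gaussian mixture to the foreground intensity histogram (EM via
scikit-learn, deterministic per seed, components sorted by mean), and
perturbs it: means shift by `±U(0.01, 3.0)`, standard deviations by
`±U(0.01, 0.1)` floored at 0.01, weights unchanged. Three readings of
the published recipe were open and are resolved as follows: shifts are
*signed* (one-sided shifts would systematically brighten; contrast
variation needs both directions); the std perturbation is *additive*
(a ≤0.1 multiplicative change on z-scored σ≈1 would be near-invisible);
and K is both the fitted and the perturbed component count.

Voxels are remapped through the posterior-weighted component transfer
`x → Σₖ γₖ(x)·(σ'ₖ/σₖ·(x−μₖ) + μ'ₖ)` with responsibilities γ under the
*original* mixture, so the map is smooth, anatomy-preserving, and exactly
the identity when the perturbed model equals the original.

Geometric augmentation applies one transform to image (linear) and mask
(nearest-neighbour): left–right flip, rotation about the RL axis
(defaults ±10°), and zoom about the volume center within a [0.8, 1.2]
band. Zoom direction is automated: volumes whose brain-to-foreground
ratio is below 0.25 are zoomed in, others out — an operational proxy for
"zoom in when much of the image is non-brain". A transform that would
push more than 5% of the mask voxels outside the field of view is
refused; the check forward-maps the mask voxel positions analytically
rather than counting output voxels, because a magnified mask can gain
voxels even while being cropped.

## Segmentation backends and post-processing

A backend maps the canonical harmonized volume to probabilities on the
same grid; predictions are thresholded at 0.5. Two backends ship:

* **external-command adapter** — writes NIfTI, runs a configurable shell
  command with `{input}`/`{output}` slots (e.g. an nnU-Net inference
  call), reads the mask back. Training is out of scope.
* **intensity-band oracle** — brain = voxels inside a configured band,
  absolute or in foreground quantiles. This is test instrumentation for
  phantoms whose brain classes occupy a known band; it is not a clinical
  segmenter. An optional binary-opening step (off by default) severs
  thin partial-volume bridges across the skull that any pure threshold
  admits on anisotropic acquisitions.

Post-processing keeps the largest 26-connected component (the standard 3D
connectivity) and removes voxels farther than `center_radius_mm` (default
80 mm, comfortably above any canine brain radius) from that component's
centroid, discarding artefacts far from the brain center. Equal-size
ties keep the component containing the lexicographically smallest voxel
index and warn. The operation never adds voxels and is idempotent on
realistic masks.

## Back-mapping and modality transfer

Masks move between grids by nearest-neighbour resampling through both
affines; output is always binary and confined to the target grid. When a
mask is transferred onto another modality, voxels mapping outside the
target field of view are dropped, and a warning is emitted when under
half of the mask lands inside — the symptom of a patient repositioned
between acquisitions. Such cases are flagged, not rescued by
re-registration, matching the pipeline's QC philosophy; the 50% fraction
is this package's operationalization of a judgement that is otherwise
visual.

## Metrics, splitting, ROI preprocessing

Scores are exhaustive voxel counts; Dice = 2·IoU/(1+IoU) holds by
construction and is asserted in tests. Degenerate denominators (e.g.
both masks empty) score 1.0 but are flagged so pipelines can reject them.
Leave-subject-out splitting groups items by subject, shuffles subjects
deterministically, and assigns greedily (largest group first) to the
smallest fold; every subject's originals and augmentations land in
exactly one fold. ROI preprocessing crops to the mask bounding box plus
a margin and normalizes the histogram by clipping to the in-box [p1, p99]
percentiles and rescaling to [0, 1]; "histogram-based normalisation" is
not otherwise specified, and percentile clip + rescale is the simplest
defensible reading.

## The phantom: what it emulates and what it does not

The generator renders nested ellipsoids on a ≤0.5 mm isotropic grid:
bright subcutaneous tissue (mean 0.88), a dark skull shell (0.12,
default 2.5 mm thick), and a brain carrying 2–3 Gaussian tissue classes
(0.45/0.55/0.62, sd 0.02) in concentric shells, with optional spherical
lesion, smooth multiplicative bias field (Gaussian-filtered noise,
default amplitude 0.1 at 40 mm length scale when enabled), and additive
Gaussian noise inside the head (default sd 0.01 in study conditions).
Default half-axes (head 38×55×40 mm, brain 24×32×22 mm) model a
mesaticephalic mid-size dog; conformation variants stretch the anterior
axis. The intensity layout is deliberate: the skull is darker than brain
and the subcutaneous layer brighter, so a naive global threshold fails
and only a *band* isolates brain — phantom tests stay honest.

Virtual scanning point-samples the reference into per-plane anisotropic
stacks (defaults: TRA 3.0 mm/0.5 mm, DOR 4.0 mm/0.6 mm, SAG 3.5 mm/
0.55 mm — mid-range of clinical protocols spanning 1.5–5 mm thickness
and 0.18–0.86 mm in-plane) with correct orientation cosines and
per-slice positions; a world offset simulates repositioning. Stacks can
be emitted as uncompressed DICOM with exact geometry tags; the round trip
through ingestion is geometrically lossless.

What the phantom does **not** model: MR physics (no k-space, Rician
noise, ghosting or motion), through-slice averaging (slices are
point-sampled at slice centers), real anatomy (no gyri, ventricles or
skull base), or inter-scanner contrast differences beyond affine scaling.
Consequently, passing phantom tests demonstrates the *geometric and
numerical* fidelity of the chain — reconstruction, harmonization,
masking, back-mapping — not clinical segmentation accuracy, which
depends on a trained backend and real data.

## Problem sizes and numerical tolerances

End-to-end checks use ten seeded full-size three-plane studies (reference
grids around 240×180×160 at 0.5 mm); unit tests use a reduced head
(30×42×32 mm half-axes) for speed. Interpolated comparisons carry a
float32 tolerance of ~1e-5; exact claims (reorientation, cropping,
fusion, metric identities, DICOM geometry round-trips) are asserted
bitwise or to 1e-9. The end-to-end Dice of back-mapped oracle masks
measures ≈0.98 against analytic truth; the ~0.02 deficit is
partial-volume loss through the 3–4 mm acquisition chain, which bounds
what any segmenter could achieve on such data.

## Known limitations

* The max-intensity fusion dilates bright structures by the union of the
  per-plane blurs; a learned segmenter absorbs this, but intensity
  thresholds on fused volumes inherit a surface bias of roughly one to
  two canonical voxels.
* Alignment QC measures displacement only within the canonical field of
  view (underestimates for large offsets; flagging is unaffected).
* Enhanced multi-frame DICOM, compressed transfer syntaxes beyond
  pydicom's native support, 4D series and deformable registration are
  out of scope.
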