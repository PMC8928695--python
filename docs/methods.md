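# Methods

## Problem setting

A segmentation-based MRAC pipeline converts T1-weighted MR images into
511 keV attenuation maps by thresholding tissue-probability maps (from a
unified-segmentation tool, recorded as provenance in
`mumap.SEGMENTATION_PROVENANCE`) into four classes and assigning discrete
coefficients: air 0.0, soft tissue 0.096, brain 0.0985, bone
0.151 cm⁻¹. Probability thresholds are 0.25 (air), 0.50 (soft), 0.25
(bone) and 0.50 (brain, the summed grey/white/CSF probability); masks
combine with precedence brain > bone > soft > air, so brain voxels are
protected from skull leakage and unclassified voxels default to air. The
nasal sinus region breaks this scheme: it is an air/soft/fine-bone
mixture that the segmenter mostly labels bone, so a dedicated sinus
treatment replaces the bone assignment there.

## Sinus delineation

**Air cavities.** Interior air is the air-thresholded mask intersected
with a filled head envelope (binary closing + hole fill of the union of
soft, bone and brain masks; a literal intersection of air and soft masks
would be near-empty, and the intent is "air inside the head"). The mask
is summed per axial slice; the seed slice is the largest local maximum of
that profile at or before the largest single inter-slice drop (scanning
toward the head top — sinus cavities end abruptly there; ties: smallest
drop index, then the local maximum closest to the drop). One seed per 2-D
8-connected component in that slice is placed at the component's centre
of mass snapped to the nearest in-component voxel, and the 3-D
26-connected components of the initial mask containing a seed form the
cavity mask; the throat and stray pockets drop out by connectivity. All
tie-break and connectivity choices are fixed but overridable parameters.

**Cuboid fit.** The search region is the anterior half of the head box
(y axis, smaller index = anterior), full lateral extent, and the
cavities' axial extent padded by 5 slices. Candidate boxes have corners
on a stride-2 lattice (stride and the 3³ minimum box are configurable)
and are scored with CG = Σp_i/(a+b+h)², evaluated in O(1) from a 3-D
inclusion–exclusion prefix table; a local stride-1 refinement of ±stride
around each bound follows. A 3-D solid has no standard "perimeter", so
the size penalty reads the total edge length 4(a+b+h) for c, making
(c/4)² = (a+b+h)²; the per-slice rectangle alternative 2(a+b) is a
one-line change. Ties resolve to the smaller volume, then the
lexicographically smallest corner, so the search is fully deterministic;
at stride 1 it equals the exhaustive argmax. No box tilting is attempted.

**Template warp.** A cuboid defined on a canonical grid is pulled back to
the subject: each subject voxel's world coordinate plus the inverse
deformation field's displacement (mm) is looked up in the template mask
with nearest-neighbour interpolation — binary masks stay crisp, and the
warped region need not remain a box. For phantom cohorts the canonical
cuboid is derived from the cohort-mean sinus compartment; for other
deployments the JSON asset's bounds are placeholders to be set once per
site.

## MRI→CT conversion

The model is a monotone three-segment polyline: HU(m) = −1000 for
m ≤ m_low, 0 for m ≥ m_high, linear between. Fitting minimizes the sum
of squared *orthogonal* distances from sample points to the polyline.
Axes are normalized first — HU by 1000 (the curve's vertical span), MRI
by the pool's 99th-percentile intensity — because without normalization
the HU axis dominates "shortest distance". The minimization is an
exhaustive search over a 64×64 breakpoint lattice spanning the pool's
intensity range, followed by one 8× local refinement; an exhaustive
lattice avoids the nondeterminism of derivative-free optimizers, and ties
resolve to the narrowest ramp, then the smallest m_low. Samples lying on
a single plateau cannot constrain both breakpoints and raise an
`IllPosedFitWarning`.

Per subject, 100 voxels are drawn without replacement (with-replacement
available by flag) from the bone-labelled voxels inside that subject's
cuboid/template region, fitted, and the procedure repeated 100 times; the
subject model is the mean of the 100 breakpoint pairs. The lattice bounds
are pinned to the full pool's range so every repeat searches one common
candidate grid. Cohort models average per-subject models with equal
weight; leave-one-out models average all but the held-out subject.
Per-subject bootstrap seeds derive from the subject's *original* cohort
index, so a leave-one-out model is exactly the mean of the retained
subjects' full-cohort models (the workflow reuses cached per-subject
models for this). Bone-to-HU conversion is deliberately out of the
model's range: converted voxels span exactly [−1000, 0] HU and map to
μ = 0.096·(HU+1000)/1000, clamped to [0, 0.096] — capping at the
soft-tissue line minimizes the bias incurred by the fine bone that does
sit in the region.

The printed coefficient for brain tissue is stored as 0.0985 cm⁻¹; a
value ten times larger is physically impossible at 511 keV (water is
≈0.096), and the coefficient is a config field so any value can be
forced.

## CT reference and bilinear scaling

The reference map converts CT HU with a two-segment bilinear transform:
μ = 9.6e-5·(HU+1000) up to 0 HU (air −1000 → 0, water 0 → 0.096 cm⁻¹),
and above 0 HU a slope fixed so that 157 HU ↔ 0.105 cm⁻¹ — the
bone/non-bone boundary value used throughout the evaluation (slightly
below spongy bone at 0.11 cm⁻¹). The transform is continuous, monotone,
and clamped at −1000 HU. CT voxels flagged NaN (un-scanned) are filled
with the soft coefficient where the MR-based map marks soft tissue, else
with air. PET-resolution matching uses isotropic Gaussian smoothing with
FWHM in mm (default 5), zero-padded because the head is surrounded by
air.

## Evaluation

* DICE = 2|A∩B|/(|A|+|B|) between bone masks, CT HU > 157 (strict)
  versus μ > 0.105 cm⁻¹, over the sinus sub-volume (axial slices 50–70,
  1-based inclusive: 21 slices = 4.2 cm at 2 mm) and the whole volume.
  Two empty masks score 1.0 (perfect agreement of absence; configurable).
* Correlation: 100 repetitions of 200 voxels drawn without replacement
  from an inclusion mask, Pearson r per draw. The CT-side HU > 157 pool
  is the default for skull analysis; any mask can be supplied (the
  phantom workflow also samples the sinus compartment, where the
  four-class maps actually vary). Zero-variance draws record NaN, which
  is serialized as null and never silently dropped.
* Sinus-VOI means: arithmetic mean μ over a manually-delineated-VOI
  stand-in, with the converted methods evaluated under their leave-one-out
  models.
* VOI relative difference (mean(PET_MRAC) − mean(PET_CTAC))/mean(PET_CTAC)
  per atlas label, restricted to grey-matter probability ≥ 0.8; empty
  masked labels are absent, zero references yield NaN. Percentages are
  fractions × 100 applied only at presentation.
* Bias atlas: voxelwise relative difference per subject pair, averaged
  across subjects inside a brain mask; outside-mask and zero-reference
  voxels are NaN.

PET reconstruction itself is out of scope; the PET-level operations
accept any co-registered pair of PET-like volumes.

## The phantom generator

Each subject is an ellipsoidal head on a 96³ grid of 2 mm isotropic
voxels: background air (−1000 HU exactly), scalp shell (0 HU), skull
shell (1000 HU, ~6 mm thick), brain interior in white/grey/CSF bands, a
lower airway tube disconnected from the sinuses, and an anterior sinus
compartment. In the facial sector anterior to the sinuses the calvarial
shell thins to ~1 voxel of facial bone embedded in soft tissue, as in
real anatomy — the compartment borders face, not full skull.

The compartment holds two overlapping superellipsoidal air cavities
(exponent 4), a 1-voxel fine-bone wall around them, and soft tissue
elsewhere; the cavity scale is solved by bisection so cavities occupy the
target air fraction (default 0.55 — majority air; wall and soft fractions
≈0.15/0.30 follow from the geometry) of the compartment box (cavity
bounding box + 2 voxels). Latent MRI intensities are class-dependent:
cavity air uniform on [m_low − Δ, m_low], compartment soft tissue on
[m_high, m_high + Δ], wall mixture across the whole
[m_low − Δ, m_high + Δ] range (Δ = 10 % of the ramp width), other classes
Gaussian around class means on a 0–1000 scale. Sinus-compartment CT is
the three-segment law of the latent MRI (breakpoints default 120/880)
plus noise, which reproduces the scatter the conversion model assumes:
concentrations at −1000 and 0 HU with a diagonal between. With both
noise levels at zero every sinus (MRI, HU) pair lies exactly on the law.
Default noise: MRI σ = 10 intensity units, CT σ = 25 HU inside the head
(low-dose CT scale).

The synthetic segmenter emulates unified segmentation: one-hot maps per
true class, except that mixture voxels (wall + compartment soft tissue)
are labelled bone with probability 0.9 — the region is "mostly classified
as bone" — and otherwise fall to air or soft by their HU; 3 % of skull
voxels leak into the soft map. Large air cavities are always labelled
air, which is what makes the cavity-delineation stage solvable.

Deformation fields are a per-axis affine (translation + scale about the
sinus centre, exactly what a template registration captures, with an
exact inverse) plus a small sinusoidal wiggle (0.3 × the 3 mm default
amplitude); forward-then-inverse composition returns to within ~0.1 voxel
on average. Per-subject anatomy jitters head radii, cavity centres and
sizes; per-subject seeds are `spec.seed × 10007 + index`, and identical
spec + seed is bit-identical.

**What the phantom does not emulate:** MR bias fields and Rician noise,
PET emission and reconstruction physics, partial-volume mixing at class
borders, continuous skull density, real inter-subject anatomical
variability, registration error beyond the smooth synthetic fields.
Passing tests therefore demonstrate algorithmic correctness and
statistical recovery under the stated generative model, not clinical
performance.

## Problem sizes and numerical choices

The test suite and the acceptance script run 10-subject cohorts on 96³
grids with the full 100 × 100 bootstrap — the same sampling sizes as the
method itself — which keeps a complete three-method evaluation within a
few minutes on one CPU. Grid compatibility is enforced at 1e-6; the
summed-volume table is float64 (box-sum error ≪ candidate gaps);
breakpoint lattice resolution after refinement is ~0.2 % of the intensity
range; masks are uint8 in NIfTI-1; all derived seeds stay below 2³¹.

## Known limitations

* The square-sum orthogonal-distance criterion is not robust: a few
  percent of gross off-curve outliers (e.g. dense cortical bone at
  +1000 HU inside the region) can collapse the fitted ramp. The region
  definitions keep such voxels rare; a robust loss would be a natural
  extension.
* The cuboid search is axis-aligned by design; severely tilted anatomy
  would fit poorly.
* The bulk method here reuses the warped template as its sinus mask
  (standing in for a registered CT-template mask), so it shares the
  template method's registration dependence.
* DICE differences between methods on phantoms are smaller than on real
  data because the phantom's skull is nearly perfectly classified.
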