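# Methods

## Model and pipeline

The pipeline segments a brain-extracted T2-weighted neonatal volume into
eight tissue classes using atlas priors for stability and morphological
operators for adaptability. All voxel coordinates are 0-based; physical
units are millimetres throughout; every threshold stated in mm³ is
converted with the voxel volume (product of spacings), so anisotropic
acquisitions are handled without special cases. Inputs are reoriented to
canonical (RAS) axis order on load so connectivity and gradient axes are
unambiguous.

### Phase 1/4 — atlas-prior mixture classification

Each class k is a mixture of J Gaussians (default J = 2; the second
component absorbs within-class heterogeneity such as partially myelinated
white matter) over bias-corrected intensity, weighted voxelwise by a prior
probability map:

    P(class k | y_i) ∝ prior_k(i) · Σ_j w_kj N(y_i / b_i ; μ_kj, σ²_kj)

EM alternates posterior computation, closed-form mixture updates (variances
floored at 1e-6 of the in-mask intensity variance to prevent component
collapse), and bias re-estimation. The multiplicative bias field b is
modelled as exp of a polynomial of total degree 3 over [-1,1]³-normalized
coordinates, fitted by ridge regression (penalty = `bias_regularization`,
default 1e-4, times the voxel count) to the log-residuals between observed
and mixture-predicted intensities, then normalized to unit geometric mean
in-mask. A nominal smoothness of 60 mm FWHM is recorded in the
configuration for provenance; with a polynomial basis the order, not that
number, fixes the effective smoothness. A candidate bias update is accepted
only if it does not decrease the observed-data log-likelihood, which makes
the likelihood trace non-decreasing by construction. The fit is fully
deterministic: components initialize at prior-weighted intensity quantiles
((j+0.5)/J), and classes whose priors are indistinguishable (e.g. flat
priors in synthetic fixtures) are deterministically spread across the
pooled quantile range, since EM cannot separate identically initialized
classes.

Priors are floored at 1e-12 inside the mask and renormalized. The floor
matters after template adaptation: the max-rule can drive non-CSF priors to
exactly zero at voxels the watershed claimed, and without a floor those
voxels would be locked to CSF regardless of intensity. 1e-12 is small
enough that priors still dominate under ordinary evidence, yet a likelihood
ratio of ~e^28 (≈ 12 noise SDs, routine for a GM-vs-CSF intensity gap)
overturns it.

Nonlinear registration is deliberately out of scope: priors are assumed
grid-aligned or affinely resampled on load, and externally produced
posterior maps can be injected in place of the built-in classifier
(`--posteriors-in`), so the morphological phases can also be driven by
another classification tool.

Phase 4 re-classifies the filtered image under the adapted template. Its
mixture is warm-started from the converged phase-1 state: the adaptation
changes *spatial priors*, not tissue intensity statistics, and a cold
restart lets the flexible second components of small classes (hippocampus,
amygdala) settle into different local optima between the two phases,
producing spurious label churn on unchanged anatomy. Bias estimation is
re-run from scratch because the filtered image differs from the original.

### Phase 2 — watershed ventricle adaptation

Markers: CSF = phase-1 CSF posterior ≥ 0.9 with connected components
smaller than 500 mm³ removed; cortical GM = posterior ≥ 0.7; background =
non-brain voxels. Marker overlaps resolve CSF > GM > background. The
control image is a multiscale Gaussian gradient magnitude with scales
σ = 0.25 mm and σ = the minimum voxel dimension, computed in physical units
(derivatives divided by the per-axis spacing) and combined across scales by
voxelwise maximum — the strongest edge at either scale is what flooding
should stop at. The watershed is a priority flood from the markers: every
voxel is assigned to exactly one basin (no watershed lines), equal-priority
voxels are served FIFO, and seeds enter the queue in ascending label order
(raster order within a label), making the transform exactly reproducible
and invariant under any strictly increasing transform of the control image.
Face (6-)connectivity is the default everywhere — the conservative choice
for thin neonatal structures; the alternatives are exposed in the
configuration.

The CSF basin, intersected with the brain mask, is max-combined into the
CSF prior. Where the per-voxel class sum then exceeds 1, non-CSF classes
are rescaled proportionally (preserving their relative odds). The CSF prior
never decreases; typical segmentations are essentially unchanged, while
bright ventricle interiors missed by the template are recovered up to the
true boundary ridge.

### Phase 3 — reconstruction filtering

Grayscale reconstruction by dilation of the T2 image from a marker that
equals the image on the confidently detected CSF (the same ≥ 0.9 /
≥ 500 mm³ rule as the phase-2 marker) and the in-mask minimum elsewhere.
The result replaces each voxel by the lowest value on the
highest-intensity path connecting it to the seed: isolated hyperintense
white matter collapses to the level of its surroundings, while seed voxels
and all edges reachable from the seed are preserved exactly. The hard-label
(argmax) reading of "detected CSF" was rejected during implementation: any
bright region the classifier mislabels as CSF — precisely the lesions this
phase exists to remove — would then sit inside the seed and be preserved
verbatim, and small isolated CSF pockets would never be suppressed, leaving
phase 5 without a role. The volume-filtered threshold rule uses only
parameters the pipeline already has.

### Phase 5 — pocket restoration

A flattened CSF pocket takes on the intensity of the gray matter around it,
so phase 4 labels it GM while phase 1 (which saw the original image)
labelled it CSF. Candidates are therefore voxels GM in phase 4 and CSF in
phase 1; a candidate connected component is restored to CSF only if it does
not touch the substantial phase-4 CSF segmentation — components adjacent to
it are ordinary boundary disagreements. "Substantial" means components of
at least the CSF-marker minimum volume (500 mm³): without that filter, one
or two stray CSF-labelled voxels inside a flattened pocket veto the
pocket's own restoration. White-matter pockets are restored by the
symmetric rule (GM in phase 4, WM in phase 1, isolated from the phase-4
WM).

## Evaluation protocol

Per class: Dice (defined as 1.0 when candidate and reference are both
empty), sensitivity and specificity with all counts restricted to an
evaluation domain (default: the brain mask — whole-field-of-view true
negatives would make specificity meaningless), symmetric mean surface
distance and Hausdorff distance between boundary-voxel centres
(face-connectivity boundaries, Euclidean distances in mm; no sub-voxel
meshing — reproducible and oracle-checkable at the ~1-voxel agreement scale
that matters here). The confusion matrix is row-normalized: entry (i, j) is
the percentage of candidate-class-i voxels with reference label j
(background included as a reference column). An option folds hippocampus
and amygdala into cortical gray matter for comparison against protocols
that do not delineate them separately.

## Synthetic phantom

The generator emulates the image properties the pipeline depends on, with
nested-ellipsoid anatomy (peripheral CSF rim, cortical GM shell, WM
compartment, deep GM, paired ventricles, inferior cerebellum and brainstem,
hippocampus/amygdala blobs) on a 64³, 1 mm isotropic grid by default
(~76 cm³ brain; structure volumes in roughly neonatal proportion). Class
mean intensities follow the T2 ordering CSF (100) > WM (75) > GM (55),
with the GM–WM contrast (20) below the CSF–WM contrast (25) as on real
neonatal T2 — this relation is what lets the gray-matter flood claim the
white-matter interior before the CSF flood crosses the stronger ventricle
ridge. Additive Gaussian noise (SD 2.0) and the anatomy are both convolved
with a 1 mm FWHM point-spread function: real acquisitions are band-limited,
edges show partial-volume profiles, and the noise is spatially correlated;
the noise field is rescaled to its nominal SD after smoothing. A smooth
multiplicative bias field is a random second-order polynomial rescaled to a
peak fractional deviation of ±5% by default (±20% in the bias-recovery
experiments). A no-PSF preset exists for experiments about the pure
intensity mixture, and an anisotropic preset (0.35 × 0.35 × 2.0 mm) mirrors
a coronal neonatal acquisition for resampling and gradient tests.

Priors are blurred one-hot maps of the *unscaled* geometry (Gaussian,
1 mm), truncated below 0.005 and renormalized: population templates have
finite support, and that truncation is exactly why an atlas-driven
classifier undersizes pathological ventricles. `ventricle_scale` is the
per-axis (linear) enlargement of the true ventricles relative to that prior
geometry, clipped to the WM compartment; at scale 2–4 the truth boundary
lies many blur-sigmas outside the template support, reproducing the
undersizing failure robustly. Bright WM lesions (intensity 90, strictly
between WM and CSF) perturb intensity only — their true label stays WM —
and are placed greedily at maximal distance from CSF, wholly inside WM.
Isolated CSF pockets are spheres (default 250 mm³) wrapped in a one-voxel
cortical-GM capsule, planted in deep white matter; their disconnection from
all other CSF is asserted at generation time. With noise SD at a quarter of
the smallest between-class mean gap (and no PSF), a nearest-mean classifier
reaches ≥ 95% in-mask accuracy, so pipeline failures are attributable to
the pipeline rather than to an inseparable phantom.

What the phantom does **not** emulate: cortical folding (so it cannot probe
sulcal-CSF/GM fusion), k-space acquisition artifacts, Rician noise (a
config flag is reserved; the pipeline contains no noise-model-specific
step, and Gaussian noise keeps the oracles analytic), multi-subject
template averaging, and real registration error beyond the blur/truncation
model. Passing phantom tests therefore demonstrates the mechanics of the
adaptation, filtering and restoration phases — not clinical accuracy on
real scans.

## Numerical choices and degenerate inputs

* Watershed tie-breaking, seed ordering, and FIFO service are fixed as
  above; tests pin them against a brute-force priority-flood oracle,
  exactly, including all-tied (constant) control images.
* Reconstruction marker > mask violations are clipped with a warning
  (probability-map rounding produces 1-ulp violations routinely).
* Hard labels break exact posterior ties toward the lower class code;
  voxels with all-zero posteriors map to background.
* An empty CSF marker after volume filtering aborts the pipeline with a
  message naming the thresholds to review — without a seed there is
  nothing to adapt.
* A constant in-mask image or an empty mask is rejected by the classifier
  with an error naming the degeneracy.
* Label volumes must be integral; 4D inputs are rejected; NaNs in scalar
  volumes are rejected at load time.

## Problem sizes

The default test and acceptance workloads use 64³ phantoms (the full
pipeline runs in ~10–15 s each), 100 random volumes ≤ 12³ for the
morphology oracles and 50 random 16³ pairs for the metric oracles; the
complete suite and the acceptance script each finish in a few minutes on a
single CPU.

## Known limitations

* The watershed assigns roughly half of the one-voxel partial-volume crest
  ring at CSF–tissue interfaces to the CSF flood; with the adapted template
  those voxels can end up CSF in the final labels. On matched phantoms this
  costs ~0.02 Dice on the cerebellum and is the dominant residual
  instability.
* The bias model is a global degree-3 polynomial: fields with structure
  finer than a few centimetres are not representable.
* The classifier assumes priors are already (at least affinely) aligned;
  severe misalignment beyond the blur/truncation scale of the template is
  not corrected, only the CSF class is adapted.
* Specificity depends strongly on the evaluation domain; it is reported
  within the brain mask by default and is configurable.
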