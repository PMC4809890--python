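# mantis-seg

Morphologically adaptive tissue classification for neonatal T2-weighted
brain MRI.

Tissue classification in neonates is hard for the standard atlas-prior
methods built for adult images: neonatal scans have inverted GM/WM contrast
(unmyelinated white matter is bright on T2), low contrast-to-noise, and —
especially after preterm birth — anatomy that can be very far from any
population template, most visibly enlarged, distorted ventricles and
hyperintense white-matter regions. A classifier driven by tissue probability
maps stays stable on typical anatomy but *undersizes* enlarged ventricles
(the template assigns them near-zero CSF probability) and mislabels bright
white matter as CSF.

This package implements a five-phase pipeline that keeps the stability of
atlas-prior classification while adding data-driven adaptability through
two morphological operators:

1. **Initial classification** — an atlas-prior Gaussian-mixture EM
   classifier (2 Gaussians per tissue class, polynomial multiplicative bias
   field, very light bias regularization 1e-4) produces posterior
   probability maps for eight classes: cortical gray matter, white matter,
   deep nuclear gray matter, CSF, brainstem, cerebellum, hippocampus,
   amygdala.
2. **Watershed ventricle adaptation** — markers are built from the phase-1
   posteriors (CSF ≥ 0.9 with components < 500 mm³ removed; cortical GM
   ≥ 0.7; non-brain voxels as background) and flooded over a multiscale
   Gaussian gradient magnitude (σ = 0.25 mm and σ = the minimum voxel
   dimension). The watershed CSF region is then max-combined into the CSF
   prior, giving a subject-specific template: `P'(CSF) = max(ws, P(CSF))`,
   with the other classes rescaled proportionally where the per-voxel sum
   would exceed 1.
3. **Reconstruction filtering** — grayscale reconstruction by dilation,
   seeded from the confidently detected CSF with the T2 image as the mask,
   flattens isolated hyperintense white matter to the level of its
   surroundings while preserving every edge on a bright path from the seed.
4. **Second classification** — the classifier runs again with the adapted
   template and the filtered image (mixture warm-started from phase 1).
5. **Pocket restoration** — isolated CSF (and WM) pockets that the
   filtering flattened are recovered from the gray-matter differences
   between the two classifications and restored in the final label volume.

Identical processing is applied to every image; no per-subject parameters.

The package also ships the full evaluation protocol (Dice, sensitivity,
specificity, symmetric mean surface distance, Hausdorff distance,
row-normalized confusion matrices) and a deterministic synthetic phantom
generator, so the entire pipeline is testable without clinical data.

## Worked example

Generate a phantom whose true ventricles are three times larger (per axis)
than the template used as prior, run the pipeline, and score it:

```bash
mantis phantom --seed 9 --out work/ph
mantis run --t2 work/ph/t2.nii.gz --mask work/ph/brain_mask.nii.gz \
          --priors work/ph/priors --out work/run
mantis evaluate --candidate work/run/final_labels.nii.gz \
          --reference work/ph/truth.nii.gz --out work/report.json
```

With the default (matched-template) phantom this prints, per class:

```
                  dice  sensitivity  specificity  mean_surface_distance_mm  hausdorff_mm
cortical_gm   0.998847     0.998827     0.999456                  0.004600      2.236068
white_matter  0.992676     0.987711     0.999000                  0.062400      1.414214
deep_gm       0.998974     1.000000     0.999987                  0.002203      1.000000
csf           0.993644     1.000000     0.994472                  0.018009      1.414214
brainstem     0.989806     0.987792     0.999894                  0.051053      1.414214
cerebellum    0.963935     0.947745     0.999178                  0.228434      2.236068
hippocampus   0.947945     0.971910     0.999631                  0.118064      1.414214
amygdala      0.921260     0.983193     0.999526                  0.160406      1.414214
```

Dice is the overlap 2|A∩B|/(|A|+|B|); the surface distances are in mm
between segmentation boundaries (sub-voxel mean distances mean the
boundaries agree to within a voxel nearly everywhere). On phantoms with
ventricles enlarged 2–4× relative to the priors, the initial classification
reaches a median ventricular-CSF Dice of only ≈ 0.18, and the full pipeline
raises it to ≈ 0.998 — that gap is the adaptability the watershed phase
exists to provide (see `scripts/acceptance.py` below).

The same pipeline is run on real data by pointing `--t2` at a
brain-extracted T2-weighted NIfTI volume, `--mask` at its brain mask, and
`--priors` at a directory of eight per-class prior maps (`c1*.nii.gz` …
`c8*.nii.gz`, aligned to the subject or resampled on load). Externally
computed phase-1 posterior maps can replace the built-in classifier via
`--posteriors-in <dir>`. All phase artifacts (markers, control image,
watershed CSF, adapted priors, filtered image, per-phase posteriors) are
written under `<out>/phases/` with a JSON run manifest.

A debug CLI exposes the morphological operators directly:
`mantis morpho reconstruct|watershed|components|gradient`.

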