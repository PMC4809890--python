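"""Deterministic synthetic neonatal T2 phantom generator.

The phantom emulates the properties of brain-extracted T2-weighted neonatal
volumes that the pipeline exploits and the failure modes it corrects:

* nested-ellipsoid anatomy — a peripheral CSF rim, cortical gray-matter
  shell, white-matter compartment, central deep nuclear gray matter and
  lateral ventricles, inferior cerebellum/brainstem lobes, and small
  hippocampus/amygdala blobs;
* T2-like intensity ordering CSF > WM > GM, with GM–WM contrast lower than
  CSF–WM contrast as on real neonatal T2;
* configurable ventricle enlargement: the ground-truth ventricles are
  scaled relative to the geometry used to build the priors, emulating the
  template/subject mismatch of preterm brain injury;
* isolated hyperintense white-matter lesions (intensity between WM and CSF)
  and isolated CSF pockets wrapped in gray matter (sulcal-CSF-like),
  planted disconnected from all other CSF;
* a smooth multiplicative bias field and additive Gaussian noise.

Everything is reproducible from the spec's seed.  Priors are built from the
*unscaled* truth by Gaussian blurring of one-hot maps with support
truncation, emulating a population template's spatial uncertainty and its
finite support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .morphology import Connectivity
from .volumes import (
    LabelVolume,
    ProbabilityMaps,
    ScalarVolume,
    TISSUE_CLASSES,
    TISSUE_CODES,
)

#: Default class mean intensities (arbitrary T2-like units).  CSF is
#: brightest; GM is darker than WM (unmyelinated neonatal white matter has
#: high water content); GM-WM contrast (20) is below CSF-WM contrast (25).
DEFAULT_MEANS: dict[int, float] = {
    1: 55.0,   # cortical gray matter
    2: 75.0,   # white matter
    3: 60.0,   # deep nuclear gray matter
    4: 100.0,  # CSF
    5: 65.0,   # brainstem
    6: 70.0,   # cerebellum
    7: 50.0,   # hippocampus
    8: 45.0,   # amygdala
}


class PlacementError(RuntimeError):
    """Raised when a lesion or pocket cannot be planted with the required
    clearance from CSF on the requested grid."""


@dataclass
class PhantomSpec:
    """Generator settings.

    ventricle_scale:
        Per-axis (linear) enlargement factor applied to the ground-truth
        ventricles relative to the prior geometry; 1.0 means matched
        priors.  Enlarged ventricles are clipped to the white-matter
        compartment, mimicking the distorted ventricles of preterm injury.
    lesion_intensity:
        Mean intensity of bright white-matter lesions; must lie strictly
        between the WM and CSF means.
    pocket_volume_mm3:
        Target volume of each isolated CSF pocket; the planted pocket is a
        digital sphere, so the achieved volume is within one voxel volume
        of the target only for volumes commensurate with the grid.
    psf_fwhm_mm:
        Acquisition point-spread function.  Both the anatomy and the noise
        are convolved with this Gaussian, so edges show partial-volume
        profiles and the noise is spatially correlated (band-limited), as
        in any real MR acquisition.  The noise field is rescaled after
        smoothing so its voxelwise SD equals ``noise_sd``.  0 disables.
    bias_amplitude:
        Peak fractional deviation of the multiplicative bias field (a
        random second-order polynomial, rescaled so max |field - 1| equals
        the amplitude inside the brain).
    noise_sd:
        Additive Gaussian noise SD, one value for all classes unless
        ``class_sds`` overrides per class.
    prior_blur_mm / prior_floor:
        Gaussian blur applied to one-hot truth maps to form priors, and the
        support truncation threshold below which a blurred prior is set to
        zero (templates have finite support).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    class_means: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MEANS))
    class_sds: Mapping[int, float] | None = None
    noise_sd: float = 2.0
    psf_fwhm_mm: float = 1.0
    ventricle_scale: float = 1.0
    n_bright_wm_lesions: int = 0
    lesion_intensity: float = 90.0
    lesion_radius_mm: float = 3.0
    n_isolated_csf_pockets: int = 0
    pocket_volume_mm3: float = 250.0
    bias_amplitude: float = 0.05
    bias_order: int = 2
    prior_blur_mm: float = 1.0
    prior_floor: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        m = self.class_means
        if not (m[4] > m[2] > m[1]):
            raise ValueError(
                "intensity ordering CSF > WM > GM must hold "
                f"(got CSF={m[4]}, WM={m[2]}, GM={m[1]})")
        if self.n_bright_wm_lesions > 0 and not (
                m[2] < self.lesion_intensity < m[4]):
            raise ValueError(
                "lesion intensity must lie strictly between WM and CSF means")
        if self.ventricle_scale < 1:
            raise ValueError("ventricle_scale must be >= 1")
        if self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sd and bias_amplitude must be >= 0")


@dataclass
class PhantomBundle:
    """Image, ground truth, mask, priors and a manifest of planted objects."""

    t2: ScalarVolume
    truth: LabelVolume
    brain_mask: LabelVolume
    priors: ProbabilityMaps
    manifest: dict
    ventricle_mask: np.ndarray
    lesion_mask: np.ndarray
    pocket_mask: np.ndarray
    bias_field: ScalarVolume


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                        indexing="ij")
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, semi_axes):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def _paint_anatomy(shape, ventricle_scale: float):
    """Label geometry; returns (labels, ventricle_mask, region masks)."""
    cx, cy, cz = (s / 2.0 for s in shape)
    sx = min(shape) / 64.0  # proportional scaling for non-default grids
    brain = _ellipsoid(shape, (cx, cy, cz + sx), (26 * sx, 28 * sx, 25 * sx))
    gm_outer = _ellipsoid(shape, (cx, cy, cz + sx),
                          (23.5 * sx, 25.5 * sx, 22.5 * sx))
    wm = _ellipsoid(shape, (cx, cy, cz + sx), (19 * sx, 21 * sx, 18 * sx))

    labels = np.zeros(shape, np.int32)
    labels[brain] = 4                      # peripheral CSF rim
    labels[gm_outer] = 1                   # cortical gray matter shell
    labels[wm] = 2                         # white matter compartment

    deep = _ellipsoid(shape, (cx, cy, cz + 2 * sx), (4 * sx, 6 * sx, 5 * sx))
    labels[deep & wm] = 3

    cereb = _ellipsoid(shape, (cx, cy - 10 * sx, cz - 13 * sx),
                       (13 * sx, 9 * sx, 7 * sx))
    labels[cereb & gm_outer] = 6
    stem = _ellipsoid(shape, (cx, cy + 8 * sx, cz - 12 * sx),
                      (5 * sx, 6 * sx, 8 * sx))
    labels[stem & gm_outer] = 5

    vent = np.zeros(shape, bool)
    for side in (-1, 1):
        v = _ellipsoid(shape, (cx + side * 9 * sx, cy, cz + 2 * sx),
                       (6 * sx * ventricle_scale,
                        11 * sx * ventricle_scale,
                        6 * sx * ventricle_scale))
        vent |= v & wm
    labels[vent] = 4

    for side in (-1, 1):
        hip = _ellipsoid(shape, (cx + side * 12 * sx, cy - 2 * sx, cz - 8 * sx),
                         (3.5 * sx,) * 3)
        labels[hip & wm & ~vent] = 7
        amy = _ellipsoid(shape, (cx + side * 13 * sx, cy + 4 * sx, cz - 8 * sx),
                         (3.0 * sx,) * 3)
        labels[amy & wm & ~vent] = 8

    return labels, vent, brain


def _plant_spheres(labels: np.ndarray, vent: np.ndarray, n: int,
                   radius_vox: float, clearance_vox: float, spacing,
                   what: str):
    """Greedy deterministic placement of ``n`` spheres inside white matter,
    maximally far from CSF and from each other.  Returns list of (center,
    sphere mask)."""
    placed = []
    for i in range(n):
        csf_or_foreign = (labels == 4) | (labels == 0)
        for _, m in placed:
            csf_or_foreign |= ndimage.binary_dilation(
                m, iterations=max(1, int(np.ceil(clearance_vox))))
        dist_csf = ndimage.distance_transform_edt(~csf_or_foreign,
                                                  sampling=spacing)
        # the sphere itself must stay wholly inside white matter
        dist_wm = ndimage.distance_transform_edt(labels == 2,
                                                 sampling=spacing)
        r_mm = radius_vox * max(spacing)
        margin = np.minimum(dist_csf - (r_mm + clearance_vox * max(spacing)),
                            dist_wm - (r_mm + 1.0))
        margin[labels != 2] = -np.inf
        best = float(margin.max())
        if best < 0:
            raise PlacementError(
                f"cannot plant {what} {i + 1}/{n}: insufficient clearance "
                f"inside white matter (short by {-best:.1f} mm)")
        center = np.unravel_index(int(np.argmax(margin)), labels.shape)
        sphere = _ellipsoid(labels.shape, center, (radius_vox,) * 3)
        placed.append((center, sphere))
    return placed


def make_priors(truth: LabelVolume, blur_mm: float,
                floor: float = 0.005,
                codes=TISSUE_CODES) -> ProbabilityMaps:
    """Tissue priors as blurred, support-truncated one-hot truth maps.

    Each class's one-hot map is smoothed with an isotropic Gaussian of
    ``blur_mm`` (in physical units), values below ``floor`` are zeroed
    (finite template support), and per-voxel sums are renormalized to 1
    inside the brain.  ``blur_mm = 0`` returns exact one-hot priors.
    """
    if blur_mm < 0:
        raise ValueError("blur_mm must be non-negative")
    spacing = np.asarray(truth.spacing)
    brain = truth.data > 0
    maps = []
    for code in codes:
        onehot = (truth.data == code).astype(float)
        if blur_mm > 0:
            onehot = ndimage.gaussian_filter(onehot, sigma=blur_mm / spacing)
            onehot[onehot < floor] = 0.0
        maps.append(onehot)
    data = np.stack(maps)
    sums = data.sum(axis=0)
    inside = brain & (sums > 0)
    data[:, inside] /= sums[inside]
    # brain voxels where every class was truncated: fall back to uniform
    orphan = brain & (sums <= 0)
    if orphan.any():
        data[:, orphan] = 1.0 / len(codes)
    data[:, ~brain] = 0.0
    return ProbabilityMaps(np.clip(data, 0.0, 1.0), tuple(codes),
                           truth.affine.copy())


def generate(spec: PhantomSpec) -> PhantomBundle:
    """Build a phantom bundle: T2-like image, truth, mask, priors, manifest.

    The ground-truth ventricles use ``spec.ventricle_scale``; the priors are
    always built from the scale-1 geometry, so any enlargement is a
    template/subject mismatch the pipeline has to adapt to.  Lesions modify
    intensity only (their true label stays white matter); pockets are CSF
    cores wrapped in a one-voxel cortical-GM shell, so suppressing them
    flattens them to gray-matter intensity.  Disconnection of lesions and
    pockets from all other CSF (face connectivity) is asserted at
    generation time.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = tuple(spec.shape), tuple(spec.spacing)
    voxvol = float(np.prod(spacing))

    truth_arr, vent, brain = _paint_anatomy(shape, spec.ventricle_scale)
    prior_arr, _, _ = _paint_anatomy(shape, 1.0)

    # isolated CSF pockets: CSF core + one-voxel GM wrap, in deep WM
    pocket_mask = np.zeros(shape, bool)
    pocket_manifest = []
    if spec.n_isolated_csf_pockets:
        r_vox = (3.0 * spec.pocket_volume_mm3 / (4.0 * np.pi * voxvol)) ** (1 / 3)
        placed = _plant_spheres(truth_arr, vent, spec.n_isolated_csf_pockets,
                                r_vox, clearance_vox=4.0, spacing=spacing,
                                what="CSF pocket")
        for center, sphere in placed:
            wrap = ndimage.binary_dilation(
                sphere, structure=Connectivity.FACE.structure(3), iterations=2)
            for arr in (truth_arr, prior_arr):
                arr[wrap & ~sphere] = 1   # cortical GM capsule
                arr[sphere] = 4           # CSF core
            pocket_mask |= sphere
            pocket_manifest.append({
                "center_voxel": [int(c) for c in center],
                "volume_mm3": float(sphere.sum() * voxvol),
            })

    # bright WM lesions: intensity-only; true label remains WM
    lesion_mask = np.zeros(shape, bool)
    lesion_manifest = []
    if spec.n_bright_wm_lesions:
        r_vox = spec.lesion_radius_mm / min(spacing)
        placed = _plant_spheres(truth_arr, vent, spec.n_bright_wm_lesions,
                                r_vox, clearance_vox=4.0, spacing=spacing,
                                what="bright WM lesion")
        for center, sphere in placed:
            lesion_mask |= sphere
            lesion_manifest.append({
                "center_voxel": [int(c) for c in center],
                "volume_mm3": float(sphere.sum() * voxvol),
                "intensity": spec.lesion_intensity,
            })

    # disconnection assertions (face connectivity)
    csf = truth_arr == 4
    struct = Connectivity.FACE.structure(3)
    if lesion_mask.any():
        near_csf = ndimage.binary_dilation(csf, structure=struct)
        if (lesion_mask & near_csf).any():
            raise PlacementError("planted lesion touches CSF")
    if pocket_mask.any():
        lab, n = ndimage.label(csf, structure=struct)
        pocket_components = set(np.unique(lab[pocket_mask])) - {0}
        other_components = set(np.unique(lab[csf & ~pocket_mask])) - {0}
        if pocket_components & other_components:
            raise PlacementError("planted pocket connects to other CSF")

    # intensities: anatomy and noise are both band-limited by the PSF
    means = np.zeros(9)
    for code, mu in spec.class_means.items():
        means[code] = mu
    img = means[truth_arr]
    img[lesion_mask] = spec.lesion_intensity
    psf_sigma_vox = None
    if spec.psf_fwhm_mm > 0:
        psf_sigma_vox = (spec.psf_fwhm_mm / 2.3548) / np.asarray(spacing)
        img = ndimage.gaussian_filter(img, sigma=psf_sigma_vox)
    noise = rng.standard_normal(shape)
    if psf_sigma_vox is not None:
        noise = ndimage.gaussian_filter(noise, sigma=psf_sigma_vox)
        noise /= max(float(noise.std()), 1e-12)
    if spec.class_sds:
        sds = np.zeros(9)
        for code in TISSUE_CODES:
            sds[code] = spec.class_sds.get(code, spec.noise_sd)
        img = img + noise * sds[truth_arr]
    else:
        img = img + noise * spec.noise_sd

    # smooth multiplicative bias: random low-order polynomial scaled to
    # +/- bias_amplitude inside the brain
    bias = np.ones(shape)
    if spec.bias_amplitude > 0:
        coords = [np.linspace(-1, 1, n) for n in shape]
        grids = np.meshgrid(*coords, indexing="ij")
        f = np.zeros(shape)
        import itertools as _it
        for exps in _it.product(range(spec.bias_order + 1), repeat=3):
            if sum(exps) == 0 or sum(exps) > spec.bias_order:
                continue
            f += rng.normal() * (grids[0] ** exps[0] * grids[1] ** exps[1]
                                 * grids[2] ** exps[2])
        peak = float(np.abs(f[brain]).max())
        if peak > 0:
            bias = 1.0 + spec.bias_amplitude * f / peak
        img = img * bias
    img[~brain] = 0.0

    affine = np.diag(list(spacing) + [1.0])
    truth = LabelVolume(truth_arr, affine, dict(TISSUE_CLASSES))
    priors = make_priors(
        LabelVolume(prior_arr, affine, dict(TISSUE_CLASSES)),
        blur_mm=spec.prior_blur_mm, floor=spec.prior_floor)

    manifest = {
        "seed": spec.seed,
        "shape": list(shape),
        "spacing": list(spacing),
        "ventricle_scale": spec.ventricle_scale,
        "ventricle_volume_mm3": float(vent.sum() * voxvol),
        "lesions": lesion_manifest,
        "pockets": pocket_manifest,
    }
    return PhantomBundle(
        t2=ScalarVolume(img, affine),
        truth=truth,
        brain_mask=LabelVolume(brain.astype(np.int32), affine,
                               {0: "background", 1: "brain"}),
        priors=priors,
        manifest=manifest,
        ventricle_mask=vent,
        lesion_mask=lesion_mask,
        pocket_mask=pocket_mask,
        bias_field=ScalarVolume(bias, affine),
    )
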