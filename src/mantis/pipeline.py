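"""The five-phase morphologically-adaptive segmentation pipeline.

Phase 1  initial atlas-prior classification of the T2 image;
Phase 2  marker-controlled watershed over a multiscale gradient terrain to
         obtain a reliable CSF/ventricle segmentation, then template
         adaptation (CSF prior := max(watershed CSF, CSF prior));
Phase 3  grayscale reconstruction by dilation seeded from confidently
         detected CSF to flatten isolated hyperintense white matter;
Phase 4  re-classification with the adapted template and filtered image;
Phase 5  restoration of isolated CSF/WM pockets suppressed by phase 3,
         detected from the gray-matter differences between the two
         classifications.

Identical processing is applied to every image: no per-subject parameters.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import classifier as clf
from .morphology import (
    Connectivity,
    default_gradient_sigmas,
    filter_small_components,
    multiscale_gradient,
    reconstruct_by_dilation,
    watershed_from_markers,
)
from .volumes import (
    LabelVolume,
    ProbabilityMaps,
    ScalarVolume,
    TISSUE_CLASSES,
    save_priors,
    save_volume,
)

logger = logging.getLogger(__name__)

CSF = 4
CORTICAL_GM = 1
WM = 2

#: Marker codes used by the watershed phase.
MARKER_CODES = {1: "csf_seed", 2: "gm_seed", 3: "background_seed"}


class PipelineError(RuntimeError):
    """A phase failed; the message names the phase."""


@dataclass
class PipelineConfig:
    """Thresholds and scales for the adaptive phases.

    Defaults: CSF marker = CSF posterior >= 0.9 with components smaller
    than 500 mm^3 removed; GM marker = cortical GM posterior >= 0.7;
    gradient scales 0.25 mm and the minimum voxel dimension.  The same
    threshold/volume rule defines the confident-CSF seed used by the
    phase-3 reconstruction, so small isolated CSF pockets are deliberately
    left out of the seed (phase 5 restores them).
    """

    csf_marker_threshold: float = 0.9
    csf_marker_min_volume_mm3: float = 500.0
    gm_marker_threshold: float = 0.7
    gradient_sigmas_mm: tuple[float, ...] | None = None  # None -> defaults
    connectivity: Connectivity = Connectivity.FACE
    classifier: clf.ClassifierConfig = field(default_factory=clf.ClassifierConfig)

    def __post_init__(self) -> None:
        for t in (self.csf_marker_threshold, self.gm_marker_threshold):
            if not 0 < t < 1:
                raise ValueError("marker thresholds must lie in (0, 1)")
        if self.csf_marker_min_volume_mm3 <= 0:
            raise ValueError("csf_marker_min_volume_mm3 must be positive")

    def sigmas_for(self, spacing) -> tuple[float, ...]:
        if self.gradient_sigmas_mm is not None:
            return tuple(self.gradient_sigmas_mm)
        return default_gradient_sigmas(spacing)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "classifier" in raw:
            raw["classifier"] = clf.ClassifierConfig(**raw["classifier"])
        if "connectivity" in raw:
            raw["connectivity"] = Connectivity[str(raw["connectivity"]).upper()]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["connectivity"] = self.connectivity.name
        return d


@dataclass
class PhaseArtifacts:
    """Every named intermediate, all on the input grid."""

    phase1: clf.ClassifierResult
    markers: LabelVolume
    control: ScalarVolume
    watershed_csf: LabelVolume
    adapted_priors: ProbabilityMaps
    filtered_t2: ScalarVolume
    phase4: clf.ClassifierResult
    restored_csf_voxels: int
    restored_wm_voxels: int
    final_labels: LabelVolume
    timings_s: dict[str, float] = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        phases = out / "phases"
        phases.mkdir(parents=True, exist_ok=True)
        save_priors(self.phase1.posteriors, phases / "phase1_posteriors")
        save_volume(self.markers, phases / "phase2_markers.nii.gz")
        save_volume(self.control, phases / "phase2_control.nii.gz")
        save_volume(self.watershed_csf, phases / "phase2_watershed_csf.nii.gz")
        save_priors(self.adapted_priors, phases / "phase2_adapted_priors")
        save_volume(self.filtered_t2, phases / "phase3_filtered_t2.nii.gz")
        save_priors(self.phase4.posteriors, phases / "phase4_posteriors")
        save_volume(self.final_labels, out / "final_labels.nii.gz")


def build_markers(p1: clf.ClassifierResult, brain_mask: np.ndarray,
                  cfg: PipelineConfig) -> LabelVolume:
    """Watershed markers from the phase-1 posteriors.

    CSF seed: CSF posterior >= threshold with small components removed;
    GM seed: cortical GM posterior >= threshold; background seed: non-brain
    voxels.  Overlaps resolve CSF > GM > background (counts are logged).
    """
    post = p1.posteriors
    spacing = post.spacing
    csf = post.map_for(CSF) >= cfg.csf_marker_threshold
    csf = filter_small_components(csf, cfg.csf_marker_min_volume_mm3,
                                  spacing, cfg.connectivity)
    if not csf.any():
        raise PipelineError(
            "phase 2: CSF marker is empty after volume filtering — the "
            "pipeline cannot adapt without a CSF seed; review "
            "csf_marker_threshold/csf_marker_min_volume_mm3")
    gm = post.map_for(CORTICAL_GM) >= cfg.gm_marker_threshold
    background = ~brain_mask.astype(bool)
    overlap = int((csf & gm).sum() + (background & (csf | gm)).sum())
    if overlap:
        logger.info("marker overlaps resolved (csf > gm > background): %d "
                    "voxels", overlap)
    markers = np.zeros(post.shape, np.int32)
    markers[background] = 3
    markers[gm] = 2
    markers[csf] = 1
    return LabelVolume(markers, post.affine.copy(), dict(MARKER_CODES))


def segment_csf_watershed(t2: ScalarVolume, markers: LabelVolume,
                          brain_mask: np.ndarray, cfg: PipelineConfig
                          ) -> tuple[LabelVolume, ScalarVolume]:
    """Watershed CSF segmentation over the multiscale gradient terrain.

    Returns the binary CSF region (intersected with the brain mask) and the
    control image.  Flooding does not shrink a typical CSF segmentation —
    the CSF seed keeps its basin — but spreads across any flat, bright
    enlarged-ventricle interior until it meets the true boundary ridge.
    """
    control = multiscale_gradient(t2.data, cfg.sigmas_for(t2.spacing),
                                  t2.spacing)
    ws = watershed_from_markers(control, markers.data, cfg.connectivity)
    csf = (ws == 1) & brain_mask.astype(bool)
    return (LabelVolume(csf.astype(np.int32), t2.affine.copy(),
                        {0: "background", 1: "csf"}),
            ScalarVolume(control, t2.affine.copy()))


def adapt_template(priors: ProbabilityMaps, csf_ws: LabelVolume
                   ) -> ProbabilityMaps:
    """Subject-specific template: CSF prior := max(watershed CSF, CSF prior).

    Where the per-voxel class sum then exceeds 1, the non-CSF classes are
    rescaled proportionally so the sum returns to 1 (proportional scaling
    preserves the relative odds of the remaining classes).  The CSF prior
    never decreases.
    """
    if priors.shape != csf_ws.shape:
        raise ValueError("adapt_template: geometry mismatch")
    data = priors.data.copy()
    k_csf = priors.codes.index(CSF)
    ws = csf_ws.data.astype(bool)
    new_csf = np.maximum(data[k_csf], ws.astype(float))
    others = [k for k in range(len(priors.codes)) if k != k_csf]
    other_sum = data[others].sum(axis=0)
    total = new_csf + other_sum
    over = total > 1.0 + 1e-12
    if over.any():
        budget = np.clip(1.0 - new_csf[over], 0.0, None)
        scale = np.where(other_sum[over] > 0, budget / other_sum[over], 0.0)
        for k in others:
            data[k][over] *= scale
    data[k_csf] = new_csf
    return ProbabilityMaps(np.clip(data, 0.0, 1.0), priors.codes,
                           priors.affine.copy())


def _confident_csf_seed(p1: clf.ClassifierResult, cfg: PipelineConfig
                        ) -> np.ndarray:
    """Confidently detected CSF: posterior >= CSF marker threshold with
    small components removed.  Used to seed the phase-3 reconstruction, so
    isolated sub-threshold-volume CSF pockets are excluded (and later
    restored by phase 5)."""
    seed = p1.posteriors.map_for(CSF) >= cfg.csf_marker_threshold
    return filter_small_components(seed, cfg.csf_marker_min_volume_mm3,
                                   p1.posteriors.spacing, cfg.connectivity)


def filter_bright_wm(t2: ScalarVolume, p1: clf.ClassifierResult,
                     brain_mask: np.ndarray, cfg: PipelineConfig
                     ) -> ScalarVolume:
    """Phase 3: flatten isolated hyperintense white matter.

    Marker image = T2 intensities on the confident-CSF seed, the global
    in-mask minimum elsewhere; output = reconstruction by dilation of the
    T2 image from that marker.  Intensities never increase; seed voxels and
    every edge on a bright path from the seed are preserved, while bright
    regions disconnected from CSF collapse to the level of their
    surroundings.
    """
    mask_arr = brain_mask.astype(bool)
    seed = _confident_csf_seed(p1, cfg)
    if not seed.any():
        logger.warning("phase 3: empty CSF seed; returning unfiltered image")
        return t2.with_data(t2.data.copy())
    floor = float(t2.data[mask_arr].min())
    marker = np.minimum(np.asarray(t2.data, float), floor)
    marker[seed] = t2.data[seed]
    filtered = reconstruct_by_dilation(marker, t2.data, cfg.connectivity)
    return t2.with_data(filtered)


def restore_pockets(p1: clf.ClassifierResult, p4: clf.ClassifierResult,
                    labels4: LabelVolume, cfg: PipelineConfig
                    ) -> tuple[LabelVolume, int, int]:
    """Phase 5: restore isolated CSF and WM pockets suppressed by phase 3.

    A pocket flattened by the reconstruction takes on gray-matter intensity
    and is classified GM in phase 4 although phase 1 saw it correctly.
    Candidate voxels are therefore GM in phase 4 but CSF (resp. WM) in
    phase 1; a candidate connected component is restored only if it does
    not touch the phase-4 CSF (resp. WM) segmentation — touching components
    are boundary disagreements, not pockets.  Isolation is judged against
    the substantial part of the phase-4 segmentation (components of at
    least the CSF-marker minimum volume): stray single-voxel specks inside
    a flattened pocket must not veto its restoration.
    """
    l1 = p1.hard_labels().data
    l4 = labels4.data.copy()
    struct = cfg.connectivity.structure(3)
    spacing = labels4.spacing
    counts = {}
    for code in (CSF, WM):
        candidates = (l4 == CORTICAL_GM) & (l1 == code)
        restored = np.zeros_like(candidates)
        if candidates.any():
            comp, n = ndimage.label(candidates, structure=struct)
            target = filter_small_components(
                l4 == code, cfg.csf_marker_min_volume_mm3, spacing,
                cfg.connectivity)
            touching = np.unique(comp[ndimage.binary_dilation(
                target, structure=struct) & (comp > 0)])
            keep = np.ones(n + 1, bool)
            keep[0] = False
            keep[touching] = False
            restored = keep[comp]
            l4[restored] = code
        counts[code] = int(restored.sum())
    return (LabelVolume(l4, labels4.affine.copy(), dict(labels4.code_table)),
            counts[CSF], counts[WM])


def run_pipeline(t2: ScalarVolume, brain_mask: LabelVolume,
                 priors: ProbabilityMaps, cfg: PipelineConfig | None = None,
                 phase1_result: clf.ClassifierResult | None = None,
                 out_dir: str | Path | None = None) -> PhaseArtifacts:
    """Execute phases 1-5; deterministic given the configuration.

    ``phase1_result`` lets externally produced posterior maps stand in for
    the built-in classifier (they must share the input grid and class
    codes).  If ``out_dir`` is given, all phase artifacts, the final label
    volume and a JSON run manifest are persisted there.
    """
    cfg = cfg or PipelineConfig()
    if t2.shape != brain_mask.shape or t2.shape != priors.shape:
        raise PipelineError("inputs do not share one grid")
    mask_arr = brain_mask.data.astype(bool)
    timings: dict[str, float] = {}

    def _run(phase: str, fn):
        start = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(f"{phase} failed: {exc}") from exc
        timings[phase] = time.perf_counter() - start
        return result

    p1 = phase1_result or _run(
        "phase1_classification",
        lambda: clf.fit(t2, mask_arr, priors, cfg.classifier))
    markers = _run("phase2_markers", lambda: build_markers(p1, mask_arr, cfg))
    ws_csf, control = _run(
        "phase2_watershed",
        lambda: segment_csf_watershed(t2, markers, mask_arr, cfg))
    adapted = _run("phase2_template_adaptation",
                   lambda: adapt_template(priors, ws_csf))
    filtered = _run("phase3_reconstruction",
                    lambda: filter_bright_wm(t2, p1, mask_arr, cfg))
    # Phase 4 warm-starts its mixture from the phase-1 fit: the adaptation
    # changes spatial priors, not tissue intensity statistics, so the
    # intensity models of the two classifications stay consistent.  Bias
    # estimation restarts from scratch (the filtered image differs).
    p4 = _run("phase4_classification",
              lambda: clf.fit(filtered, mask_arr, adapted, cfg.classifier,
                              init_state=p1.mixture))
    labels4 = p4.hard_labels()
    final, n_csf, n_wm = _run(
        "phase5_restoration", lambda: restore_pockets(p1, p4, labels4, cfg))
    logger.info("phase 5 restored %d CSF and %d WM pocket voxels", n_csf, n_wm)

    # per-phase class voxel-count deltas for audit
    l1 = p1.hard_labels().data
    for code in sorted(TISSUE_CLASSES):
        if code == 0:
            continue
        logger.info("class %s: phase1 %d -> final %d voxels",
                    TISSUE_CLASSES[code], int((l1 == code).sum()),
                    int((final.data == code).sum()))

    artifacts = PhaseArtifacts(
        phase1=p1, markers=markers, control=control, watershed_csf=ws_csf,
        adapted_priors=adapted, filtered_t2=filtered, phase4=p4,
        restored_csf_voxels=n_csf, restored_wm_voxels=n_wm,
        final_labels=final, timings_s=timings)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        artifacts.save(out)
        manifest = {
            "config": cfg.to_dict(),
            "timings_s": timings,
            "restored_csf_voxels": n_csf,
            "restored_wm_voxels": n_wm,
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return artifacts
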