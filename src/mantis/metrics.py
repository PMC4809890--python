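"""Segmentation evaluation: overlap, surface distances and confusion.

Per tissue class the report holds the Dice coefficient, sensitivity and
specificity (counts restricted to an evaluation domain, by default the
brain mask), the symmetric mean surface distance and the Hausdorff
distance, both in millimetres between boundary-voxel centres.  The
confusion matrix is row-normalized: entry (i, j) is the percentage of
candidate-class-i voxels whose reference label is j (background included
as a reference column), so each row sums to 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .volumes import LabelVolume, TISSUE_CLASSES


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty
    (perfect agreement on absence)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError(f"dice: grid mismatch {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _boundary_points(mask: np.ndarray, spacing) -> np.ndarray:
    """Physical coordinates of boundary voxels: foreground voxels with at
    least one face neighbour outside the mask (the array edge counts as
    outside)."""
    mask = np.asarray(mask, bool)
    struct = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=struct,
                                      border_value=0)
    boundary = mask & ~interior
    coords = np.argwhere(boundary).astype(float)
    return coords * np.asarray(spacing[:mask.ndim], float)


def surface_distances(a: np.ndarray, b: np.ndarray,
                      spacing=(1.0, 1.0, 1.0)) -> tuple[float, float]:
    """Symmetric mean surface distance and Hausdorff distance in mm.

    Boundary point sets are the centres of face-boundary voxels; the mean
    surface distance averages the two directed mean distances, and the
    Hausdorff distance is the larger of the two directed maxima.
    """
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError("surface_distances: grid mismatch")
    if not a.any() or not b.any():
        raise ValueError("undefined surface distance for an empty mask")
    pa = _boundary_points(a, spacing)
    pb = _boundary_points(b, spacing)
    d_ab, _ = cKDTree(pb).query(pa, k=1)
    d_ba, _ = cKDTree(pa).query(pb, k=1)
    msd = 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))
    hd = max(float(d_ab.max()), float(d_ba.max()))
    return msd, hd


def sensitivity_specificity(candidate: np.ndarray, reference: np.ndarray,
                            domain: np.ndarray) -> tuple[float, float]:
    """True positive and true negative rates within an evaluation domain.

    All counts are restricted to ``domain`` (typically the brain mask, so
    that specificity is not inflated by the empty field of view).  An empty
    reference within the domain makes sensitivity undefined (NaN, with a
    warning).
    """
    domain = np.asarray(domain, bool)
    if not domain.any():
        raise ValueError("evaluation domain is empty")
    c = np.asarray(candidate, bool) & domain
    r = np.asarray(reference, bool) & domain
    tp = int((c & r).sum())
    fn = int((~c & r).sum())
    fp = int((c & ~r & domain).sum())
    tn = int((~c & ~r & domain).sum())
    if tp + fn == 0:
        warnings.warn("empty reference within domain: sensitivity undefined",
                      stacklevel=2)
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


def confusion_matrix(candidate: LabelVolume, reference: LabelVolume,
                     codes=None) -> pd.DataFrame:
    """Row-normalized confusion: % of candidate-class voxels per reference
    label (rows: candidate classes; columns: reference classes plus
    background)."""
    if candidate.shape != reference.shape:
        raise ValueError("confusion_matrix: grid mismatch")
    if codes is None:
        codes = sorted(c for c in TISSUE_CLASSES if c != 0)
    cand = candidate.data.ravel()
    ref = reference.data.ravel()
    ncodes = int(max(cand.max(), ref.max())) + 1
    counts = np.bincount(cand * ncodes + ref,
                         minlength=ncodes * ncodes).reshape(ncodes, ncodes)
    col_codes = [0] + list(codes)
    rows = {}
    for code in codes:
        row = counts[code, :] if code < ncodes else np.zeros(ncodes)
        total = row.sum()
        vals = [100.0 * (row[c] if c < ncodes else 0) / total if total else 0.0
                for c in col_codes]
        rows[TISSUE_CLASSES.get(code, f"class_{code}")] = vals
    cols = [TISSUE_CLASSES.get(c, f"class_{c}") for c in col_codes]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


@dataclass
class MetricsReport:
    per_class: pd.DataFrame          # rows: class names; dice/sens/spec/msd/hd
    confusion: pd.DataFrame          # row-normalized percentages

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion": self.confusion.to_dict(orient="index"),
        }


def evaluate(candidate: LabelVolume, reference: LabelVolume,
             domain: np.ndarray | None = None,
             merge_limbic_into_cortex: bool = False) -> MetricsReport:
    """Full per-class evaluation of a candidate against a reference.

    ``merge_limbic_into_cortex`` folds hippocampus and amygdala into the
    cortical gray-matter class in both volumes before scoring (for
    comparison against protocols that do not delineate them separately).
    Surface distances are NaN when either mask is empty for a class.
    """
    if candidate.shape != reference.shape:
        raise ValueError("evaluate: grid mismatch")
    cand = candidate.data.copy()
    ref = reference.data.copy()
    codes = sorted(c for c in TISSUE_CLASSES if c != 0)
    if merge_limbic_into_cortex:
        for arr in (cand, ref):
            arr[(arr == 7) | (arr == 8)] = 1
        codes = [c for c in codes if c not in (7, 8)]
    if domain is None:
        domain = ref > 0
    spacing = reference.spacing
    rows = {}
    for code in codes:
        cm = cand == code
        rm = ref == code
        d = dice(cm, rm)
        if (rm & domain).any():
            sens, spec = sensitivity_specificity(cm, rm, domain)
        else:  # class absent from the reference: sensitivity undefined
            sens = float("nan")
            tn = int((~cm & domain).sum())
            fp = int((cm & domain).sum())
            spec = tn / (tn + fp) if tn + fp else float("nan")
        if cm.any() and rm.any():
            msd, hd = surface_distances(cm, rm, spacing)
        else:
            msd = hd = float("nan")
        rows[TISSUE_CLASSES[code]] = {
            "dice": d, "sensitivity": sens, "specificity": spec,
            "mean_surface_distance_mm": msd, "hausdorff_mm": hd,
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    conf = confusion_matrix(
        LabelVolume(cand, candidate.affine, dict(candidate.code_table)),
        LabelVolume(ref, reference.affine, dict(reference.code_table)),
        codes=codes)
    return MetricsReport(per_class=per_class, confusion=conf)
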