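"""Independent brute-force oracles used to validate the fast operators.

These deliberately share no code with the implementations they check:
reconstruction iterates explicit neighbour-shift maxima; the watershed
oracle selects the next voxel by a linear scan over the frontier; surface
distances enumerate all boundary-point pairs.
"""

from __future__ import annotations

import numpy as np

from mantis.morphology import Connectivity


def _neighbor_shifts(ndim: int, conn: Connectivity):
    """Offsets of the connectivity neighbourhood (excluding the centre)."""
    rank = min(conn.value, ndim)
    shifts = []
    for delta in np.ndindex(*(3,) * ndim):
        d = tuple(x - 1 for x in delta)
        order = sum(abs(x) for x in d)
        if 0 < order <= rank:
            shifts.append(d)
    return shifts


def _shift(arr: np.ndarray, delta, fill):
    out = np.full_like(arr, fill)
    src = tuple(slice(max(0, -d), arr.shape[i] - max(0, d))
                for i, d in enumerate(delta))
    dst = tuple(slice(max(0, d), arr.shape[i] - max(0, -d))
                for i, d in enumerate(delta))
    out[dst] = arr[src]
    return out


def reconstruct_oracle(marker: np.ndarray, mask: np.ndarray,
                       conn: Connectivity) -> np.ndarray:
    """Iterate unit-dilate (neighbour-shift maximum) + voxelwise minimum
    with the mask until the fixed point."""
    marker = np.minimum(np.asarray(marker, float), np.asarray(mask, float))
    shifts = _neighbor_shifts(marker.ndim, conn)
    current = marker.copy()
    while True:
        dilated = current.copy()
        for d in shifts:
            np.maximum(dilated, _shift(current, d, -np.inf), out=dilated)
        nxt = np.minimum(dilated, mask)
        if np.array_equal(nxt, current):
            return nxt
        current = nxt


def watershed_oracle(control: np.ndarray, markers: np.ndarray,
                     conn: Connectivity) -> np.ndarray:
    """Priority flood implemented as a linear-scan frontier.

    Semantics mirror the documented contract: pop the frontier voxel with
    the lowest (control value, insertion counter); label its unlabelled
    neighbours and append them.  Seeds enter in ascending label order,
    raster order within each label.
    """
    control = np.asarray(control, float)
    labels = np.asarray(markers).astype(np.int64).copy()
    shifts = _neighbor_shifts(control.ndim, conn)
    shape = control.shape

    front_idx: list[tuple] = []
    front_val: list[float] = []
    front_ctr: list[int] = []
    ctr = 0
    for lab in np.unique(labels[labels > 0]):
        for pos in np.argwhere(labels == lab):
            pos = tuple(int(p) for p in pos)
            front_idx.append(pos)
            front_val.append(float(control[pos]))
            front_ctr.append(ctr)
            ctr += 1
    while front_idx:
        vals = np.array(front_val)
        best = np.flatnonzero(vals == vals.min())
        ctrs = np.array(front_ctr)[best]
        i = int(best[np.argmin(ctrs)])
        pos = front_idx.pop(i)
        front_val.pop(i)
        front_ctr.pop(i)
        lab = labels[pos]
        for d in shifts:
            npos = tuple(p + dd for p, dd in zip(pos, d))
            if any(p < 0 or p >= s for p, s in zip(npos, shape)):
                continue
            if labels[npos] == 0:
                labels[npos] = lab
                front_idx.append(npos)
                front_val.append(float(control[npos]))
                front_ctr.append(ctr)
                ctr += 1
    return labels


def boundary_points_oracle(mask: np.ndarray, spacing) -> np.ndarray:
    """Boundary voxels by explicit face-neighbour inspection."""
    mask = np.asarray(mask, bool)
    pts = []
    for pos in np.argwhere(mask):
        pos = tuple(int(p) for p in pos)
        on_edge = False
        for ax in range(mask.ndim):
            for step in (-1, 1):
                npos = list(pos)
                npos[ax] += step
                if not (0 <= npos[ax] < mask.shape[ax]) or \
                        not mask[tuple(npos)]:
                    on_edge = True
        if on_edge:
            pts.append([p * s for p, s in zip(pos, spacing)])
    return np.array(pts, float)


def surface_distances_oracle(a: np.ndarray, b: np.ndarray,
                             spacing) -> tuple[float, float]:
    """All-pairs O(n^2) symmetric mean and Hausdorff surface distances."""
    pa = boundary_points_oracle(a, spacing)
    pb = boundary_points_oracle(b, spacing)
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
    d = np.sqrt(d2)
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    msd = 0.5 * (d_ab.mean() + d_ba.mean())
    hd = max(d_ab.max(), d_ba.max())
    return float(msd), float(hd)


def confusion_oracle(cand: np.ndarray, ref: np.ndarray, codes,
                     col_codes) -> np.ndarray:
    """Exhaustive pairwise tally, row-normalized to percentages."""
    out = np.zeros((len(codes), len(col_codes)))
    for i, ci in enumerate(codes):
        sel = cand == ci
        total = sel.sum()
        if total == 0:
            continue
        for j, cj in enumerate(col_codes):
            out[i, j] = 100.0 * ((sel) & (ref == cj)).sum() / total
    return out
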