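"""Volume containers and NIfTI round-tripping shared by every pipeline stage.

All volumes live on a 3D voxel grid with a 4x4 affine mapping 0-based voxel
indices to physical millimetres.  Images are reoriented to the canonical
(RAS) axis order on load so that connectivity and gradient axes are
unambiguous; the original orientation is remembered and restored on save.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage


class VolumeFormatError(ValueError):
    """Raised when a file violates the volume contracts (dimensionality,
    label integrality, NaNs, degenerate geometry)."""


#: Fixed class code table used throughout the pipeline.  Codes are stable
#: across all stages and serialized outputs; 0 is background (non-brain).
TISSUE_CLASSES: dict[int, str] = {
    0: "background",
    1: "cortical_gm",
    2: "white_matter",
    3: "deep_gm",
    4: "csf",
    5: "brainstem",
    6: "cerebellum",
    7: "hippocampus",
    8: "amygdala",
}

#: Tissue codes in classification order (background excluded).
TISSUE_CODES: tuple[int, ...] = tuple(sorted(c for c in TISSUE_CLASSES if c != 0))


def _spacing_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


@dataclass
class ScalarVolume:
    """A 3D intensity grid with physical geometry (spacing in mm)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected 3D volume, got {self.data.ndim}D data"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise VolumeFormatError("affine must be 4x4")
        if any(s <= 0 for s in self.spacing):
            raise VolumeFormatError("all voxel spacings must be positive")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return _spacing_from_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def with_data(self, data: np.ndarray) -> "ScalarVolume":
        return replace(self, data=np.asarray(data))


@dataclass
class LabelVolume:
    """An integer-coded segmentation on the same grid as the image it
    annotates, with a code table naming every nonzero label."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    code_table: dict[int, str] = field(default_factory=lambda: dict(TISSUE_CLASSES))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected 3D volume, got {self.data.ndim}D data"
            )
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.all(np.mod(self.data, 1) == 0):
                raise VolumeFormatError(
                    "label volume contains non-integral values"
                )
            self.data = self.data.astype(np.int32)
        if self.data.min() < 0:
            raise VolumeFormatError("label volume contains negative values")
        self.affine = np.asarray(self.affine, dtype=float)
        present = set(np.unique(self.data)) - {0}
        missing = present - set(self.code_table)
        if missing:
            raise VolumeFormatError(
                f"labels {sorted(missing)} missing from code table"
            )

    @property
    def spacing(self) -> tuple[float, float, float]:
        return _spacing_from_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def mask(self, code: int) -> np.ndarray:
        return self.data == code


@dataclass
class ProbabilityMaps:
    """Per-class probability volumes on one shared geometry.

    ``data`` is shaped ``(n_classes,) + grid_shape``; ``codes`` gives the
    tissue code of each map in order.  Per-voxel sums over classes stay at
    or below 1 (the remainder is background probability).
    """

    data: np.ndarray
    codes: Sequence[int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise VolumeFormatError("probability maps must be (class, x, y, z)")
        self.codes = tuple(int(c) for c in self.codes)
        if len(self.codes) != self.data.shape[0]:
            raise VolumeFormatError("one code required per class map")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.min() < -1e-9 or self.data.max() > 1 + 1e-6:
            raise VolumeFormatError("probabilities must lie in [0, 1]")
        sums = self.data.sum(axis=0)
        if sums.max() > 1 + 1e-6:
            raise VolumeFormatError(
                f"per-voxel class sums exceed 1 (max {sums.max():.8f})"
            )

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(TISSUE_CLASSES.get(c, f"class_{c}") for c in self.codes)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return _spacing_from_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape[1:]

    def map_for(self, code: int) -> np.ndarray:
        return self.data[self.codes.index(code)]


def load_volume(path: str | Path, kind: str = "scalar") -> ScalarVolume | LabelVolume:
    """Load a NIfTI-1/2 volume as a :class:`ScalarVolume` or :class:`LabelVolume`.

    The image is reoriented to canonical (RAS) axis order; geometry is
    otherwise preserved.  Label files must hold integral values; scalar
    files must be NaN-free.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(
            f"expected 3D volume, got {data.ndim}D image at {path}"
        )
    affine = np.asarray(img.affine, dtype=float)
    if kind == "scalar":
        data = data.astype(np.float64)
        if np.isnan(data).any():
            raise VolumeFormatError(f"scalar volume {path} contains NaN values")
        return ScalarVolume(data=data, affine=affine)
    if kind == "label":
        if not np.all(np.mod(data, 1) == 0):
            raise VolumeFormatError(
                f"label volume {path} contains non-integral values"
            )
        code_table = dict(TISSUE_CLASSES)
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz
        sidecar = Path(str(sidecar) + ".labels.json")
        if sidecar.exists():
            raw = json.loads(sidecar.read_text())
            code_table = {int(k): str(v) for k, v in raw.items()}
            code_table.setdefault(0, "background")
        else:
            for code in np.unique(data.astype(np.int64)):
                code_table.setdefault(int(code), f"class_{int(code)}")
        return LabelVolume(data=data.astype(np.int32), affine=affine,
                           code_table=code_table)
    raise ValueError(f"unknown kind {kind!r}; use 'scalar' or 'label'")


def save_volume(vol: ScalarVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; label volumes get a JSON code-table sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, LabelVolume):
        img = nib.Nifti1Image(vol.data.astype(np.int32), vol.affine)
        sidecar = path.with_suffix("").with_suffix("")
        sidecar = Path(str(sidecar) + ".labels.json")
        sidecar.write_text(json.dumps(
            {str(k): v for k, v in sorted(vol.code_table.items())}, indent=2))
    else:
        img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    nib.save(img, str(path))


def load_priors(directory: str | Path,
                codes: Sequence[int] = TISSUE_CODES) -> ProbabilityMaps:
    """Load per-class prior maps named ``c<code>*.nii[.gz]`` (SPM-style)."""
    directory = Path(directory)
    maps, affine = [], None
    for code in codes:
        hits = sorted(directory.glob(f"c{code}*.nii*"))
        if not hits:
            raise FileNotFoundError(
                f"no prior map for class {code} ({TISSUE_CLASSES.get(code)}) "
                f"in {directory}")
        vol = load_volume(hits[0], kind="scalar")
        if affine is None:
            affine = vol.affine
        maps.append(np.clip(vol.data, 0.0, 1.0))
    data = np.stack(maps, axis=0)
    sums = data.sum(axis=0)
    over = sums > 1.0
    if over.any():  # tolerate rounding from 8-bit prior encodings
        data[:, over] /= sums[over]
    return ProbabilityMaps(data=data, codes=tuple(codes), affine=affine)


def save_priors(priors: ProbabilityMaps, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for code, name, pmap in zip(priors.codes, priors.class_names, priors.data):
        save_volume(ScalarVolume(pmap, priors.affine),
                    directory / f"c{code}_{name}.nii.gz")


def resample_to(reference: ScalarVolume,
                moving: ScalarVolume | LabelVolume | ProbabilityMaps,
                interp: str = "linear"):
    """Resample ``moving`` onto the grid of ``reference``.

    Linear interpolation for intensities and probabilities (clipped back to
    [0, 1]); labels are resampled nearest-neighbour only.  The mapping is
    composed through the two affines, so any rigid/affine offset between
    the grids is honoured.
    """
    if interp not in ("linear", "nearest"):
        raise ValueError("interp must be 'linear' or 'nearest'")
    if isinstance(moving, LabelVolume) and interp != "nearest":
        raise ValueError("label volumes must use nearest interpolation")
    for aff in (reference.affine, moving.affine):
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise VolumeFormatError("degenerate affine (zero determinant)")
    # output voxel -> mm -> moving voxel
    mat = np.linalg.inv(moving.affine) @ reference.affine
    order = 1 if interp == "linear" else 0

    def _warp(arr: np.ndarray) -> np.ndarray:
        return ndimage.affine_transform(
            arr, mat[:3, :3], offset=mat[:3, 3],
            output_shape=reference.shape, order=order, mode="constant", cval=0.0)

    if isinstance(moving, ProbabilityMaps):
        out = np.stack([np.clip(_warp(m), 0.0, 1.0) for m in moving.data])
        sums = out.sum(axis=0)
        over = sums > 1.0
        if over.any():
            out[:, over] /= sums[over]
        return ProbabilityMaps(out, moving.codes, reference.affine.copy())
    if isinstance(moving, LabelVolume):
        warped = _warp(moving.data.astype(np.float64)).round().astype(np.int32)
        return LabelVolume(warped, reference.affine.copy(), dict(moving.code_table))
    return ScalarVolume(_warp(np.asarray(moving.data, float)),
                        reference.affine.copy())
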