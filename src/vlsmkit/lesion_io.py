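"""Binary lesion-mask I/O and cohort assembly.

Lesion masks (volumes of interest, VOIs) are binary 3-D images on a shared
template grid -- typically MNI space after spatial normalization, which is
assumed to have happened upstream. This module reads and writes masks as
NIfTI, harmonizes them onto a common grid by explicit nearest-neighbour
resampling, stacks them into cohorts, and builds overlay frequency maps
(how many patients' tumors cover each voxel).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: Affines are considered identical when every element agrees within this
#: tolerance (mm). Beyond it an explicit resample is required; silent
#: resampling would hide registration errors.
AFFINE_TOL = 1e-4

__all__ = [
    "AFFINE_TOL",
    "VolumeGrid",
    "LesionMask",
    "LesionCohort",
    "OverlayMap",
    "read_mask",
    "write_mask",
    "resample_to_grid",
    "build_overlay",
    "subset_cohort",
    "read_manifest",
    "write_overlay_nifti",
]


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a 3-D sampling grid: shape plus voxel-to-world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    space_label: str = ""

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be a positive triple, got {shape}")
        affine = np.array(self.affine, dtype=float)  # copy: frozen below
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        affine.setflags(write=False)
        object.__setattr__(self, "affine", affine)

    def matches(self, other: "VolumeGrid", tol: float = AFFINE_TOL) -> bool:
        return self.shape == other.shape and bool(
            np.all(np.abs(self.affine - other.affine) <= tol)
        )

    @classmethod
    def isotropic(
        cls, shape: Sequence[int], voxel_mm: float = 1.0, space_label: str = ""
    ) -> "VolumeGrid":
        """Axis-aligned grid with isotropic voxels, origin at the corner."""
        affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        return cls(tuple(shape), affine, space_label)


@dataclass
class LesionMask:
    """One patient's binary tumor mask on a :class:`VolumeGrid`."""

    sample_id: str
    grid: VolumeGrid
    voxels: np.ndarray

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.shape != self.grid.shape:
            raise ValueError(
                f"{self.sample_id}: voxel array shape {vox.shape} does not "
                f"match grid shape {self.grid.shape}"
            )
        uniq = np.unique(vox)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"{self.sample_id}: mask voxels must be binary")
        self.voxels = vox.astype(np.uint8)

    @property
    def volume_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        """An empty mask is representable but not a valid tumor VOI."""
        return self.volume_voxels == 0


class LesionCohort:
    """An aligned, ordered stack of binary lesion masks.

    All masks must share the grid (within :data:`AFFINE_TOL`), have unique
    sample ids, and be non-empty: every included patient has a tumor.
    """

    def __init__(self, masks: Iterable[LesionMask]):
        masks = list(masks)
        if not masks:
            raise ValueError("cohort must contain at least one mask")
        grid = masks[0].grid
        ids = []
        for m in masks:
            if not grid.matches(m.grid):
                raise ValueError(
                    f"mask {m.sample_id!r} is not on the cohort grid; "
                    "resample explicitly with resample_to_grid()"
                )
            if m.is_empty:
                raise ValueError(f"mask {m.sample_id!r} is empty")
            ids.append(m.sample_id)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in cohort")
        self.grid = grid
        self.masks = masks
        self.sample_ids = ids
        self._stack: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self):
        return iter(self.masks)

    def stacked(self) -> np.ndarray:
        """Boolean array of shape (n_samples, *grid.shape); cached."""
        if self._stack is None:
            self._stack = np.stack([m.voxels.astype(bool) for m in self.masks])
        return self._stack

    def volumes(self) -> np.ndarray:
        return np.array([m.volume_voxels for m in self.masks])


@dataclass
class OverlayMap:
    """Per-voxel count of masks covering that voxel (lesion frequency map)."""

    grid: VolumeGrid
    counts: np.ndarray
    n_samples: int


def read_mask(
    path: str | Path,
    expected_grid: VolumeGrid | None = None,
    sample_id: str | None = None,
    strict: bool = False,
    threshold: float = 0.5,
) -> LesionMask:
    """Read a binary lesion mask from a NIfTI file.

    Data are binarized at ``threshold`` (probability maps become masks); in
    ``strict`` mode any value outside {0, 1} is an error instead. If
    ``expected_grid`` is given and the file's grid differs beyond tolerance
    a ``ValueError`` is raised -- resampling is never silent.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    if strict:
        uniq = np.unique(data)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"{path}: non-binary data in strict mode")
    vox = (data > threshold).astype(np.uint8)
    grid = VolumeGrid(tuple(data.shape), img.affine)
    if expected_grid is not None and not grid.matches(expected_grid):
        raise ValueError(
            f"{path}: grid mismatch with expected grid; call resample_to_grid()"
        )
    sid = sample_id if sample_id is not None else path.name.split(".")[0]
    mask = LesionMask(sid, grid, vox)
    if mask.is_empty:
        warnings.warn(f"{path}: mask has no lesioned voxels (invalid as tumor VOI)")
    return mask


def write_mask(mask: LesionMask, path: str | Path) -> Path:
    """Write a mask as uint8 NIfTI, preserving the affine."""
    path = Path(path)
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))
    return path


def resample_to_grid(mask: LesionMask, grid: VolumeGrid) -> LesionMask:
    """Nearest-neighbour resample of a binary mask onto a target grid.

    Each target voxel is pulled back through the composed world transform
    (target voxel -> mm -> source voxel) and sampled at the nearest source
    voxel; out-of-field voxels are 0. Binarity is preserved by construction.
    """
    if grid.matches(mask.grid):
        return LesionMask(mask.sample_id, grid, mask.voxels.copy())
    # target ijk -> world -> source ijk
    composed = np.linalg.inv(mask.grid.affine) @ grid.affine
    ii, jj, kk = np.indices(grid.shape)
    coords = np.stack(
        [ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)], axis=0
    )
    src = composed @ coords
    src_ijk = np.rint(src[:3]).astype(int)
    inb = np.all(
        (src_ijk >= 0) & (src_ijk < np.array(mask.grid.shape)[:, None]), axis=0
    )
    out = np.zeros(int(np.prod(grid.shape)), dtype=np.uint8)
    si, sj, sk = src_ijk[:, inb]
    out[inb] = mask.voxels[si, sj, sk]
    return LesionMask(mask.sample_id, grid, out.reshape(grid.shape))


def build_overlay(cohort: LesionCohort) -> OverlayMap:
    """Sum the cohort's masks voxel-wise into a lesion frequency map."""
    counts = cohort.stacked().sum(axis=0).astype(np.int32)
    return OverlayMap(cohort.grid, counts, len(cohort))


def subset_cohort(cohort: LesionCohort, keep_ids: Iterable[str]) -> LesionCohort:
    """Order-preserving subset of a cohort by sample id."""
    keep = set(keep_ids)
    unknown = keep - set(cohort.sample_ids)
    if unknown:
        raise KeyError(f"unknown sample ids: {sorted(unknown)}")
    kept = [m for m in cohort.masks if m.sample_id in keep]
    return LesionCohort(kept)


def read_manifest(path: str | Path, expected_grid: VolumeGrid | None = None) -> LesionCohort:
    """Assemble a cohort from a manifest CSV with columns sample_id, mask_path.

    Relative mask paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if not {"sample_id", "mask_path"}.issubset(df.columns):
        raise ValueError("manifest needs columns sample_id, mask_path")
    masks = []
    for _, row in df.iterrows():
        mpath = Path(row["mask_path"])
        if not mpath.is_absolute():
            mpath = path.parent / mpath
        masks.append(read_mask(mpath, expected_grid, sample_id=str(row["sample_id"])))
    return LesionCohort(masks)


def write_overlay_nifti(overlay: OverlayMap, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(overlay.counts.astype(np.int32), overlay.grid.affine)
    nib.save(img, str(path))
    return path
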