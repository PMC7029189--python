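"""Volumetric I/O: NIfTI reading/writing, ROI extraction, and region demeaning.

All model computation downstream operates in 0-based voxel-index space; the
affine is carried on :class:`VolumeGrid` only for I/O and for reporting
world-millimetre coordinates.  Mask voxel ordering is fixed (lexicographic by
z, then y, then x) so that every derived quantity is reproducible across runs
and platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "RegionMask",
    "RegionTimeSeries",
    "load_volume",
    "save_volume",
    "mask_from_volume",
    "masks_from_parcellation",
    "extract_region",
    "remove_region_mean",
    "write_parameter_map",
    "read_network_table",
]

#: Connective-field parameters that may be painted back into a volume.
PARAMETER_NAMES = ("x0", "y0", "z0", "sigma", "fit_r2")


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a 3-D voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along each of the three axes.
    affine
        4x4 voxel-index -> world (mm) transform, NIfTI convention.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(affine[:3, :3])) < np.finfo(float).tiny:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def matches(self, other: "VolumeGrid", tol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=tol)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    @classmethod
    def isotropic(cls, shape: Sequence[int], voxel_size: float = 1.0) -> "VolumeGrid":
        aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
        return cls(tuple(shape), aff)


def _canonical_order(indices: np.ndarray) -> np.ndarray:
    """Sort voxel indices lexicographically by z, then y, then x."""
    order = np.lexsort((indices[:, 0], indices[:, 1], indices[:, 2]))
    return indices[order]


@dataclass(frozen=True)
class RegionMask:
    """An ordered set of in-grid voxel indices naming one region of interest."""

    grid: VolumeGrid
    voxel_indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        idx = np.asarray(self.voxel_indices, dtype=np.intp)
        if idx.ndim != 2 or idx.shape[1] != 3:
            raise ValueError("voxel_indices must be an (n, 3) integer array")
        if idx.shape[0] == 0:
            raise ValueError(f"mask {self.label!r} is empty")
        if (idx < 0).any() or (idx >= np.asarray(self.grid.shape)).any():
            raise ValueError(f"mask {self.label!r} has voxels outside the grid")
        idx = _canonical_order(idx)
        flat = np.ravel_multi_index(idx.T, self.grid.shape)
        if np.unique(flat).size != flat.size:
            raise ValueError(f"mask {self.label!r} contains duplicate voxels")
        object.__setattr__(self, "voxel_indices", idx)

    def __len__(self) -> int:
        return self.voxel_indices.shape[0]

    @property
    def coords(self) -> np.ndarray:
        """Voxel indices as floats, the default coordinate frame of model fits."""
        return self.voxel_indices.astype(float)

    @property
    def world_coords(self) -> np.ndarray:
        """Voxel centers in world millimetres (through the grid affine)."""
        return self.grid.voxel_to_world(self.voxel_indices)

    def to_volume(self) -> np.ndarray:
        vol = np.zeros(self.grid.shape, dtype=np.uint8)
        vol[tuple(self.voxel_indices.T)] = 1
        return vol


@dataclass
class RegionTimeSeries:
    """Per-voxel BOLD residual time courses for one region.

    ``data`` is (n_voxels, n_timepoints), rows aligned with
    ``mask.voxel_indices``.  ``demeaned`` records whether the across-voxel mean
    time course has been removed.
    """

    mask: RegionMask
    data: np.ndarray
    demeaned: bool = False

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be 2-D (voxels x time)")
        if data.shape[0] != len(self.mask):
            raise ValueError(
                f"data has {data.shape[0]} rows but mask {self.mask.label!r} "
                f"has {len(self.mask)} voxels"
            )
        self.data = data

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def load_volume(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    """Load a 3-D or 4-D NIfTI volume.

    Returns the data array (3-D for single volumes, with any trailing
    singleton time axis squeezed; 4-D otherwise) and the grid geometry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:  # nibabel raises several exception types
        raise IOError(f"could not read NIfTI volume {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim not in (3, 4):
        raise IOError(f"{path}: expected a 3-D or 4-D volume, got {data.ndim}-D")
    if np.isnan(data).all():
        raise ValueError(f"{path}: volume contains no finite values")
    grid = VolumeGrid(data.shape[:3], np.asarray(img.affine))
    return data, grid


def save_volume(data: np.ndarray, grid: VolumeGrid, path: str | Path) -> Path:
    """Write an array on ``grid`` to a NIfTI-1 file."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data), grid.affine)
    nib.save(img, str(path))
    return path


def mask_from_volume(
    mask_vol: np.ndarray, grid: VolumeGrid, label: str = "", threshold: float = 0.5
) -> RegionMask:
    """Build a :class:`RegionMask` from a binary (or probabilistic) 3-D volume."""
    mask_vol = np.asarray(mask_vol)
    if mask_vol.shape != grid.shape:
        raise ValueError("mask volume shape does not match grid")
    idx = np.argwhere(np.nan_to_num(mask_vol) > threshold)
    if idx.shape[0] == 0:
        raise ValueError(f"mask {label!r} selects no voxels")
    return RegionMask(grid, idx, label=label)


def masks_from_parcellation(
    labels_vol: np.ndarray, grid: VolumeGrid, ids: Sequence[int] | None = None
) -> dict[int, RegionMask]:
    """Split an integer-labeled parcellation volume into per-parcel masks.

    Label 0 is background by convention.
    """
    labels_vol = np.asarray(np.rint(np.nan_to_num(labels_vol)), dtype=int)
    if labels_vol.shape != grid.shape:
        raise ValueError("parcellation shape does not match grid")
    present = [int(v) for v in np.unique(labels_vol) if v != 0]
    if ids is not None:
        missing = sorted(set(int(i) for i in ids) - set(present))
        if missing:
            raise ValueError(f"parcel ids absent from the parcellation: {missing}")
        present = [int(i) for i in ids]
    return {
        pid: RegionMask(grid, np.argwhere(labels_vol == pid), label=str(pid))
        for pid in present
    }


def extract_region(
    data4d: np.ndarray, grid: VolumeGrid, mask: RegionMask
) -> RegionTimeSeries:
    """Pull the voxel-by-time matrix of a region out of a 4-D volume."""
    data4d = np.asarray(data4d, dtype=float)
    if data4d.ndim == 3:
        data4d = data4d[..., np.newaxis]
    if data4d.ndim != 4 or data4d.shape[:3] != grid.shape:
        raise ValueError("4-D data shape does not match grid")
    if not mask.grid.matches(grid):
        raise ValueError(
            f"mask {mask.label!r} grid (shape {mask.grid.shape}) does not match "
            f"the data grid (shape {grid.shape})"
        )
    rows = data4d[tuple(mask.voxel_indices.T)]
    dead = ~(np.abs(rows) > 0).any(axis=1)
    if dead.any():
        warnings.warn(
            f"region {mask.label!r}: {int(dead.sum())} all-zero voxel series retained",
            stacklevel=2,
        )
    return RegionTimeSeries(mask=mask, data=rows, demeaned=False)


def remove_region_mean(ts: RegionTimeSeries) -> RegionTimeSeries:
    """Subtract the region's mean time course from every voxel's series.

    Removes correlation carried by the shared regional mean signal so that
    connective-field fits reflect voxel-specific covariance.  Requires at
    least two voxels (on a single voxel the operation annihilates the signal).
    """
    if ts.n_voxels < 2:
        raise ValueError("region-mean removal needs >= 2 voxels")
    mean_tc = np.nanmean(ts.data, axis=0, keepdims=True)
    return RegionTimeSeries(mask=ts.mask, data=ts.data - mean_tc, demeaned=True)


def write_parameter_map(fields, grid: VolumeGrid, which: str, path: str | Path) -> Path:
    """Paint one fitted parameter of a :class:`~topofield.confield.ConnectiveFieldMap`
    into a NIfTI volume (NaN outside the seed mask)."""
    if which not in PARAMETER_NAMES:
        raise ValueError(f"unknown parameter {which!r}; choose from {PARAMETER_NAMES}")
    if len(fields.fields) == 0:
        raise ValueError("connective field map holds no fitted fields")
    vol = np.full(grid.shape, np.nan)
    for f in fields.fields:
        vol[tuple(int(i) for i in f.seed_voxel)] = getattr(f, which)
    return save_volume(vol, grid, path)


def read_network_table(path: str | Path) -> pd.DataFrame:
    """Read a parcel -> network assignment table (TSV with columns
    ``parcel_id`` and ``network``)."""
    df = pd.read_csv(path, sep="\t")
    required = {"parcel_id", "network"}
    if not required.issubset(df.columns):
        raise ValueError(f"network table must have columns {sorted(required)}")
    df["parcel_id"] = df["parcel_id"].astype(int)
    return df
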