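"""NIfTI volume handling and canonical ROI time-series extraction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["BoldVolume", "read_volume", "write_volume", "read_mask", "extract_roi_series"]


@dataclass
class BoldVolume:
    """A 4-D BOLD dataset: data array (X, Y, Z, T), voxel-to-world affine, TR."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got shape {self.data.shape}")
        if self.affine.shape != (4, 4) or np.linalg.det(self.affine[:3, :3]) == 0:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if self.data.shape[3] < 1:
            raise ValueError("need at least one timepoint")

    @property
    def shape3d(self):
        return self.data.shape[:3]

    @property
    def n_timepoints(self):
        return self.data.shape[3]


def read_volume(path, tr_seconds=None):
    """Read a NIfTI file as a :class:`BoldVolume`.

    3-D images are promoted to 4-D with T = 1 (with a warning).  The TR is
    taken from the header zooms unless overridden.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        warnings.warn(f"{path}: 3-D image promoted to 4-D with T=1", RuntimeWarning)
        data = data[..., None]
    elif data.ndim != 4:
        raise ValueError(f"{path}: expected 3-D or 4-D image, got shape {data.shape}")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return BoldVolume(data=data.astype(np.float64), affine=img.affine, tr_seconds=tr_seconds)


def write_volume(vol, path):
    """Write a :class:`BoldVolume` (or a 3-D map with an affine) to NIfTI."""
    if isinstance(vol, BoldVolume):
        data, affine, tr = vol.data, vol.affine, vol.tr_seconds
    else:
        raise TypeError("write_volume expects a BoldVolume")
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = tr
    img.header.set_zooms(zooms)
    nib.save(img, str(path))
    return path


def write_map(values3d, affine, path):
    """Write a 3-D spatial map to NIfTI."""
    img = nib.Nifti1Image(np.asarray(values3d, dtype=np.float32), np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    return path


def read_mask(path, reference=None, atol=1e-4):
    """Read a 3-D binary mask; optionally check alignment against a reference volume.

    Raises if the mask's shape or affine disagrees with the reference (both
    shapes printed), since silent misalignment is the classic failure mode.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: mask must be 3-D, got shape {data.shape}")
    mask = data > 0
    if reference is not None:
        if mask.shape != reference.shape3d:
            raise ValueError(
                f"mask shape {mask.shape} does not match data shape {reference.shape3d}"
            )
        if not np.allclose(img.affine, reference.affine, atol=atol):
            raise ValueError(
                f"mask affine differs from data affine beyond {atol}:\n"
                f"{img.affine}\nvs\n{reference.affine}"
            )
    return mask


def voxel_index_table(mask, affine):
    """Canonical ordering of in-mask voxels: ascending flat index, x fastest.

    Returns a DataFrame with voxel indices (i, j, k) and world coordinates in
    mm; the row order defines the column order of every extracted matrix, so
    all downstream stages are invariant to how the input file was laid out.
    """
    mask = np.asarray(mask, dtype=bool)
    i, j, k = np.nonzero(mask)
    flat = np.ravel_multi_index((i, j, k), mask.shape, order="F")
    order = np.argsort(flat)
    i, j, k = i[order], j[order], k[order]
    ijk1 = np.column_stack([i, j, k, np.ones(i.size)])
    world = ijk1 @ np.asarray(affine, dtype=float).T
    return pd.DataFrame(
        {"i": i, "j": j, "k": k, "x_mm": world[:, 0], "y_mm": world[:, 1], "z_mm": world[:, 2]}
    )


def extract_roi_series(vol, mask):
    """Extract a time x voxel matrix from a :class:`BoldVolume` under a mask.

    Voxel ordering is canonical (see :func:`voxel_index_table`).
    Returns ``(data, index_table)``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape3d:
        raise ValueError(f"mask shape {mask.shape} does not match data shape {vol.shape3d}")
    if not mask.any():
        raise ValueError("empty mask")
    table = voxel_index_table(mask, vol.affine)
    data = vol.data[table["i"].to_numpy(), table["j"].to_numpy(), table["k"].to_numpy(), :].T
    return np.ascontiguousarray(data, dtype=float), table
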