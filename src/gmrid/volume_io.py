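"""Volume container, canonical voxel indexing, and NIfTI / npz I/O.

The flattened volume is the vector y of the degradation model
``y = x + n``; every module converts between grid and linear voxel
indices through :func:`linear_index` / :func:`grid_index` so that
eigenvectors and voxels never go out of alignment.

Canonical linearization: 0-based, C-order (last axis fastest).
Internal compute precision is float64 regardless of the on-disk dtype;
NIfTI output is stored as float32.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

log = logging.getLogger("gmrid")


class UnsupportedFormatError(ValueError):
    """Raised for files that are not 3D scalar volumes in a known format."""


@dataclass
class Volume:
    """A 3D scalar intensity grid with voxel geometry.

    Parameters
    ----------
    data : ndarray
        3D real-valued intensities; stored as float64.
    voxel_size : tuple of float
        Physical spacing per axis in mm (default isotropic 1 mm).
    affine : ndarray or None
        Optional 4x4 voxel-to-world matrix, preserved on NIfTI round trips.
    """

    data: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise UnsupportedFormatError(
                f"expected a 3D volume, got {self.data.ndim}D data"
            )
        if self.data.size < 1:
            raise ValueError("volume must contain at least one voxel")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must all be finite")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n(self) -> int:
        """Total voxel count n = nx * ny * nz."""
        return int(self.data.size)

    @property
    def intensity_range(self) -> tuple:
        return float(self.data.min()), float(self.data.max())

    def flat(self) -> np.ndarray:
        """The volume as the length-n column vector y (canonical C-order)."""
        return self.data.reshape(-1)


def linear_index(ijk, shape) -> np.ndarray:
    """Grid coordinates -> canonical linear index (C-order, last axis fastest)."""
    i, j, k = np.asarray(ijk[0]), np.asarray(ijk[1]), np.asarray(ijk[2])
    return np.ravel_multi_index((i, j, k), shape, order="C")


def grid_index(idx, shape) -> tuple:
    """Canonical linear index -> grid coordinates (i, j, k)."""
    return np.unravel_index(np.asarray(idx), shape, order="C")


def read_volume(path) -> Volume:
    """Read a 3D volume from NIfTI-1 (.nii/.nii.gz) or the plain .npz format.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    UnsupportedFormatError
        For non-3D data (e.g. 4D time series) or unknown extensions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if np.iscomplexobj(data):
            raise UnsupportedFormatError("complex-valued volumes are not supported")
        data = np.squeeze(data) if data.ndim == 4 and data.shape[-1] == 1 else data
        if data.ndim != 3:
            raise UnsupportedFormatError(
                f"expected a 3D volume, got {data.ndim}D data in {path}"
            )
        zooms = img.header.get_zooms()[:3]
        return Volume(data.astype(np.float64), voxel_size=zooms, affine=img.affine)
    if name.endswith(".npz"):
        with np.load(path) as f:
            data = f["data"]
            if np.iscomplexobj(data):
                raise UnsupportedFormatError("complex-valued volumes are not supported")
            if data.ndim != 3:
                raise UnsupportedFormatError(
                    f"expected a 3D volume, got {data.ndim}D data in {path}"
                )
            voxel_size = tuple(f["voxel_size"]) if "voxel_size" in f else (1.0, 1.0, 1.0)
            affine = f["affine"] if "affine" in f else None
        return Volume(data, voxel_size=voxel_size, affine=affine)
    raise UnsupportedFormatError(
        f"unrecognized volume format: {path} (expected .nii, .nii.gz or .npz)"
    )


def write_volume(vol: Volume, path) -> None:
    """Write a Volume; read_volume(write_volume(v)) preserves data/shape/voxel_size.

    NIfTI output is float32; the .npz format keeps full float64 precision.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        affine = vol.affine if vol.affine is not None else np.diag(list(vol.voxel_size) + [1.0])
        img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
        img.header.set_zooms(vol.voxel_size)
        nib.save(img, str(path))
    elif name.endswith(".npz"):
        payload = {"data": vol.data, "voxel_size": np.asarray(vol.voxel_size)}
        if vol.affine is not None:
            payload["affine"] = vol.affine
        np.savez(path, **payload)
    else:
        raise UnsupportedFormatError(
            f"unrecognized output format: {path} (expected .nii, .nii.gz or .npz)"
        )


def rescale_to_unit(vol: Volume):
    """Map intensities to [0,1] by the volume's own min/max.

    Returns the rescaled Volume and the (lo, hi) pair needed to undo the
    map.  Noise levels quoted as a percentage of the maximum intensity
    become plain fractions of this rescaled range.  Constant volumes are
    mapped to zeros (hi - lo is degenerate; restore still round-trips).
    """
    lo, hi = vol.intensity_range
    span = hi - lo
    if span <= 0:
        data = np.zeros_like(vol.data)
    else:
        data = (vol.data - lo) / span
    return Volume(data, voxel_size=vol.voxel_size, affine=vol.affine), (lo, hi)


def restore_from_unit(data01: np.ndarray, bounds) -> np.ndarray:
    lo, hi = bounds
    span = hi - lo
    if span <= 0:
        return np.full_like(data01, lo)
    return lo + data01 * span
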