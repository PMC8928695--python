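"""Volume containers, NIfTI I/O, and shared grid primitives.

Every stage of the pipeline moves data around as :class:`VolumeGrid`
objects: a 3-D scalar field (or a 3-component displacement field) with a
voxel spacing in millimetres and a voxel-to-world affine.  Axis convention
is ``(x, y, z)`` with ``z`` the axial slice index; smaller ``y`` is
anterior.  All pairwise operations require the two grids to agree in shape,
spacing and affine to within a small tolerance.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Tuple

import nibabel as nib
import numpy as np
from scipy import ndimage

#: FWHM of a Gaussian in units of its standard deviation, 2*sqrt(2*ln 2).
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

GRID_TOL = 1e-6


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


def _default_affine(spacing: Tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class VolumeGrid:
    """A scalar or displacement volume on a regular grid.

    Parameters
    ----------
    data:
        ``(nx, ny, nz)`` scalar array, or ``(nx, ny, nz, 3)`` displacement
        array holding per-voxel world-space displacements in millimetres.
    spacing:
        Per-axis voxel size in millimetres, strictly positive.
    affine:
        4x4 voxel-index to world-coordinate map.  Defaults to a diagonal
        affine built from ``spacing``.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4) or (
            self.data.ndim == 4 and self.data.shape[-1] != 3
        ):
            raise ValueError(
                f"expected a 3-D volume or (.., 3) displacement field, "
                f"got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    # -- convenience -------------------------------------------------
    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def is_vector(self) -> bool:
        return self.data.ndim == 4

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """New volume carrying ``data`` on this grid."""
        return VolumeGrid(data, self.spacing, self.affine.copy())

    def copy(self) -> "VolumeGrid":
        return self.like(self.data.copy())

    def world_coordinates(self) -> np.ndarray:
        """``(nx, ny, nz, 3)`` world coordinates of every voxel centre (mm)."""
        idx = np.indices(self.shape, dtype=float)
        pts = np.stack([idx[0], idx[1], idx[2], np.ones(self.shape)], axis=-1)
        world = pts @ self.affine.T
        return world[..., :3]


def grids_compatible(a: VolumeGrid, b: VolumeGrid, tol: float = GRID_TOL) -> bool:
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=tol)
        and np.allclose(a.affine, b.affine, atol=tol)
    )


def require_same_grid(*volumes: VolumeGrid, tol: float = GRID_TOL) -> None:
    """Raise :class:`GridMismatchError` unless all volumes share one grid."""
    ref = volumes[0]
    for v in volumes[1:]:
        if not grids_compatible(ref, v, tol=tol):
            raise GridMismatchError(
                f"grid mismatch: {ref.shape}/{ref.spacing} vs {v.shape}/{v.spacing}"
            )


def require_binary(v: VolumeGrid) -> None:
    vals = np.unique(v.data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask volume must contain only {0, 1}")


@dataclass
class TissueProbabilitySet:
    """Six aligned tissue-probability volumes from unified MR segmentation.

    ``grey``, ``white`` and ``csf`` are the brain classes; ``soft`` is
    scalp/soft tissue, ``bone`` is skull, ``air`` is (interior and exterior)
    air.  Each map is bounded in [0, 1].
    """

    grey: VolumeGrid
    white: VolumeGrid
    csf: VolumeGrid
    soft: VolumeGrid
    bone: VolumeGrid
    air: VolumeGrid

    CLASS_NAMES = ("grey", "white", "csf", "soft", "bone", "air")

    def __post_init__(self) -> None:
        require_same_grid(*self.maps())
        for name, v in zip(self.CLASS_NAMES, self.maps()):
            if v.data.min() < -GRID_TOL or v.data.max() > 1 + GRID_TOL:
                raise ValueError(f"probability map '{name}' not within [0, 1]")

    def maps(self) -> Tuple[VolumeGrid, ...]:
        return (self.grey, self.white, self.csf, self.soft, self.bone, self.air)

    def items(self) -> Iterator[Tuple[str, VolumeGrid]]:
        return zip(self.CLASS_NAMES, self.maps())

    @property
    def grid(self) -> VolumeGrid:
        return self.grey

    def brain_probability(self) -> VolumeGrid:
        """Combined grey + white + CSF probability, clipped to [0, 1]."""
        p = self.grey.data + self.white.data + self.csf.data
        return self.grey.like(np.clip(p, 0.0, 1.0))


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path) -> VolumeGrid:
    """Read a 3-D NIfTI-1 volume (optionally gzipped), promoting to float.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for
    an image that is not 3-D.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got shape {data.shape}")
    data = np.asarray(data, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(data, spacing, np.asarray(img.affine, dtype=float))


def read_displacement_field(path) -> VolumeGrid:
    """Read a 3-component displacement field stored as a 4-D NIfTI.

    Accepts ``(nx, ny, nz, 3)`` or the SPM-style ``(nx, ny, nz, 1, 3)``
    layout; displacements are interpreted as world-space millimetres.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 5 and data.shape[3] == 1:
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: expected (nx,ny,nz,3) field, got {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(data, spacing, np.asarray(img.affine, dtype=float))


def write_volume(volume: VolumeGrid, path, dtype=None) -> None:
    """Write a volume as NIfTI-1; ``dtype`` overrides the stored dtype."""
    data = volume.data if dtype is None else volume.data.astype(dtype)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_zooms(tuple(volume.spacing) + ((1.0,) if volume.is_vector else ()))
    nib.save(img, str(path))


def write_mask(mask: VolumeGrid, path) -> None:
    """Write a binary mask as unsigned 8-bit NIfTI-1."""
    require_binary(mask)
    write_volume(mask, path, dtype=np.uint8)


# ---------------------------------------------------------------------------
# Smoothing / resampling primitives
# ---------------------------------------------------------------------------

def gaussian_smooth(volume: VolumeGrid, fwhm_mm: float) -> VolumeGrid:
    """Isotropic Gaussian smoothing with a FWHM given in millimetres.

    The kernel standard deviation is ``fwhm / (2 sqrt(2 ln 2))`` converted
    to voxels per axis.  Zero-padding is used at the boundary (the head is
    surrounded by air, which is 0 in a mu-map).  ``fwhm_mm == 0`` is the
    identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return volume.copy()
    sigma_vox = [fwhm_mm / FWHM_TO_SIGMA / s for s in volume.spacing]
    if volume.is_vector:
        sigma_vox = sigma_vox + [0.0]
    out = ndimage.gaussian_filter(
        np.asarray(volume.data, dtype=float), sigma=sigma_vox, mode="constant", cval=0.0
    )
    return volume.like(out)
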