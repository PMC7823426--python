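"""Voxel-grid containers and mask/matrix plumbing.

All voxel maps travel through :class:`VolumeGrid` (a 3D lattice plus a
voxel-to-world affine), boolean :class:`Mask` objects select the analysis
voxels, and :class:`MaskedMatrix` holds the subjects x in-mask-voxels value
matrix that the multivariate decomposition consumes.  Stacking volumes into a
matrix and un-masking a per-voxel vector back into a volume are exact inverse
operations inside the mask.

Voxel coordinates are 0-based and the in-mask voxel order is row-major over
the lattice, so matrices round-trip bit-exactly and reproducibly.  All
modalities of a study must share one grid; a grid mismatch is a hard error
rather than a silent resample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "Mask",
    "MaskedMatrix",
    "compute_mask",
    "stack_volumes",
    "unmask",
    "smooth_gaussian",
]

#: conversion between Gaussian FWHM and standard deviation
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

AFFINE_ATOL = 1e-4


@dataclass
class VolumeGrid:
    """A 3D scalar lattice with a voxel-to-world affine.

    Parameters
    ----------
    data
        3D array of voxel values.
    affine
        4x4 voxel-to-world transform (homogeneous coordinates).
    units
        Free-text label for the voxel values (e.g. ``"GM volume"``).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("every lattice dimension must be >= 1")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def congruent(self, other: "VolumeGrid | Mask", atol: float = AFFINE_ATOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image, units: str = "") -> "VolumeGrid":
        data = np.asanyarray(img.dataobj)
        return cls(data=np.asarray(data, dtype=float), affine=np.asarray(img.affine), units=units)

    @classmethod
    def load(cls, path, units: str = "") -> "VolumeGrid":
        return cls.from_nifti(nib.load(str(path)), units=units)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


@dataclass
class Mask:
    """Boolean analysis mask congruent with a :class:`VolumeGrid`."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        self.affine = np.asarray(self.affine, dtype=float)
        if not self.data.any():
            raise ValueError("mask is empty: at least one in-mask voxel is required")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def coordinates(self) -> np.ndarray:
        """In-mask voxel coordinates, row-major over the lattice, 0-based."""
        return np.argwhere(self.data)

    def congruent(self, other: "VolumeGrid | Mask", atol: float = AFFINE_ATOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "Mask":
        img = nib.load(str(path))
        return cls(data=np.asanyarray(img.dataobj) > 0, affine=np.asarray(img.affine))


@dataclass
class MaskedMatrix:
    """Subjects x in-mask-voxels matrix tied to its mask."""

    values: np.ndarray
    mask: Mask
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (subjects x voxels)")
        if self.values.shape[1] != self.mask.n_voxels:
            raise ValueError(
                f"column count {self.values.shape[1]} does not match "
                f"mask voxel count {self.mask.n_voxels}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("MaskedMatrix must not contain NaN/inf; fix the mask")
        if self.subject_ids is not None and len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length must equal the number of rows")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def row_volume(self, i: int, fill: float = 0.0) -> VolumeGrid:
        return unmask(self.values[i], self.mask, fill=fill)


def _check_congruent(volumes: Sequence[VolumeGrid], names: Sequence[str] | None = None):
    ref = volumes[0]
    bad = []
    for i, v in enumerate(volumes[1:], start=1):
        if not ref.congruent(v):
            bad.append(names[i] if names else f"volume {i}")
    if bad:
        raise ValueError(
            "grid mismatch: the following volumes do not share the reference "
            f"lattice/affine: {bad}"
        )


def compute_mask(
    volumes: Sequence[VolumeGrid],
    threshold: float = 0.0,
    strategy: str = "finite-and-varying",
    names: Sequence[str] | None = None,
) -> Mask:
    """Build an analysis mask from a set of co-registered volumes.

    Strategies
    ----------
    ``mean-above-threshold``
        Keep voxels whose across-volume mean exceeds ``threshold``.
    ``intersection-nonzero``
        Keep voxels nonzero (and finite) in every volume.
    ``finite-and-varying``
        Keep voxels that are finite in every volume and have nonzero variance
        across volumes (the minimal requirement for the decomposition).
    """
    if len(volumes) == 0:
        raise ValueError("no volumes given")
    _check_congruent(volumes, names)
    stack = np.stack([np.asarray(v.data, dtype=float) for v in volumes])
    finite = np.isfinite(stack).all(axis=0)
    with np.errstate(invalid="ignore"):
        if strategy == "mean-above-threshold":
            keep = finite & (np.where(finite, stack, 0.0).mean(axis=0) > threshold)
        elif strategy == "intersection-nonzero":
            keep = finite & (stack != 0).all(axis=0)
        elif strategy == "finite-and-varying":
            keep = finite & (np.where(finite, stack, 0.0).std(axis=0) > 0)
        else:
            raise ValueError(f"unknown mask strategy: {strategy!r}")
    if not keep.any():
        raise ValueError(f"mask is empty under strategy {strategy!r}")
    return Mask(data=keep, affine=volumes[0].affine)


def stack_volumes(
    volumes: Sequence[VolumeGrid],
    mask: Mask,
    subject_ids: Iterable[str] | None = None,
) -> MaskedMatrix:
    """Stack per-subject volumes into a subjects x in-mask-voxels matrix."""
    for i, v in enumerate(volumes):
        if not mask.congruent(v):
            raise ValueError(f"volume {i} is not congruent with the mask grid")
    sel = mask.data
    values = np.stack([np.asarray(v.data, dtype=float)[sel] for v in volumes])
    ids = list(subject_ids) if subject_ids is not None else None
    return MaskedMatrix(values=values, mask=mask, subject_ids=ids)


def unmask(vector: np.ndarray, mask: Mask, fill: float = 0.0) -> VolumeGrid:
    """Write a per-voxel vector back into a volume; out-of-mask voxels = fill."""
    vector = np.asarray(vector, dtype=float)
    if vector.ndim != 1 or vector.size != mask.n_voxels:
        raise ValueError(
            f"vector length {vector.size} does not match mask voxel count {mask.n_voxels}"
        )
    out = np.full(mask.shape, float(fill))
    out[mask.data] = vector
    return VolumeGrid(data=out, affine=mask.affine)


def smooth_gaussian(volume: VolumeGrid, fwhm_mm) -> VolumeGrid:
    """Separable 3D Gaussian smoothing with FWHM given in mm.

    sigma = FWHM / (2 sqrt(2 ln 2)) per axis, converted to voxel units via the
    grid's voxel size.  Boundaries are handled by reflection (symmetric
    extension), which preserves both constant fields and the total sum; a zero
    FWHM returns the input unchanged.
    """
    fwhm = np.asarray(fwhm_mm, dtype=float)
    if fwhm.ndim == 0:
        fwhm = np.repeat(fwhm, 3)
    if fwhm.shape != (3,):
        raise ValueError("fwhm_mm must be a scalar or a length-3 sequence")
    if np.any(fwhm < 0):
        raise ValueError("FWHM must be non-negative")
    if np.all(fwhm == 0):
        return VolumeGrid(data=np.array(volume.data, dtype=float, copy=True),
                          affine=volume.affine, units=volume.units)
    sigma_vox = fwhm * FWHM_TO_SIGMA / volume.voxel_size
    smoothed = ndimage.gaussian_filter(
        np.asarray(volume.data, dtype=float), sigma=sigma_vox, mode="reflect"
    )
    return VolumeGrid(data=smoothed, affine=volume.affine, units=volume.units)
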