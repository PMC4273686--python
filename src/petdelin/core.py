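"""Shared spatial containers: voxel grids, scalar volumes, binary masks, boxes.

All world coordinates are millimetres in a right-handed frame whose origin
sits at the phantom centre.  Arrays are indexed ``(ix, iy, iz)`` with ``ix``
fastest-varying in NIfTI storage order, so volumes round-trip through
nibabel with a diagonal affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "GridSpec",
    "VoxelVolume",
    "BinaryMask",
    "BoundingBox",
    "standard_grid",
]


@dataclass(frozen=True)
class GridSpec:
    """Image lattice: matrix dimensions (voxels) and voxel size (mm)."""

    matrix: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.matrix) != 3 or len(self.voxel_size) != 3:
            raise ValueError("matrix and voxel_size must be 3-vectors")
        if any(int(n) <= 0 for n in self.matrix):
            raise ValueError(f"matrix dimensions must be positive, got {self.matrix}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        object.__setattr__(self, "matrix", tuple(int(n) for n in self.matrix))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.matrix

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        return float(np.prod(self.voxel_size)) / 1000.0

    def centered_origin(self) -> np.ndarray:
        """World position (mm) of voxel (0,0,0) for a grid centred on the origin."""
        n = np.asarray(self.matrix, dtype=float)
        v = np.asarray(self.voxel_size, dtype=float)
        return -(n - 1.0) / 2.0 * v


def standard_grid(matrix: int = 200, nz: int = 75) -> GridSpec:
    """One of the two reconstruction lattices used throughout.

    ``matrix=200`` gives 4.073 x 4.073 mm pixels, ``matrix=400`` gives
    2.036 x 2.036 mm; slice thickness is 2.027 mm in both cases.  ``nz``
    controls the axial extent (default +/- 76 mm).
    """
    if matrix == 200:
        dx = 4.073
    elif matrix == 400:
        dx = 2.036
    else:
        raise ValueError(f"matrix must be 200 or 400, got {matrix}")
    return GridSpec((matrix, matrix, int(nz)), (dx, dx, 2.027))


def _axes(grid: GridSpec, origin: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    o = np.asarray(origin, dtype=float)
    return tuple(
        o[k] + np.arange(grid.matrix[k]) * grid.voxel_size[k] for k in range(3)
    )


@dataclass
class VoxelVolume:
    """3-D scalar field (activity concentration in kBq/ml, or SUV-like units)."""

    values: np.ndarray
    grid: GridSpec
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.origin is None:
            self.origin = self.grid.centered_origin()
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("voxel values must be non-negative")

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) of voxel centres."""
        return _axes(self.grid, self.origin)

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.values.copy(), self.grid, self.origin.copy())

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.grid.voxel_size) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float32), self.affine())

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VoxelVolume":
        img = nib.load(str(path))
        aff = img.affine
        if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
            raise ValueError("only axis-aligned (diagonal-affine) NIfTI volumes are supported")
        # qform/sform are stored float32; round away the representation noise
        vox = tuple(round(float(d), 6) for d in np.diag(aff[:3, :3]))
        if any(v <= 0 for v in vox):
            raise ValueError("negative voxel sizes (flipped axes) are not supported")
        data = np.asanyarray(img.dataobj).astype(float)
        grid = GridSpec(data.shape, vox)
        return cls(data, grid, aff[:3, 3].copy())


@dataclass
class BinaryMask:
    """Boolean volume on the same lattice conventions as :class:`VoxelVolume`."""

    values: np.ndarray
    grid: GridSpec
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.origin is None:
            self.origin = self.grid.centered_origin()
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return _axes(self.grid, self.origin)

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_ml

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.values.copy(), self.grid, self.origin.copy())

    def same_space(self, other: "BinaryMask | VoxelVolume") -> bool:
        return (
            self.grid == other.grid
            and np.allclose(self.origin, other.origin, atol=1e-6)
        )

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.grid.voxel_size) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.uint8), self.affine()), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "BinaryMask":
        vol = VoxelVolume.load(path)
        return cls(vol.values > 0.5, vol.grid, vol.origin)


@dataclass(frozen=True)
class BoundingBox:
    """Half-open voxel-index box: ``lo`` inclusive, ``hi`` exclusive."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lo", tuple(int(v) for v in self.lo))
        object.__setattr__(self, "hi", tuple(int(v) for v in self.hi))
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"empty bounding box: lo={self.lo}, hi={self.hi}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    @property
    def n_voxels(self) -> int:
        return int(np.prod([h - l for l, h in zip(self.lo, self.hi)]))

    def clipped(self, shape: Sequence[int]) -> "BoundingBox":
        lo = tuple(max(0, l) for l in self.lo)
        hi = tuple(min(int(s), h) for s, h in zip(shape, self.hi))
        return BoundingBox(lo, hi)

    @classmethod
    def from_mask(cls, mask: BinaryMask, margin: int = 3) -> "BoundingBox":
        """Tight box around the mask support, dilated by ``margin`` voxels per axis."""
        if mask.voxel_count == 0:
            raise ValueError("cannot build a bounding box from an empty mask")
        idx = np.argwhere(mask.values)
        lo = idx.min(axis=0) - margin
        hi = idx.max(axis=0) + 1 + margin
        return cls(tuple(lo), tuple(hi)).clipped(mask.values.shape)
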