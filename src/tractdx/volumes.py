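"""Voxel-volume containers on a shared grid.

All volumes (FA maps, lesion masks, atlas label images) must arrive already
co-registered to a common space: combining two volumes requires identical
grids (same dimensions, affines equal within a small tolerance). No
registration or resampling is ever performed here.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "VoxelGrid",
    "FAVolume",
    "BinaryMask",
    "LabelVolume",
    "GridMismatchError",
    "VolumeValidationError",
]

#: absolute tolerance for declaring two affines equal
GRID_ATOL = 1e-4


class GridMismatchError(ValueError):
    """Two volumes live on different voxel grids and cannot be combined."""


class VolumeValidationError(ValueError):
    """A volume's data violates its datatype contract."""


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a voxel volume: dimensions plus voxel->world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise VolumeValidationError(f"grid dims must be three positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise VolumeValidationError("affine must be a 4x4 matrix")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)
        if np.any(self.voxel_size <= 0):
            raise VolumeValidationError("voxel sizes must all be positive")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, from the affine's column norms."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def matches(self, other: "VoxelGrid", atol: float = GRID_ATOL) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    def require_match(self, other: "VoxelGrid", what: str = "volumes") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"cannot combine {what}: grids differ "
                f"(shapes {self.shape} vs {other.shape}); volumes must be co-registered"
            )


class _Volume:
    """Common base: a data array bound to a :class:`VoxelGrid`."""

    def __init__(self, data: np.ndarray, grid: VoxelGrid):
        data = np.asarray(data)
        if tuple(data.shape) != grid.shape:
            raise VolumeValidationError(
                f"data shape {data.shape} does not match grid dims {grid.shape}"
            )
        self.data = data
        self.grid = grid

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def affine(self) -> np.ndarray:
        return self.grid.affine


class FAVolume(_Volume):
    """A fractional-anisotropy map (unitless, FA in [0, 1] on the raw scale).

    A *skeletonized* FA volume is nonzero only on white-matter skeleton
    voxels; zeros elsewhere are background, not measurements.
    """

    def __init__(self, data, grid: VoxelGrid, check_range: bool = True):
        data = np.asarray(data, dtype=float)
        if not np.all(np.isfinite(data)):
            raise VolumeValidationError("FA volume contains non-finite values")
        if check_range and (data.min() < 0.0 or data.max() > 1.0):
            raise VolumeValidationError(
                f"FA values outside [0, 1] (range {data.min():g}..{data.max():g})"
            )
        super().__init__(data, grid)


class BinaryMask(_Volume):
    """A {0,1} voxel mask (lesion, skeleton, or ROI mask)."""

    def __init__(self, data, grid: VoxelGrid, rebinarize_threshold: float | None = None):
        data = np.asarray(data)
        if not np.all(np.isfinite(np.asarray(data, dtype=float))):
            raise VolumeValidationError("mask contains non-finite values")
        values = np.unique(data)
        if not np.all(np.isin(values, (0, 1))):
            if rebinarize_threshold is None:
                raise VolumeValidationError(
                    "mask contains values other than 0/1; pass rebinarize_threshold "
                    "to rebinarize an interpolated mask"
                )
            data = (np.asarray(data, dtype=float) > rebinarize_threshold).astype(np.uint8)
        super().__init__(np.asarray(data, dtype=bool), grid)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


class LabelVolume(_Volume):
    """An integer atlas label image plus a label-group name map.

    ``name_map`` maps an ROI-group name (e.g. a tract) to the set of integer
    atlas labels it comprises; label 0 is background.
    """

    def __init__(self, data, grid: VoxelGrid, name_map: Mapping[str, frozenset[int]] | None = None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.integer):
            as_float = np.asarray(data, dtype=float)
            if not np.all(np.isfinite(as_float)):
                raise VolumeValidationError("label volume contains non-finite values")
            if not np.all(as_float == np.round(as_float)):
                raise VolumeValidationError("label volume contains non-integer values")
            data = as_float.astype(np.int32)
        if data.min() < 0:
            raise VolumeValidationError("labels must be non-negative (0 = background)")
        super().__init__(data, grid)
        self.name_map: dict[str, frozenset[int]] = {}
        if name_map is not None:
            present = set(np.unique(self.data).tolist())
            for name, labels in name_map.items():
                labels = frozenset(int(l) for l in labels)
                if not labels:
                    raise VolumeValidationError(f"label group {name!r} is empty")
                if not labels & present:
                    warnings.warn(
                        f"label group {name!r} has no label present in the volume", stacklevel=2
                    )
                self.name_map[str(name)] = labels

    def group_mask(self, name: str) -> np.ndarray:
        """Boolean voxel mask of one named label group."""
        if name not in self.name_map:
            raise KeyError(f"unknown ROI name {name!r}; known: {sorted(self.name_map)}")
        return np.isin(self.data, sorted(self.name_map[name]))
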