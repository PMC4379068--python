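"""Sampling grids and in-memory volume types.

World coordinates are stereotaxic millimetres with the origin at bregma:
+x is the animal's right, +y anterior, +z dorsal.  Voxel indices are
0-based and refer to voxel centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Tuple

import numpy as np

__all__ = [
    "VolumeGrid",
    "ImageVolume",
    "LabelAtlas",
    "BrainMask",
    "small_grid",
    "large_grid",
]

#: default axis meaning: array axis i -> world axis i
_DEFAULT_ORIENTATION = ("lateral", "anteroposterior", "dorsoventral")


@dataclass(frozen=True)
class VolumeGrid:
    """Regular sampling geometry with an affine voxel->world map.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along each array axis.
    voxel_size : tuple of float
        Voxel edge length in mm along each axis (all > 0).
    origin_world : tuple of float
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    axis_orientation : tuple of str
        Labels mapping array axes to (lateral, anteroposterior,
        dorsoventral).  Only the default order is currently supported.
    """

    dims: Tuple[int, int, int]
    voxel_size: Tuple[float, float, float]
    origin_world: Tuple[float, float, float]
    axis_orientation: Tuple[str, str, str] = _DEFAULT_ORIENTATION

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")
        if tuple(self.axis_orientation) != _DEFAULT_ORIENTATION:
            raise ValueError(
                "axis_orientation must be (lateral, anteroposterior, dorsoventral)"
            )
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(
            self, "origin_world", tuple(float(v) for v in self.origin_world)
        )

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm map (homogeneous)."""
        a = np.eye(4)
        a[0, 0], a[1, 1], a[2, 2] = self.voxel_size
        a[:3, 3] = self.origin_world
        return a

    @property
    def inverse_affine(self) -> np.ndarray:
        a = np.eye(4)
        for i in range(3):
            a[i, i] = 1.0 / self.voxel_size[i]
            a[i, 3] = -self.origin_world[i] / self.voxel_size[i]
        return a

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices (may be fractional) to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk * np.array(self.voxel_size) + np.array(self.origin_world)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) world-mm points to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.array(self.origin_world)) / np.array(self.voxel_size)

    def world_extent(self) -> np.ndarray:
        """(2, 3) array of world coords of the first and last voxel centres."""
        lo = self.voxel_to_world(np.zeros(3))
        hi = self.voxel_to_world(np.array(self.dims, dtype=float) - 1)
        return np.vstack([lo, hi])

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D world coordinate arrays along each axis."""
        return tuple(
            self.origin_world[i] + self.voxel_size[i] * np.arange(self.dims[i])
            for i in range(3)
        )


def small_grid(voxel_size: float = 0.2) -> VolumeGrid:
    """Canonical skull-size grid, 96 x 120 x 96, laterally centred on bregma."""
    return VolumeGrid(
        dims=(96, 120, 96),
        voxel_size=(voxel_size,) * 3,
        origin_world=(-95 * voxel_size / 2.0, -16.1, -13.5),
    )


def large_grid(voxel_size: float = 0.2) -> VolumeGrid:
    """Canonical wide-field grid, 150^3, includes extra-cranial margin."""
    return VolumeGrid(
        dims=(150, 150, 150),
        voxel_size=(voxel_size,) * 3,
        origin_world=(-149 * voxel_size / 2.0, -19.9, -19.9),
    )


@dataclass
class ImageVolume:
    """A scalar 3-D field (SUV or unitless) on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray
    modality_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got ndim={self.values.ndim}")
        if tuple(self.values.shape) != self.grid.dims:
            raise ValueError(
                f"values shape {self.values.shape} != grid dims {self.grid.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.grid, self.values.copy(), self.modality_tag)


@dataclass
class LabelAtlas:
    """Integer region labels (0 = background) plus a name table.

    ``names`` maps each nonzero label to ``(region, hemisphere)`` with
    hemisphere in {"left", "right"}; every region must appear once per
    hemisphere.
    """

    grid: VolumeGrid
    labels: np.ndarray
    names: Mapping[int, Tuple[str, str]]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or tuple(self.labels.shape) != self.grid.dims:
            raise ValueError("label field incongruent with grid dims")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")
        by_region: dict[str, set[str]] = {}
        for _, (region, hemi) in self.names.items():
            if hemi not in ("left", "right"):
                raise ValueError(f"bad hemisphere {hemi!r} for region {region!r}")
            by_region.setdefault(region, set()).add(hemi)
        unpaired = [r for r, h in by_region.items() if h != {"left", "right"}]
        if unpaired:
            raise ValueError(f"regions without both hemispheres: {sorted(unpaired)}")

    @property
    def regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, (region, _) in sorted(self.names.items()):
            seen.setdefault(region, None)
        return list(seen)

    def label_for(self, region: str, hemisphere: str) -> int:
        for lab, (r, h) in self.names.items():
            if r == region and h == hemisphere:
                return lab
        raise KeyError(f"{region} ({hemisphere})")


@dataclass
class BrainMask:
    """Boolean brain-tissue mask on a grid; must be nonempty."""

    grid: VolumeGrid
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3 or tuple(self.mask.shape) != self.grid.dims:
            raise ValueError("mask incongruent with grid dims")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def world_points(self) -> np.ndarray:
        """(N, 3) world coordinates of all mask voxels."""
        ijk = np.argwhere(self.mask)
        return self.grid.voxel_to_world(ijk)
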