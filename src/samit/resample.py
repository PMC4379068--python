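"""World-space resampling: reslicing between grids and left-right mirroring."""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi

from .grid import ImageVolume, VolumeGrid

__all__ = ["reslice_to_grid", "flip_lr", "resample_voxel_map"]

_ORDERS = {"nearest": 0, "trilinear": 1}


def resample_voxel_map(
    values: np.ndarray,
    voxel_map: np.ndarray,
    output_shape: tuple[int, int, int],
    interpolation: str = "trilinear",
    cval: float = 0.0,
) -> np.ndarray:
    """Sample ``values`` at ``voxel_map @ (i,j,k,1)`` for every output voxel.

    ``voxel_map`` is a 4x4 homogeneous map from output voxel indices to
    input voxel indices.  Out-of-field voxels get ``cval``.
    """
    if interpolation not in _ORDERS:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return ndi.affine_transform(
        np.asarray(values, dtype=float),
        voxel_map[:3, :3],
        offset=voxel_map[:3, 3],
        output_shape=output_shape,
        order=_ORDERS[interpolation],
        mode="grid-constant",
        cval=cval,
        prefilter=False,
    )


def _check_overlap(a: VolumeGrid, b: VolumeGrid) -> None:
    ea, eb = a.world_extent(), b.world_extent()
    lo = np.maximum(np.minimum(ea[0], ea[1]), np.minimum(eb[0], eb[1]))
    hi = np.minimum(np.maximum(ea[0], ea[1]), np.maximum(eb[0], eb[1]))
    if np.any(lo > hi):
        raise ValueError("grids have disjoint fields of view")


def reslice_to_grid(
    image: ImageVolume,
    target: VolumeGrid,
    interpolation: str = "trilinear",
) -> ImageVolume:
    """Reslice ``image`` onto ``target`` by sampling through world space."""
    _check_overlap(image.grid, target)
    voxel_map = image.grid.inverse_affine @ target.affine
    out = resample_voxel_map(
        image.values, voxel_map, target.dims, interpolation=interpolation
    )
    if interpolation == "nearest":
        out = out.astype(image.values.dtype)
    return ImageVolume(grid=target, values=out, modality_tag=image.modality_tag)


def flip_lr(image: ImageVolume) -> ImageVolume:
    """Mirror about the x = 0 mm world plane (not the array midplane)."""
    grid = image.grid
    # mirrored x index: i' = c - i with c = -2 * origin_x / voxel_x
    c = -2.0 * grid.origin_world[0] / grid.voxel_size[0]
    if abs(c - round(c)) < 1e-9:
        # voxel centres map onto voxel centres: exact, lossless mirror
        c = int(round(c))
        nx = grid.dims[0]
        out = np.zeros_like(np.asarray(image.values))
        src = c - np.arange(nx)
        valid = (src >= 0) & (src < nx)
        out[valid] = np.asarray(image.values)[src[valid]]
        return ImageVolume(grid=grid, values=out, modality_tag=image.modality_tag)
    flip_world = np.diag([-1.0, 1.0, 1.0, 1.0])
    voxel_map = grid.inverse_affine @ flip_world @ grid.affine
    out = resample_voxel_map(image.values, voxel_map, grid.dims)
    return ImageVolume(grid=grid, values=out, modality_tag=image.modality_tag)
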