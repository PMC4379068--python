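"""NIfTI-1 reading/writing and region-name tables.

The NIfTI affine stores the bregma-centred world map directly (RAS-like:
+x right, +y anterior, +z dorsal).  Only axis-aligned affines are
accepted; oblique acquisitions must be resliced upstream.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping, Tuple

import nibabel as nib
import numpy as np

from .grid import BrainMask, ImageVolume, LabelAtlas, VolumeGrid

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_label_atlas",
    "write_label_atlas",
    "read_name_table",
    "write_name_table",
]


def _grid_from_affine(affine: np.ndarray, shape: Tuple[int, int, int]) -> VolumeGrid:
    A = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(A[:3, :3])) < 1e-12:
        raise ValueError("non-invertible NIfTI affine")
    off = A[:3, :3] - np.diag(np.diag(A[:3, :3]))
    if np.abs(off).max() > 1e-6:
        raise ValueError("oblique/rotated NIfTI affine not supported; reslice first")
    voxel = np.diag(A[:3, :3])
    if np.any(voxel <= 0):
        raise ValueError("negative voxel step in affine; data must be RAS-ordered")
    return VolumeGrid(dims=tuple(shape), voxel_size=tuple(voxel), origin_world=tuple(A[:3, 3]))


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a 3-D NIfTI-1 volume (single-frame 4-D accepted)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"{path}: not a readable NIfTI volume ({exc})") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if data.shape[3] != 1:
            raise ValueError(
                f"{path}: multi-frame 4-D volume ({data.shape[3]} frames) not supported"
            )
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D data, got ndim={data.ndim}")
    grid = _grid_from_affine(img.affine, data.shape)
    return ImageVolume(grid=grid, values=data, modality_tag="")


def write_volume(image: ImageVolume, path: str | os.PathLike) -> None:
    """Write an :class:`ImageVolume` as NIfTI-1; re-reading reproduces it."""
    path = Path(path)
    if not np.all(np.isfinite(image.values)):
        raise ValueError("refusing to write non-finite values")
    affine = image.grid.affine
    nii = nib.Nifti1Image(np.asarray(image.values), affine)
    nii.header.set_xyzt_units("mm")
    nib.save(nii, str(path))


def read_mask(path: str | os.PathLike) -> BrainMask:
    vol = read_volume(path)
    return BrainMask(grid=vol.grid, mask=vol.values > 0.5)


def write_mask(mask: BrainMask, path: str | os.PathLike) -> None:
    write_volume(
        ImageVolume(mask.grid, mask.mask.astype(np.uint8), "mask"), path
    )


def read_name_table(path: str | os.PathLike) -> dict[int, Tuple[str, str]]:
    """Two-column delimited text: ``label<TAB or ,>Region_L`` / ``Region_R``."""
    names: dict[int, Tuple[str, str]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split("\t")
        parts = [p.strip() for p in parts if p.strip()]
        if len(parts) != 2:
            raise ValueError(f"bad name-table line: {raw!r}")
        label = int(parts[0])
        tag = parts[1]
        if tag.endswith("_L"):
            names[label] = (tag[:-2], "left")
        elif tag.endswith("_R"):
            names[label] = (tag[:-2], "right")
        else:
            raise ValueError(f"region tag must end in _L or _R: {tag!r}")
    return names


def write_name_table(names: Mapping[int, Tuple[str, str]], path: str | os.PathLike) -> None:
    lines = []
    for label in sorted(names):
        region, hemi = names[label]
        suffix = "L" if hemi == "left" else "R"
        lines.append(f"{label}\t{region}_{suffix}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_label_atlas(
    volume_path: str | os.PathLike, names_path: str | os.PathLike
) -> LabelAtlas:
    vol = read_volume(volume_path)
    labels = np.rint(vol.values).astype(np.int32)
    return LabelAtlas(grid=vol.grid, labels=labels, names=read_name_table(names_path))


def write_label_atlas(
    atlas: LabelAtlas,
    volume_path: str | os.PathLike,
    names_path: str | os.PathLike,
) -> None:
    write_volume(
        ImageVolume(atlas.grid, atlas.labels.astype(np.int16), "labels"), volume_path
    )
    write_name_table(atlas.names, names_path)
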