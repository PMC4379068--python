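"""VOI-level quantification: whole-brain normalisation, per-region mean
uptake and right-to-left asymmetry ratios."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import BrainMask, ImageVolume, LabelAtlas

__all__ = [
    "VOIReport",
    "whole_brain_normalize",
    "region_stats",
    "cohort_voi_table",
]


def whole_brain_normalize(image: ImageVolume, mask: BrainMask) -> ImageVolume:
    """Divide every voxel by the mean over the brain mask."""
    if image.grid != mask.grid:
        raise ValueError("image and mask must share a grid")
    mean = float(np.asarray(image.values, dtype=float)[mask.mask].mean())
    if mean <= 0:
        raise ValueError(f"whole-brain mean must be > 0, got {mean}")
    return ImageVolume(
        grid=image.grid,
        values=np.asarray(image.values, dtype=float) / mean,
        modality_tag=image.modality_tag,
    )


@dataclass
class VOIReport:
    """Per-region uptake table.

    ``per_region`` columns: suv_left, suv_right, mean_suv (volume-weighted
    bilateral mean), rl_ratio (right / left), n_left, n_right.  Regions with
    no labelled voxels on either side are absent from the table.
    """

    per_region: pd.DataFrame

    def to_csv(self, path) -> None:
        self.per_region.to_csv(path)


def region_stats(image: ImageVolume, atlas: LabelAtlas) -> VOIReport:
    """Mean uptake per bilateral region pair plus right/left ratio."""
    if image.grid != atlas.grid:
        raise ValueError("image and atlas must share a grid; reslice first")
    labels = atlas.labels.ravel()
    values = np.asarray(image.values, dtype=float).ravel()
    if not (labels > 0).any():
        raise ValueError("atlas has no labelled voxels")
    nmax = int(labels.max()) + 1
    sums = np.bincount(labels, weights=values, minlength=nmax)
    counts = np.bincount(labels, minlength=nmax)
    rows = {}
    for region in atlas.regions:
        lab_l = atlas.label_for(region, "left")
        lab_r = atlas.label_for(region, "right")
        n_l = int(counts[lab_l]) if lab_l < nmax else 0
        n_r = int(counts[lab_r]) if lab_r < nmax else 0
        if n_l + n_r == 0:
            continue  # flagged absent
        s_l = sums[lab_l] if lab_l < nmax else 0.0
        s_r = sums[lab_r] if lab_r < nmax else 0.0
        mean_l = s_l / n_l if n_l else np.nan
        mean_r = s_r / n_r if n_r else np.nan
        bilateral = (s_l + s_r) / (n_l + n_r)  # volume-weighted
        ratio = mean_r / mean_l if n_l and n_r and mean_l != 0 else np.nan
        rows[region] = {
            "suv_left": mean_l,
            "suv_right": mean_r,
            "mean_suv": bilateral,
            "rl_ratio": ratio,
            "n_left": n_l,
            "n_right": n_r,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "region"
    return VOIReport(per_region=df)


def cohort_voi_table(
    images: list[ImageVolume], atlas: LabelAtlas
) -> pd.DataFrame:
    """Across-subject mean and SD of regional uptake and R/L ratio.

    Columns: mean_suv, sd_suv, mean_rl, sd_rl, n.  With a single subject the
    SD columns are NaN (flagged undefined).
    """
    if not images:
        raise ValueError("empty cohort")
    reports = [region_stats(img, atlas) for img in images]
    regions = reports[0].per_region.index
    suv = pd.DataFrame(
        [r.per_region["mean_suv"].reindex(regions) for r in reports]
    )
    rl = pd.DataFrame(
        [r.per_region["rl_ratio"].reindex(regions) for r in reports]
    )
    out = pd.DataFrame(
        {
            "mean_suv": suv.mean(axis=0),
            "sd_suv": suv.std(axis=0, ddof=1) if len(images) > 1 else np.nan,
            "mean_rl": rl.mean(axis=0),
            "sd_rl": rl.std(axis=0, ddof=1) if len(images) > 1 else np.nan,
            "n": len(images),
        }
    )
    out.index.name = "region"
    return out
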