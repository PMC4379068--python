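"""Tracer-specific template construction.

Three steps: (1) affine SSD alignment of every cohort image to a
representative image, (2) symmetrisation by registering the left-right
flipped average back onto the average and taking their mean, and (3) rigid
NMI coregistration of the symmetric average onto a reference volume in
stereotaxic space, with the resulting transform propagated to every input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ImageVolume
from .registration import (
    RegistrationConfig,
    RegistrationResult,
    apply_transform,
    register_affine_ssd,
    register_rigid_nmi,
)
from .resample import flip_lr, reslice_to_grid
from .transforms import AffineTransform, compose

__all__ = [
    "Template",
    "TemplateBuildReport",
    "align_cohort",
    "voxelwise_average",
    "symmetrize",
    "coregister_to_reference",
    "build_template",
    "flip_residual",
    "suggest_representative",
]


@dataclass
class Template:
    """Population-average volume plus its construction provenance."""

    volume: ImageVolume
    tracer: str
    strain: str
    n_subjects: int
    subject_transforms: list[AffineTransform]
    symmetric: bool

    def __post_init__(self) -> None:
        if self.n_subjects != len(self.subject_transforms):
            raise ValueError("n_subjects != number of subject transforms")


@dataclass
class TemplateBuildReport:
    subject_costs: list[float]
    subject_converged: list[bool]
    symmetrization_transform: AffineTransform
    coregistration_transform: AffineTransform
    symmetrization_converged: bool = True
    coregistration_converged: bool = True


def flip_residual(volume: ImageVolume, mask: np.ndarray | None = None) -> float:
    """Mean |v - flip(v)| relative to mean |v| over ``mask`` (or everywhere)."""
    flipped = flip_lr(volume)
    diff = np.abs(volume.values - flipped.values)
    ref = np.abs(volume.values)
    if mask is not None:
        diff, ref = diff[mask], ref[mask]
    denom = float(ref.mean())
    if denom == 0:
        return 0.0
    return float(diff.mean()) / denom


def suggest_representative(images: list[ImageVolume]) -> int:
    """Index of the image with median total SSD to all the others."""
    n = len(images)
    if n == 1:
        return 0
    totals = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                d = images[i].values - images[j].values
                totals[i] += float(np.mean(d * d))
    order = np.argsort(totals)
    return int(order[(n - 1) // 2])


def align_cohort(
    images: list[ImageVolume],
    representative_index: int = 0,
    config: RegistrationConfig | None = None,
) -> tuple[list[ImageVolume], list[AffineTransform], list[RegistrationResult | None]]:
    """Register every image (SSD affine) to the representative one and
    resample onto its grid; the representative maps through the identity.
    """
    if not images:
        raise ValueError("empty cohort")
    if not 0 <= representative_index < len(images):
        raise IndexError(
            f"representative_index {representative_index} out of range for {len(images)} images"
        )
    config = config or RegistrationConfig(cost="ssd", dof=12)
    rep = images[representative_index]
    aligned: list[ImageVolume] = []
    transforms: list[AffineTransform] = []
    results: list[RegistrationResult | None] = []
    for i, img in enumerate(images):
        if i == representative_index:
            aligned.append(reslice_to_grid(img, rep.grid))
            transforms.append(AffineTransform.identity())
            results.append(None)
            continue
        res = register_affine_ssd(img, rep, config)
        aligned.append(apply_transform(img, res.transform, rep.grid))
        transforms.append(res.transform)
        results.append(res)
    return aligned, transforms, results


def voxelwise_average(images: list[ImageVolume]) -> ImageVolume:
    """Arithmetic per-voxel mean; all images must share one grid."""
    if not images:
        raise ValueError("empty cohort")
    grid = images[0].grid
    for img in images[1:]:
        if img.grid != grid:
            raise ValueError("grid mismatch in voxelwise_average")
    stack = np.stack([np.asarray(img.values, dtype=float) for img in images])
    return ImageVolume(grid=grid, values=stack.mean(axis=0),
                       modality_tag=images[0].modality_tag)


def symmetrize(
    average: ImageVolume, config: RegistrationConfig | None = None
) -> tuple[ImageVolume, AffineTransform, bool]:
    """Mean of the average and its flip-registered duplicate.

    The left-right flipped copy is affinely registered (SSD) back onto the
    original average, then the two are averaged voxelwise.
    """
    config = config or RegistrationConfig(cost="ssd", dof=12)
    flipped = flip_lr(average)
    res = register_affine_ssd(flipped, average, config)
    registered = apply_transform(flipped, res.transform, average.grid)
    out = ImageVolume(
        grid=average.grid,
        values=0.5 * (np.asarray(average.values, float) + registered.values),
        modality_tag=average.modality_tag,
    )
    return out, res.transform, res.converged


def coregister_to_reference(
    symmetric_avg: ImageVolume,
    reference: ImageVolume,
    config: RegistrationConfig | None = None,
) -> tuple[AffineTransform, bool]:
    """Rigid NMI map from template space into the reference's world space."""
    config = config or RegistrationConfig(cost="nmi", dof=6)
    res = register_rigid_nmi(symmetric_avg, reference, config)
    return res.transform, res.converged


def build_template(
    images: list[ImageVolume],
    representative_index: int = 0,
    reference: ImageVolume | None = None,
    config: RegistrationConfig | None = None,
    nmi_config: RegistrationConfig | None = None,
    tracer: str = "",
    strain: str = "",
) -> tuple[Template, TemplateBuildReport]:
    """Full three-step template construction.

    Each returned subject transform is the composition
    (coregistration after intra-modal alignment): applying it to a raw
    input reproduces that subject's contribution in reference space.
    When ``reference`` is None the coregistration step is skipped and the
    template stays in the representative image's space.
    """
    aligned, intra, results = align_cohort(images, representative_index, config)
    average = voxelwise_average(aligned)
    sym, sym_t, sym_ok = symmetrize(average, config)
    if reference is not None:
        coreg, coreg_ok = coregister_to_reference(sym, reference, nmi_config)
        volume = apply_transform(sym, coreg, reference.grid)
    else:
        coreg, coreg_ok = AffineTransform.identity(), True
        volume = sym
    subject_transforms = [compose(coreg, t) for t in intra]
    template = Template(
        volume=volume,
        tracer=tracer or images[0].modality_tag,
        strain=strain,
        n_subjects=len(images),
        subject_transforms=subject_transforms,
        symmetric=True,
    )
    report = TemplateBuildReport(
        subject_costs=[0.0 if r is None else r.final_cost for r in results],
        subject_converged=[True if r is None else r.converged for r in results],
        symmetrization_transform=sym_t,
        coregistration_transform=coreg,
        symmetrization_converged=sym_ok,
        coregistration_converged=coreg_ok,
    )
    return template, report
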