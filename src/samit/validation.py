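"""Randomised-misalignment registration-error protocol.

Each image undergoes 40 random misalignments (10 translations, 10
rotations, 10 anisotropic scalings, 10 combined), is smoothed with a wide
Gaussian kernel and re-registered to the template with SSD affine
registration.  The error is the mean Euclidean displacement (mm) between
each brain voxel's original position and its position after misalignment
plus recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import BrainMask, ImageVolume
from .registration import (
    RegistrationConfig,
    apply_transform,
    register_affine_ssd,
    smooth_gaussian,
)
from .transforms import AffineTransform, compose

__all__ = [
    "MISALIGNMENT_KINDS",
    "MisalignmentSpec",
    "ErrorRow",
    "ErrorReport",
    "sample_misalignment",
    "mean_displacement_error",
    "evaluate_registration_error",
]

MISALIGNMENT_KINDS = ("translate", "rotate", "scale", "combined")
_KIND_CODES = {k: i for i, k in enumerate(MISALIGNMENT_KINDS)}


@dataclass(frozen=True)
class MisalignmentSpec:
    """Uniform sampling ranges for the four misalignment classes."""

    translation_range: float = 0.5  # +/- mm
    rotation_range: float = 20.0  # +/- deg
    scale_range: float = 0.10  # +/- fraction
    combined_rotation_range: float = 10.0  # +/- deg, used for kind=combined
    n_per_kind: int = 10
    seed: int = 0
    #: optional quantisation steps (mm, deg, fraction) emulating integer draws
    quantize: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("translation_range", "rotation_range", "scale_range",
                     "combined_rotation_range"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_per_kind < 1:
            raise ValueError("n_per_kind must be >= 1")


def _maybe_quantize(x: np.ndarray, step: float | None) -> np.ndarray:
    if step is None or step == 0:
        return x
    return np.round(x / step) * step


def sample_misalignment(
    spec: MisalignmentSpec, kind: str, replicate: int, image_id: int = 0
) -> AffineTransform:
    """Draw one random misalignment, deterministic per
    (seed, image_id, kind, replicate).  Transforms act about bregma.
    """
    if kind not in _KIND_CODES:
        raise ValueError(f"unknown misalignment kind {kind!r}")
    rng = np.random.default_rng(
        [spec.seed, image_id, _KIND_CODES[kind], replicate]
    )
    qt, qr, qs = spec.quantize if spec.quantize is not None else (None, None, None)
    trans = np.zeros(3)
    rot = np.zeros(3)
    scale = np.ones(3)
    if kind in ("translate", "combined"):
        trans = _maybe_quantize(
            rng.uniform(-spec.translation_range, spec.translation_range, 3), qt
        )
    if kind in ("rotate", "combined"):
        r = spec.rotation_range if kind == "rotate" else spec.combined_rotation_range
        rot = _maybe_quantize(rng.uniform(-r, r, 3), qr)
    if kind in ("scale", "combined"):
        scale = 1.0 + _maybe_quantize(
            rng.uniform(-spec.scale_range, spec.scale_range, 3), qs
        )
    return AffineTransform.from_params(
        tx=trans[0], ty=trans[1], tz=trans[2],
        rx=rot[0], ry=rot[1], rz=rot[2],
        sx=scale[0], sy=scale[1], sz=scale[2],
    )


def mean_displacement_error(
    applied: AffineTransform, recovered: AffineTransform, mask: BrainMask
) -> float:
    """Mean over brain voxels of ||recovered(applied(p)) - p|| in mm."""
    points = mask.world_points()
    net = compose(recovered, applied)
    moved = net.apply_points(points)
    return float(np.mean(np.linalg.norm(moved - points, axis=1)))


@dataclass
class ErrorRow:
    image_id: int
    kind: str
    replicate: int
    applied: AffineTransform
    recovered: AffineTransform
    error_mm: float
    converged: bool = True


@dataclass
class ErrorReport:
    rows: list[ErrorRow]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table (image, kind, replicate, error_mm)."""
        return pd.DataFrame(
            {
                "image": [r.image_id for r in self.rows],
                "kind": [r.kind for r in self.rows],
                "replicate": [r.replicate for r in self.rows],
                "error_mm": [r.error_mm for r in self.rows],
            }
        )

    def summary(self) -> pd.DataFrame:
        """Per-kind mean, SD, min, max (mm), recomputed from the rows."""
        df = self.to_dataframe()
        out = df.groupby("kind", sort=False)["error_mm"].agg(
            ["mean", "std", "min", "max"]
        )
        return out.reindex([k for k in MISALIGNMENT_KINDS if k in out.index])

    @property
    def mean_error(self) -> float:
        return float(np.mean([r.error_mm for r in self.rows]))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def evaluate_registration_error(
    images: list[ImageVolume],
    template: ImageVolume,
    mask: BrainMask,
    spec: MisalignmentSpec | None = None,
    reg_config: RegistrationConfig | None = None,
    smoothing_fwhm: float = 8.0,
    kinds: tuple[str, ...] = MISALIGNMENT_KINDS,
    recover: bool = True,
) -> ErrorReport:
    """Full protocol: misalign, smooth, re-register, measure displacement.

    ``images`` are assumed already normalised to the template's space.  Both
    the misaligned image and the template are smoothed identically before
    re-registration.  ``recover=False`` skips re-registration (baseline).
    """
    spec = spec or MisalignmentSpec()
    # default re-registration: full affine with shears regularised to zero,
    # as heavy smoothing otherwise admits shear-compensated mis-poses
    reg_config = reg_config or RegistrationConfig(
        cost="ssd", dof=12, level_factors=(4, 2), shear_penalty=10.0
    )
    template_smooth = smooth_gaussian(template, smoothing_fwhm)
    rows: list[ErrorRow] = []
    for image_id, image in enumerate(images):
        for kind in kinds:
            for replicate in range(spec.n_per_kind):
                t_mis = sample_misalignment(spec, kind, replicate, image_id)
                misaligned = apply_transform(image, t_mis, template.grid)
                smoothed = smooth_gaussian(misaligned, smoothing_fwhm)
                if recover:
                    res = register_affine_ssd(smoothed, template_smooth, reg_config)
                    t_rec, ok = res.transform, res.converged
                else:
                    t_rec, ok = AffineTransform.identity(), True
                err = mean_displacement_error(t_mis, t_rec, mask)
                rows.append(
                    ErrorRow(image_id, kind, replicate, t_mis, t_rec, err, ok)
                )
    return ErrorReport(rows=rows)
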