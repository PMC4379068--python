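"""Digital rat-brain phantoms: stylised region geometry, tracer-uptake
profiles, camera-like blur, noise, inter-subject variability and lesions.

Geometry is deliberately schematic — disjoint ellipsoids at approximate
stereotaxic centroids inside an ellipsoidal brain shell, mirror-symmetric
about the x = 0 mm midplane.  The fidelity target is the statistical
structure of regional uptake, not anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.ndimage as ndi

from .grid import BrainMask, ImageVolume, LabelAtlas, VolumeGrid, small_grid
from .registration import FWHM_TO_SIGMA
from .transforms import AffineTransform

__all__ = [
    "REGIONS",
    "REGION_GEOMETRY",
    "BRAIN_SHELL",
    "UPTAKE_PROFILES",
    "UptakeProfile",
    "PhantomSpec",
    "LesionSpec",
    "make_label_phantom",
    "simulate_subject",
    "simulate_cohort",
]

#: canonical composite-region names, one label pair (left/right) each
REGIONS = (
    "accumbens",
    "amygdala",
    "caudate_putamen",
    "cerebellum",
    "cortex",
    "globus_pallidus",
    "hippocampus",
    "hypothalamus",
    "medulla",
    "midbrain",
    "pons",
    "septum",
    "thalamus",
)

#: per-region ellipsoid (center for the right hemisphere, x > 0) as
#: ((cx, cy, cz), (rx, ry, rz)) in stereotaxic mm; the left twin is the
#: x-mirror.  Chosen to be pairwise disjoint on 0.1 mm sampling.
REGION_GEOMETRY: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "accumbens": ((1.6, 1.8, -7.2), (0.9, 1.0, 0.9)),
    "amygdala": ((4.8, -2.6, -8.0), (1.2, 1.4, 1.2)),
    "caudate_putamen": ((3.3, 0.0, -3.8), (1.5, 2.0, 1.6)),
    "cerebellum": ((2.8, -12.0, -4.2), (2.4, 2.0, 2.2)),
    "cortex": ((4.8, -3.5, -1.2), (1.8, 5.5, 1.4)),
    "globus_pallidus": ((3.1, -1.2, -6.6), (1.0, 1.1, 1.0)),
    "hippocampus": ((2.6, -4.5, -3.2), (1.4, 1.8, 1.1)),
    "hypothalamus": ((1.2, -2.6, -9.0), (0.9, 1.6, 0.8)),
    "medulla": ((1.5, -13.0, -8.0), (1.2, 1.6, 1.4)),
    "midbrain": ((1.5, -7.0, -5.5), (1.2, 1.5, 1.5)),
    "pons": ((1.5, -9.5, -8.5), (1.2, 1.6, 1.2)),
    "septum": ((0.8, 0.6, -5.5), (0.7, 1.4, 1.1)),
    "thalamus": ((1.8, -3.6, -5.8), (1.4, 1.6, 1.3)),
}

#: brain shell ellipsoid (center, radii) in mm; contains every region
BRAIN_SHELL = ((0.0, -5.5, -4.4), (8.8, 12.3, 7.8))

#: per-tracer regional uptake: region -> (mean SUV, between-subject SD)
UPTAKE_PROFILES: dict[str, dict[str, tuple[float, float]]] = {
    "fdg": {
        "accumbens": (1.06, 0.05), "amygdala": (0.78, 0.04),
        "caudate_putamen": (1.28, 0.06), "cerebellum": (0.94, 0.07),
        "cortex": (1.09, 0.04), "globus_pallidus": (1.10, 0.08),
        "hippocampus": (1.05, 0.03), "hypothalamus": (0.77, 0.06),
        "medulla": (0.90, 0.07), "midbrain": (1.08, 0.03),
        "pons": (0.85, 0.10), "septum": (1.05, 0.04), "thalamus": (1.17, 0.06),
    },
    "flumazenil": {
        "accumbens": (0.63, 0.15), "amygdala": (0.66, 0.13),
        "caudate_putamen": (0.71, 0.14), "cerebellum": (0.50, 0.11),
        "cortex": (0.87, 0.16), "globus_pallidus": (0.63, 0.14),
        "hippocampus": (0.86, 0.16), "hypothalamus": (0.55, 0.12),
        "medulla": (0.29, 0.08), "midbrain": (0.72, 0.17),
        "pons": (0.34, 0.09), "septum": (0.68, 0.14), "thalamus": (0.62, 0.16),
    },
    "medas": {
        "accumbens": (1.00, 0.04), "amygdala": (0.82, 0.05),
        "caudate_putamen": (1.20, 0.03), "cerebellum": (0.85, 0.05),
        "cortex": (0.87, 0.02), "globus_pallidus": (1.28, 0.05),
        "hippocampus": (0.96, 0.01), "hypothalamus": (1.06, 0.06),
        "medulla": (1.20, 0.04), "midbrain": (1.31, 0.05),
        "pons": (1.40, 0.05), "septum": (1.07, 0.05), "thalamus": (1.21, 0.04),
    },
    "pk11195": {
        "accumbens": (0.38, 0.07), "amygdala": (0.40, 0.07),
        "caudate_putamen": (0.33, 0.06), "cerebellum": (0.58, 0.14),
        "cortex": (0.51, 0.09), "globus_pallidus": (0.32, 0.07),
        "hippocampus": (0.36, 0.06), "hypothalamus": (0.39, 0.07),
        "medulla": (0.51, 0.09), "midbrain": (0.38, 0.08),
        "pons": (0.42, 0.08), "septum": (0.38, 0.07), "thalamus": (0.36, 0.07),
    },
    "raclopride": {
        "accumbens": (1.50, 0.53), "amygdala": (0.94, 0.35),
        "caudate_putamen": (2.37, 0.83), "cerebellum": (0.69, 0.20),
        "cortex": (1.02, 0.32), "globus_pallidus": (2.10, 0.84),
        "hippocampus": (0.86, 0.26), "hypothalamus": (0.86, 0.29),
        "medulla": (0.80, 0.26), "midbrain": (0.92, 0.28),
        "pons": (0.82, 0.26), "septum": (1.26, 0.46), "thalamus": (1.10, 0.37),
    },
    "hmpao": {
        "accumbens": (0.96, 0.08), "amygdala": (0.86, 0.07),
        "caudate_putamen": (0.94, 0.05), "cerebellum": (1.05, 0.07),
        "cortex": (1.04, 0.03), "globus_pallidus": (0.87, 0.09),
        "hippocampus": (1.13, 0.03), "hypothalamus": (1.01, 0.04),
        "medulla": (0.89, 0.07), "midbrain": (1.10, 0.04),
        "pons": (0.91, 0.05), "septum": (1.01, 0.09), "thalamus": (1.07, 0.03),
    },
}


@dataclass(frozen=True)
class UptakeProfile:
    """Regional mean uptake and between-subject SD for one tracer."""

    tracer: str
    regions: Mapping[str, tuple[float, float]]
    background: float | None = None  # shell uptake; default 0.5 * mean of means

    def __post_init__(self) -> None:
        missing = set(REGIONS) - set(self.regions)
        if missing:
            raise ValueError(f"profile missing regions: {sorted(missing)}")
        if any(m <= 0 for m, _ in self.regions.values()):
            raise ValueError("region means must be > 0")

    @classmethod
    def for_tracer(cls, tracer: str) -> "UptakeProfile":
        key = tracer.lower()
        if key not in UPTAKE_PROFILES:
            raise KeyError(f"unknown tracer {tracer!r}; choose from {sorted(UPTAKE_PROFILES)}")
        return cls(tracer=key, regions=UPTAKE_PROFILES[key])

    @property
    def background_uptake(self) -> float:
        if self.background is not None:
            return self.background
        return 0.5 * float(np.mean([m for m, _ in self.regions.values()]))


@dataclass(frozen=True)
class LesionSpec:
    """Focal (sphere at ``center``) or diffuse (named regions) uptake change."""

    multiplier: float
    center: tuple[float, float, float] | None = None
    radius: float = 1.0
    regions: tuple[str, ...] = ()
    bilateral: bool = True  # for region-list lesions: hit both hemispheres

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("lesion multiplier must be > 0")
        if self.center is None and not self.regions:
            raise ValueError("lesion needs a center (focal) or regions (diffuse)")


@dataclass(frozen=True)
class PhantomSpec:
    grid: VolumeGrid = field(default_factory=small_grid)
    profile: UptakeProfile = field(
        default_factory=lambda: UptakeProfile.for_tracer("pk11195")
    )
    psf_fwhm: float = 1.2
    noise_sd: float = 0.05
    subject_variability_sd: float = 0.1
    seed: int = 0
    #: linear background-uptake slopes (per mm) along y and z, centred on the
    #: brain shell: gross anterior-posterior / dorsal-ventral contrast that
    #: survives heavy smoothing and anchors rotational alignment, as the
    #: uptake topography of a real brain does.  Applied to shell background
    #: only, never to labelled regions.  Mirror-symmetric in x by design.
    background_gradient: tuple[float, float] = (0.03, 0.05)

    def __post_init__(self) -> None:
        if self.psf_fwhm < 0 or self.noise_sd < 0 or self.subject_variability_sd < 0:
            raise ValueError("psf_fwhm, noise_sd and subject_variability_sd must be >= 0")


def _ellipsoid_mask(grid: VolumeGrid, center: Sequence[float], radii: Sequence[float]) -> np.ndarray:
    xs, ys, zs = grid.coordinate_arrays()
    dx = (xs[:, None, None] - center[0]) / radii[0]
    dy = (ys[None, :, None] - center[1]) / radii[1]
    dz = (zs[None, None, :] - center[2]) / radii[2]
    return dx * dx + dy * dy + dz * dz <= 1.0


def region_labels() -> dict[int, tuple[str, str]]:
    """Label numbering: region i gets 2i+1 (left) and 2i+2 (right)."""
    names: dict[int, tuple[str, str]] = {}
    for i, region in enumerate(REGIONS):
        names[2 * i + 1] = (region, "left")
        names[2 * i + 2] = (region, "right")
    return names


def _mirror_index(grid: VolumeGrid) -> np.ndarray | None:
    """Index map i -> i' mirroring about x = 0 mm, or None if not aligned."""
    c = -2.0 * grid.origin_world[0] / grid.voxel_size[0]
    if abs(c - round(c)) > 1e-9:
        return None
    src = int(round(c)) - np.arange(grid.dims[0])
    if src.min() < 0 or src.max() >= grid.dims[0]:
        return None
    return src


def make_label_phantom(spec: PhantomSpec) -> tuple[LabelAtlas, BrainMask]:
    """Deterministic 26-label atlas (13 regions x 2 hemispheres) + brain mask.

    On grids whose voxel centres are mirror-aligned about x = 0 the left
    hemisphere is the exact index-mirror of the right, so boundary voxels
    cannot differ between sides through floating-point round-off.
    """
    grid = spec.grid
    mirror = _mirror_index(grid)
    labels = np.zeros(grid.dims, dtype=np.int16)
    claimed = np.zeros(grid.dims, dtype=bool)
    shell = _ellipsoid_mask(grid, *BRAIN_SHELL)
    if mirror is not None:
        shell |= shell[mirror]
    for i, region in enumerate(REGIONS):
        (cx, cy, cz), radii = REGION_GEOMETRY[region]
        m_right = _ellipsoid_mask(grid, (cx, cy, cz), radii)
        if mirror is not None:
            m_left = m_right[mirror]
        else:
            m_left = _ellipsoid_mask(grid, (-cx, cy, cz), radii)
        for hemi, label, m in (
            ("left", 2 * i + 1, m_left),
            ("right", 2 * i + 2, m_right),
        ):
            if (m & claimed).any():
                raise ValueError(f"region {region} ({hemi}) overlaps another region")
            if (m & ~shell).any():
                raise ValueError(f"region {region} ({hemi}) pokes out of the brain shell")
            labels[m] = label
            claimed |= m
    atlas = LabelAtlas(grid=grid, labels=labels, names=region_labels())
    return atlas, BrainMask(grid=grid, mask=shell)


def _lesion_multiplier_map(
    spec: PhantomSpec, atlas: LabelAtlas, lesion: LesionSpec
) -> np.ndarray:
    mult = np.ones(spec.grid.dims)
    if lesion.center is not None:
        sphere = _ellipsoid_mask(spec.grid, lesion.center, (lesion.radius,) * 3)
        mult[sphere] = lesion.multiplier
    for region in lesion.regions:
        hemis = ("left", "right") if lesion.bilateral else ("right",)
        for hemi in hemis:
            lab = atlas.label_for(region, hemi)
            mult[atlas.labels == lab] = lesion.multiplier
    return mult


def simulate_subject(
    spec: PhantomSpec,
    lesion: LesionSpec | None = None,
    subject_seed: int = 0,
) -> ImageVolume:
    """One tracer-uptake volume: piecewise-constant regional uptake with
    region-level multiplicative variability, optional lesion, Gaussian PSF
    blur and additive voxel noise.  Deterministic per (spec.seed, subject_seed).
    """
    rng = np.random.default_rng([spec.seed, subject_seed])
    atlas, mask = make_label_phantom(spec)
    values = np.zeros(spec.grid.dims)
    gy, gz = spec.background_gradient
    if gy or gz:
        _, ys, zs = spec.grid.coordinate_arrays()
        cy, cz = BRAIN_SHELL[0][1], BRAIN_SHELL[0][2]
        mod = (
            1.0
            + gy * (ys[None, :, None] - cy)
            + gz * (zs[None, None, :] - cz)
        )
        mod = np.clip(mod, 0.05, None)
        background = spec.profile.background_uptake * np.broadcast_to(
            mod, spec.grid.dims
        )
        values[mask.mask] = background[mask.mask]
    else:
        values[mask.mask] = spec.profile.background_uptake
    sv = spec.subject_variability_sd
    for i, region in enumerate(REGIONS):
        mean, _ = spec.profile.regions[region]
        # one multiplicative factor per region (bilateral), unit mean
        factor = float(np.exp(rng.normal(-0.5 * sv * sv, sv))) if sv > 0 else 1.0
        for label in (2 * i + 1, 2 * i + 2):
            values[atlas.labels == label] = mean * factor
    if lesion is not None:
        values *= _lesion_multiplier_map(spec, atlas, lesion)
    if spec.psf_fwhm > 0:
        sigma_vox = [spec.psf_fwhm * FWHM_TO_SIGMA / v for v in spec.grid.voxel_size]
        values = ndi.gaussian_filter(values, sigma_vox, mode="constant")
    if spec.noise_sd > 0:
        level = spec.noise_sd * float(values[mask.mask].mean())
        values = values + rng.normal(0.0, level, size=values.shape)
    return ImageVolume(grid=spec.grid, values=values, modality_tag=spec.profile.tracer)


@dataclass
class Cohort:
    volumes: list[ImageVolume]
    misalignments: list[AffineTransform]
    atlas: LabelAtlas
    mask: BrainMask


def simulate_cohort(
    spec: PhantomSpec,
    n: int,
    lesion: LesionSpec | None = None,
    cohort_seed: int = 0,
    misalignment: "object | None" = None,
) -> Cohort:
    """Simulate ``n`` independent subjects; optionally apply a random
    misalignment to each (emulating un-normalised raw data).

    ``misalignment`` is a :class:`samit.validation.MisalignmentSpec`; the
    'combined' kind is drawn per subject.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from .registration import apply_transform
    from .validation import sample_misalignment

    atlas, mask = make_label_phantom(spec)
    volumes: list[ImageVolume] = []
    transforms: list[AffineTransform] = []
    for i in range(n):
        vol = simulate_subject(spec, lesion=lesion, subject_seed=cohort_seed * 100003 + i)
        t = AffineTransform.identity()
        if misalignment is not None:
            t = sample_misalignment(misalignment, "combined", replicate=i, image_id=cohort_seed * 100003 + i)
            vol = apply_transform(vol, t, vol.grid)
        volumes.append(vol)
        transforms.append(t)
    return Cohort(volumes=volumes, misalignments=transforms, atlas=atlas, mask=mask)
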