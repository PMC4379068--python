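import numpy as np
import pytest

from samit.grid import ImageVolume, VolumeGrid
from samit.phantom import PhantomSpec, UptakeProfile, simulate_subject


def wide_grid(n: int = 75, voxel: float = 0.4) -> VolumeGrid:
    """Wide-FOV grid (default 30 mm cube) so +/-20 deg rotations of the
    brain shell never clip at the field-of-view edge."""
    return VolumeGrid(
        dims=(n, n, n),
        voxel_size=(voxel,) * 3,
        origin_world=(-(n - 1) * voxel / 2.0, -19.9, -19.9),
    )


@pytest.fixture(scope="session")
def wide_fov_grid() -> VolumeGrid:
    return wide_grid()


@pytest.fixture(scope="session")
def clean_phantom(wide_fov_grid) -> ImageVolume:
    """Noise-free, PSF-blurred phantom on the wide grid (shared, read-only)."""
    spec = PhantomSpec(
        grid=wide_fov_grid, psf_fwhm=1.2, noise_sd=0.0,
        subject_variability_sd=0.0, seed=0,
    )
    return simulate_subject(spec)


@pytest.fixture(scope="session")
def clean_phantom_spec(wide_fov_grid) -> PhantomSpec:
    return PhantomSpec(
        grid=wide_fov_grid, psf_fwhm=1.2, noise_sd=0.0,
        subject_variability_sd=0.0, seed=0,
    )


def trilinear_oracle(values: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Reference per-point trilinear interpolation (zero outside).

    ``points``: (N, 3) fractional voxel coordinates.  Written as an explicit
    8-corner loop, independent of scipy.ndimage.
    """
    values = np.asarray(values, dtype=float)
    out = np.zeros(len(points))
    for n, p in enumerate(np.asarray(points, dtype=float)):
        base = np.floor(p).astype(int)
        frac = p - base
        acc = 0.0
        for di in (0, 1):
            for dj in (0, 1):
                for dk in (0, 1):
                    idx = base + (di, dj, dk)
                    if np.any(idx < 0) or np.any(idx >= values.shape):
                        v = 0.0
                    else:
                        v = values[tuple(idx)]
                    w = (
                        (frac[0] if di else 1 - frac[0])
                        * (frac[1] if dj else 1 - frac[1])
                        * (frac[2] if dk else 1 - frac[2])
                    )
                    acc += w * v
        out[n] = acc
    return out
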