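"""Homogeneous world-space affine transforms.

Parameterisation: ``matrix = T @ Rz @ Ry @ Rx @ S @ Sh`` acting about the
world origin (bregma).  Translations are mm, rotations degrees, scales
dimensionless, shears dimensionless (fixed at 0 unless 12-dof).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AffineTransform",
    "params_to_matrix",
    "matrix_to_params",
    "compose",
    "invert",
]

N_PARAMS = 12  # tx ty tz rx ry rz sx sy sz hxy hxz hyz

IDENTITY_PARAMS = np.array(
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
)


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """3x3 rotation, Rz @ Ry @ Rx, angles in degrees."""
    ax, ay, az = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def params_to_matrix(params: np.ndarray) -> np.ndarray:
    """Build the 4x4 matrix T @ R @ S @ Sh from a 12-vector."""
    p = np.asarray(params, dtype=float)
    if p.shape != (N_PARAMS,):
        raise ValueError(f"expected {N_PARAMS} params, got shape {p.shape}")
    tx, ty, tz, rx, ry, rz, sx, sy, sz, hxy, hxz, hyz = p
    R = _rotation_matrix(rx, ry, rz)
    S = np.diag([sx, sy, sz])
    Sh = np.array([[1.0, hxy, hxz], [0.0, 1.0, hyz], [0.0, 0.0, 1.0]])
    m = np.eye(4)
    m[:3, :3] = R @ S @ Sh
    m[:3, 3] = (tx, ty, tz)
    return m


def matrix_to_params(matrix: np.ndarray) -> np.ndarray:
    """Decompose a 4x4 affine into the 12-vector (inverse of params_to_matrix).

    Uses an RQ-style decomposition of the 3x3 block into rotation x scale x
    shear.  Raises for singular or reflecting matrices.
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape != (4, 4):
        raise ValueError("matrix must be 4x4")
    A = m[:3, :3]
    det = np.linalg.det(A)
    if abs(det) < 1e-12:
        raise np.linalg.LinAlgError("singular transform")
    if det < 0:
        raise ValueError("reflecting transform cannot be decomposed as T.R.S.Sh")
    # Gram-Schmidt on columns: A = R * U with U upper triangular, R rotation.
    q, u = np.linalg.qr(A)
    # enforce positive diagonal of u
    d = np.sign(np.diag(u))
    d[d == 0] = 1.0
    q = q * d
    u = (u.T * d).T
    if np.linalg.det(q) < 0:  # defensive; det>0 guaranteed above
        q, u = -q, -u
    scales = np.diag(u).copy()
    shear = np.array(
        [u[0, 1] / scales[0], u[0, 2] / scales[0], u[1, 2] / scales[1]]
    )
    # Euler angles from q = Rz @ Ry @ Rx
    ry = np.arcsin(np.clip(-q[2, 0], -1.0, 1.0))
    if abs(q[2, 0]) < 1.0 - 1e-12:
        rx = np.arctan2(q[2, 1], q[2, 2])
        rz = np.arctan2(q[1, 0], q[0, 0])
    else:  # gimbal lock
        rx = np.arctan2(-q[1, 2], q[1, 1])
        rz = 0.0
    return np.array(
        [
            m[0, 3],
            m[1, 3],
            m[2, 3],
            np.rad2deg(rx),
            np.rad2deg(ry),
            np.rad2deg(rz),
            scales[0],
            scales[1],
            scales[2],
            shear[0],
            shear[1],
            shear[2],
        ]
    )


@dataclass(frozen=True)
class AffineTransform:
    """Invertible 4x4 world-space (mm) transform."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.array(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("matrix must be 4x4")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-9):
            raise ValueError("bottom row must be [0, 0, 0, 1]")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise np.linalg.LinAlgError("singular transform")
        m[3] = [0.0, 0.0, 0.0, 1.0]
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_params(
        cls,
        tx: float = 0.0,
        ty: float = 0.0,
        tz: float = 0.0,
        rx: float = 0.0,
        ry: float = 0.0,
        rz: float = 0.0,
        sx: float = 1.0,
        sy: float = 1.0,
        sz: float = 1.0,
        hxy: float = 0.0,
        hxz: float = 0.0,
        hyz: float = 0.0,
    ) -> "AffineTransform":
        return cls(
            params_to_matrix(
                np.array([tx, ty, tz, rx, ry, rz, sx, sy, sz, hxy, hxz, hyz])
            )
        )

    @classmethod
    def from_param_vector(cls, p: np.ndarray) -> "AffineTransform":
        return cls(params_to_matrix(p))

    @classmethod
    def translation(cls, tx: float, ty: float, tz: float) -> "AffineTransform":
        return cls.from_params(tx=tx, ty=ty, tz=tz)

    # -- introspection -----------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        """Decomposed (tx,ty,tz, rx,ry,rz, sx,sy,sz, hxy,hxz,hyz)."""
        return matrix_to_params(self.matrix)

    @property
    def is_rigid(self) -> bool:
        p = self.params
        return bool(
            np.allclose(p[6:9], 1.0, atol=1e-9) and np.allclose(p[9:12], 0.0, atol=1e-9)
        )

    # -- application -------------------------------------------------------
    def apply_points(self, xyz: np.ndarray) -> np.ndarray:
        """Transform (..., 3) world points."""
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def to_dict(self) -> dict:
        p = self.params
        return {
            "matrix": self.matrix.tolist(),
            "translation_mm": p[:3].tolist(),
            "rotation_deg": p[3:6].tolist(),
            "scale": p[6:9].tolist(),
            "shear": p[9:12].tolist(),
        }


def compose(a: AffineTransform, b: AffineTransform) -> AffineTransform:
    """Transform applying ``b`` first, then ``a`` (matrix product a @ b)."""
    return AffineTransform(a.matrix @ b.matrix)


def invert(a: AffineTransform) -> AffineTransform:
    return AffineTransform(np.linalg.inv(a.matrix))
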