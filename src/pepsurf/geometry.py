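"""Rigid-body geometry helpers: poses, rotation sampling, superposition."""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidPose", "fibonacci_sphere", "kabsch_rmsd", "right_jacobian",
           "rotation_to_axis"]


@dataclasses.dataclass(frozen=True)
class RigidPose:
    """A 6-DOF placement: rotation about an anchor point, then translation.

    ``quat`` is a unit quaternion in (x, y, z, w) order; the pose maps a
    coordinate set ``X`` to ``R (X - anchor) + anchor + translation``.
    When ``anchor`` is None the centroid of the transformed coordinates
    is used, which for a full bead set equals the conformer centroid.
    """

    quat: tuple[float, float, float, float]
    translation: tuple[float, float, float]
    anchor: tuple[float, float, float] | None = None

    def __post_init__(self):
        q = np.asarray(self.quat, dtype=float)
        n = np.linalg.norm(q)
        if not np.isfinite(n) or n == 0:
            raise ValueError("invalid quaternion")
        object.__setattr__(self, "quat", tuple(q / n))
        object.__setattr__(self, "translation",
                           tuple(float(x) for x in self.translation))
        if self.anchor is not None:
            object.__setattr__(self, "anchor",
                               tuple(float(x) for x in self.anchor))

    @classmethod
    def identity(cls, anchor=None) -> "RigidPose":
        return cls((0.0, 0.0, 0.0, 1.0), (0.0, 0.0, 0.0), anchor)

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quat)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        anchor = (np.asarray(self.anchor) if self.anchor is not None
                  else coords.mean(axis=0))
        return (self.rotation.apply(coords - anchor) + anchor
                + np.asarray(self.translation))


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` deterministic near-uniform unit vectors (golden-angle spiral)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def rotation_to_axis(axis: np.ndarray) -> Rotation:
    """Minimum-angle rotation taking +z onto ``axis`` (unit vector)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, axis))
    if c > 1.0 - 1e-12:
        return Rotation.identity()
    if c < -1.0 + 1e-12:
        return Rotation.from_rotvec([np.pi, 0.0, 0.0])
    rv = np.cross(z, axis)
    rv = rv / np.linalg.norm(rv) * np.arccos(np.clip(c, -1.0, 1.0))
    return Rotation.from_rotvec(rv)


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """CA-style RMSD after optimal superposition of ``b`` onto ``a``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shape mismatch {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(ac, bc)
    return float(rssd / np.sqrt(len(a)))


def right_jacobian(w: np.ndarray) -> np.ndarray:
    """Right Jacobian of SO(3) at rotation vector ``w``.

    Satisfies exp([w + dw]) ~= exp([w]) exp([J_r(w) dw]) to first order.
    """
    w = np.asarray(w, dtype=float)
    theta = np.linalg.norm(w)
    W = np.array([[0.0, -w[2], w[1]],
                  [w[2], 0.0, -w[0]],
                  [-w[1], w[0], 0.0]])
    if theta < 1e-6:
        return np.eye(3) - 0.5 * W + W @ W / 6.0
    c1 = (1.0 - np.cos(theta)) / theta**2
    c2 = (theta - np.sin(theta)) / theta**3
    return np.eye(3) - c1 * W + c2 * (W @ W)
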