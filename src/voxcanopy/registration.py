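"""Sphere-target fitting and rigid multi-scan registration.

Scans are registered by matching the centers of reference spheres: each
sphere is fitted by least squares, and the rigid transform between center
sets is the orthogonal Procrustes (Kabsch) solution.  When the
correspondence between centers is unknown it is searched exhaustively over
permutations, keeping the assignment with the smallest post-fit RMS.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = ["RigidTransform", "fit_sphere", "register_scans"]


@dataclass
class RigidTransform:
    """Proper rigid motion x ↦ R x + t."""

    rotation: np.ndarray  # (3, 3), orthonormal, det = +1
    translation: np.ndarray  # (3,)
    rms: float | None = None  # post-fit residual when estimated from data

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-8:
            raise ValueError(f"rotation is not orthonormal (|RᵀR − I| = {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has det = −1 (reflection, not a rigid motion)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def to_dict(self) -> dict:
        return {
            "rotation_row_major": self.rotation.ravel().tolist(),
            "translation": self.translation.tolist(),
            "rms": self.rms,
        }


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least-squares sphere fit: (center, radius, RMS geometric residual).

    Algebraic fit (linear in center and radius) refined by geometric
    Gauss-Newton.  Raises for fewer than 4 points or a coplanar set.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 4:
        raise ValueError("sphere fit needs at least 4 points")
    a = np.column_stack([2.0 * pts, np.ones(len(pts))])
    # coplanarity check via the design-matrix rank
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1e-12):
        raise ValueError("points are coplanar; sphere is not determined")
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(max(sol[3] + center @ center, 0.0)))

    def resid(x):
        return np.linalg.norm(pts - x[:3], axis=1) - x[3]

    out = least_squares(resid, np.append(center, radius), method="lm")
    center, radius = out.x[:3], float(abs(out.x[3]))
    rms = float(np.sqrt(np.mean(resid(out.x) ** 2)))
    return center, radius, rms


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cd - rot @ cs
    tf = RigidTransform(rot, t)
    tf.rms = float(np.sqrt(np.mean(np.sum((tf.apply(src) - dst) ** 2, axis=1))))
    return tf


def register_scans(
    source_centers: np.ndarray,
    target_centers: np.ndarray,
    correspondence: str = "given",
) -> RigidTransform:
    """Rigid transform mapping source sphere centers onto target centers.

    ``correspondence='given'`` assumes row-wise pairing;
    ``correspondence='search'`` tries every permutation of the target set
    (exhaustive; intended for the handful of spheres a field campaign
    deploys) and keeps the assignment with minimum post-fit RMS.
    """
    src = np.asarray(source_centers, dtype=float).reshape(-1, 3)
    dst = np.asarray(target_centers, dtype=float).reshape(-1, 3)
    if len(src) < 3 or len(dst) < 3:
        raise ValueError("registration needs at least 3 sphere centers")
    for name, arr in (("source", src), ("target", dst)):
        c = arr - arr.mean(axis=0)
        sv = np.linalg.svd(c, compute_uv=False)
        if sv[1] < 1e-9 * max(sv[0], 1e-12):
            raise ValueError(f"{name} centers are collinear; rotation is ambiguous")
    if correspondence == "given":
        if len(src) != len(dst):
            raise ValueError("given correspondence requires equal-length center sets")
        return _kabsch(src, dst)
    if correspondence != "search":
        raise ValueError("correspondence must be 'given' or 'search'")
    if len(dst) > 8:
        raise ValueError("correspondence search is exhaustive; at most 8 spheres")
    best: RigidTransform | None = None
    for perm in itertools.permutations(range(len(dst)), len(src)):
        tf = _kabsch(src, dst[list(perm)])
        if best is None or tf.rms < best.rms:
            best = tf
    return best
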