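"""Rigid-body geometry for ribosome neighbor analysis.

Conventions
-----------
Orientations are stored as ZYZ intrinsic Euler angles ``(rot, tilt, psi)``
in degrees, the dialect used by STAR particle tables.  The rotation ``R``
built from these angles maps *particle-frame* vectors into the *lab*
(tomogram) frame::

    R = Rz(rot) @ Ry(tilt) @ Rz(psi)        (intrinsic composition)

Quaternions exposed through the public API are unit quaternions in
scalar-first order ``(w, x, y, z)``; internally everything is a
:class:`scipy.spatial.transform.Rotation`.

The relative transform of neighbor ``j`` seen from particle ``i`` is

    t_rel = R_i^T (x_j - x_i)            (Angstrom, in i's frame)
    R_rel = R_i^{-1} R_j

so the transform of ``(j, i)`` is the group inverse of ``(i, j)``.

The metric used to cluster transforms is a scaled Euclidean/geodesic mix::

    d(T1, T2) = sqrt(|t1 - t2|^2 / sigma_t^2 + ang(q1, q2)^2 / sigma_theta^2)

with ``ang`` the geodesic rotation angle in degrees,
``2 * arccos(|q1 . q2|)`` (the absolute value folds the quaternion double
cover).  With ``symmetrize=True`` the distance is minimised over
``{T2, T2^{-1}}``, which makes the two orderings of a physical pair — and
the two halves of a C2 dimer — equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "euler_to_rotation",
    "rotation_to_euler",
    "rotation_to_quat",
    "quat_to_rotation",
    "euler_to_quat",
    "quat_to_euler",
    "geodesic_angle_deg",
    "RelativeTransform",
    "relative_transform",
    "pair_transforms",
    "invert_transforms",
    "compose_transform",
    "transform_distance",
    "symmetrized_cross_distances",
]

#: numerical tolerance for unit-quaternion validation
UNIT_TOL = 1e-6


def euler_to_rotation(angles_deg: np.ndarray) -> Rotation:
    """Build rotations from ``(rot, tilt, psi)`` ZYZ intrinsic Euler angles.

    Parameters
    ----------
    angles_deg : array-like, shape (3,) or (n, 3)
        Euler angles in degrees.
    """
    return Rotation.from_euler("ZYZ", np.asarray(angles_deg, dtype=float), degrees=True)


def rotation_to_euler(rot: Rotation) -> np.ndarray:
    """Inverse of :func:`euler_to_rotation`; returns degrees, shape (..., 3)."""
    return rot.as_euler("ZYZ", degrees=True)


def rotation_to_quat(rot: Rotation) -> np.ndarray:
    """Rotation -> scalar-first unit quaternion(s) ``(w, x, y, z)``.

    The canonical form (non-negative scalar part) is returned so that equal
    rotations map to bitwise-equal quaternions.
    """
    q = rot.as_quat(canonical=True)  # xyzw
    return np.roll(q, 1, axis=-1)


def quat_to_rotation(q_wxyz: np.ndarray) -> Rotation:
    """Scalar-first quaternion(s) -> Rotation.  Validates unit norm."""
    q = np.asarray(q_wxyz, dtype=float)
    norms = np.linalg.norm(q, axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-5):
        raise ValueError(
            f"non-unit quaternion (|q| deviates from 1 by up to "
            f"{np.abs(norms - 1.0).max():.3g})"
        )
    return Rotation.from_quat(np.roll(q, -1, axis=-1))


def euler_to_quat(angles_deg: np.ndarray) -> np.ndarray:
    """ZYZ Euler angles (degrees) -> scalar-first unit quaternion."""
    return rotation_to_quat(euler_to_rotation(angles_deg))


def quat_to_euler(q_wxyz: np.ndarray) -> np.ndarray:
    """Scalar-first unit quaternion -> ZYZ Euler angles in degrees."""
    return rotation_to_euler(quat_to_rotation(q_wxyz))


def geodesic_angle_deg(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Geodesic rotation angle between unit quaternions, in degrees.

    ``2 * arccos(|<q1, q2>|)``; the absolute value handles the double cover,
    so the result lies in [0, 180].
    """
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    dot = np.abs(np.sum(q1 * q2, axis=-1))
    return np.degrees(2.0 * np.arccos(np.clip(dot, -1.0, 1.0)))


@dataclass(frozen=True)
class RelativeTransform:
    """Rigid transform of a neighbor expressed in a source particle's frame."""

    source_id: int
    target_id: int
    t_rel: np.ndarray  # (3,) Angstrom, target position in source frame
    q_rel: np.ndarray  # (4,) scalar-first unit quaternion, source -> target
    theta: float  # geodesic rotation angle, degrees, in [0, 180]
    center_distance: float  # |t_rel|, Angstrom

    def inverse(self) -> "RelativeTransform":
        """The transform of the source seen from the target (group inverse)."""
        r_inv = quat_to_rotation(self.q_rel).inv()
        return RelativeTransform(
            source_id=self.target_id,
            target_id=self.source_id,
            t_rel=-r_inv.apply(self.t_rel),
            q_rel=rotation_to_quat(r_inv),
            theta=self.theta,
            center_distance=self.center_distance,
        )


def relative_transform(pose_i, pose_j) -> RelativeTransform:
    """Relative transform of pose ``j`` in the frame of pose ``i``.

    Both arguments need ``position`` (3-vector, Angstrom) and ``quaternion``
    (scalar-first, unit within 1e-5) attributes, e.g.
    :class:`ribotopo.field.ParticlePose`.
    """
    r_i = quat_to_rotation(pose_i.quaternion)
    r_j = quat_to_rotation(pose_j.quaternion)
    dx = np.asarray(pose_j.position, dtype=float) - np.asarray(pose_i.position, dtype=float)
    t_rel = r_i.inv().apply(dx)
    r_rel = r_i.inv() * r_j
    q_rel = rotation_to_quat(r_rel)
    identity = np.array([1.0, 0.0, 0.0, 0.0])
    return RelativeTransform(
        source_id=getattr(pose_i, "particle_id", -1),
        target_id=getattr(pose_j, "particle_id", -1),
        t_rel=t_rel,
        q_rel=q_rel,
        theta=float(geodesic_angle_deg(q_rel, identity)),
        center_distance=float(np.linalg.norm(t_rel)),
    )


def pair_transforms(
    positions: np.ndarray, rotations: Rotation, src: np.ndarray, dst: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized relative transforms for ordered index pairs.

    Returns ``(t_rel, q_rel)`` with shapes (m, 3) and (m, 4) (scalar-first).
    """
    src = np.asarray(src, dtype=int)
    dst = np.asarray(dst, dtype=int)
    r_src = rotations[src]
    dx = positions[dst] - positions[src]
    t_rel = r_src.inv().apply(dx)
    q_rel = rotation_to_quat(r_src.inv() * rotations[dst])
    return t_rel, q_rel


def invert_transforms(t: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Group inverses of an array of transforms (vectorized)."""
    r_inv = quat_to_rotation(q).inv()
    single = np.asarray(t).ndim == 1
    t_inv = -r_inv.apply(np.atleast_2d(t))
    q_inv = rotation_to_quat(r_inv)
    if single:
        return t_inv[0], q_inv
    return t_inv, q_inv


def compose_transform(
    t1: np.ndarray, q1: np.ndarray, t2: np.ndarray, q2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Compose two transforms: apply T1, then T2 in the frame T1 produced.

    ``(T1 * T2)(x) = R1 (R2 x + t2) + t1`` — i.e. chaining a neighbor's
    neighbor back into the original particle's frame.
    """
    r1 = quat_to_rotation(q1)
    r2 = quat_to_rotation(q2)
    t = np.asarray(t1, dtype=float) + r1.apply(np.asarray(t2, dtype=float))
    return t, rotation_to_quat(r1 * r2)


def transform_distance(
    t1: np.ndarray,
    q1: np.ndarray,
    t2: np.ndarray,
    q2: np.ndarray,
    sigma_t: float = 25.0,
    sigma_theta: float = 10.0,
    symmetrize: bool = True,
) -> float:
    """Scaled distance between two rigid transforms (see module docstring)."""
    if sigma_t <= 0 or sigma_theta <= 0:
        raise ValueError("metric scales sigma_t and sigma_theta must be > 0")

    def _d(ta, qa, tb, qb):
        dt = np.linalg.norm(np.asarray(ta, dtype=float) - np.asarray(tb, dtype=float))
        ang = float(geodesic_angle_deg(qa, qb))
        return float(np.hypot(dt / sigma_t, ang / sigma_theta))

    d = _d(t1, q1, t2, q2)
    if symmetrize:
        t2i, q2i = invert_transforms(t2, q2)
        d = min(d, _d(t1, q1, t2i, q2i))
    return d


def symmetrized_cross_distances(
    t_block: np.ndarray,
    q_block: np.ndarray,
    t_all: np.ndarray,
    q_all: np.ndarray,
    t_all_inv: np.ndarray,
    q_all_inv: np.ndarray,
    sigma_t: float,
    sigma_theta: float,
) -> np.ndarray:
    """Block of the symmetrized distance matrix, shape (len(block), len(all)).

    The caller precomputes the inverses of the full sample once
    (:func:`invert_transforms`) so each block costs two vectorized metric
    evaluations.  Used by DBSCAN neighborhood construction and medoids.
    """

    def _d2(tb, qb, ta, qa):
        dt2 = np.sum((tb[:, None, :] - ta[None, :, :]) ** 2, axis=-1)
        dot = np.abs(np.einsum("ik,jk->ij", qb, qa))
        ang = np.degrees(2.0 * np.arccos(np.clip(dot, -1.0, 1.0)))
        return dt2 / sigma_t**2 + (ang / sigma_theta) ** 2

    d2 = np.minimum(
        _d2(t_block, q_block, t_all, q_all),
        _d2(t_block, q_block, t_all_inv, q_all_inv),
    )
    return np.sqrt(d2)
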