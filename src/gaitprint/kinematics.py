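"""Segment poses from marker clusters and Z-X-Y cardan joint angles.

Each lower-limb segment (pelvis, thigh, shank, foot) carries a cluster of
>=3 reflective markers.  For every frame, the segment's rotation relative to
its standing-trial orientation is recovered by a least-squares orthogonal
(Procrustes/Kabsch) fit of the current cluster onto the standing cluster.
Joint angles are the Z-X-Y cardan decomposition of the relative rotation
``R_proximal^T @ R_distal``; by construction the standing trial maps to
all-zero angles.

Conventions (package constants; the relevance analysis downstream is
sign-agnostic after standardization):

* lab frame: x = running direction, y = perpendicular (medio-lateral),
  z = vertical up;
* cardan order Z then X then Y, returned as ``(angle_z, angle_x, angle_y)``
  in degrees with ``angle_x`` on the principal branch (-90, 90);
* semantic mapping per joint: Y ~ flexion-extension, X ~ ab-adduction
  (ankle: in-eversion slot per the channel table), Z ~ axial rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channels import ANGLE_CHANNELS

#: segment chain and the joints between consecutive segments
SEGMENTS = ("pelvis", "thigh", "shank", "foot")
JOINTS = ("hip", "knee", "ankle")
#: joint -> (proximal segment, distal segment)
JOINT_SEGMENTS = {"hip": ("pelvis", "thigh"), "knee": ("thigh", "shank"), "ankle": ("shank", "foot")}

#: joint -> (flex-ext channel, ab-ad channel, axial-rotation channel); the
#: cardan triple (z, x, y) maps to (axial, ab-ad, flex-ext).
JOINT_CHANNELS = {
    "hip": ("hip_flex_ext", "hip_ab_ad", "hip_int_ext_rot"),
    "knee": ("knee_flex_ext", "knee_ab_ad", "knee_int_ext_rot"),
    "ankle": ("ankle_dorsi_plantar", "ankle_ab_ad", "ankle_in_eversion"),
}

_GIMBAL_TOL = 1.0 - 1e-9


class GimbalLockError(ValueError):
    """Z-X-Y decomposition is degenerate: |second rotation| is at 90 deg."""


@dataclass(frozen=True)
class ClusterPose:
    """Rigid pose of a marker cluster relative to its reference (standing) pose.

    Attributes
    ----------
    rotation : (3, 3) ndarray
        Proper orthogonal matrix mapping reference-centered coordinates onto
        current-centered coordinates.
    translation : (3,) ndarray
        Centroid displacement in metres.
    residual : float
        Root-mean-square marker residual of the rigid fit, metres.
    """

    rotation: np.ndarray
    translation: np.ndarray
    residual: float


def _rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def compose_zxy(angle_z: float, angle_x: float, angle_y: float) -> np.ndarray:
    """Rotation matrix ``Rz(angle_z) @ Rx(angle_x) @ Ry(angle_y)`` (degrees)."""
    return _rot_z(angle_z) @ _rot_x(angle_x) @ _rot_y(angle_y)


def cardan_zxy(R: np.ndarray) -> tuple[float, float, float]:
    """Decompose a proper rotation into Z-X-Y cardan angles (degrees).

    Returns ``(angle_z, angle_x, angle_y)`` with
    ``compose_zxy(*angles) == R`` and ``angle_x`` in (-90, 90).

    Raises
    ------
    GimbalLockError
        If ``|R[2, 1]| >= 1 - 1e-9`` (the middle rotation is at +-90 deg and
        the first/third angles are no longer separable).
    ValueError
        If ``R`` is not a proper orthogonal 3x3 matrix.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"expected 3x3 rotation, got shape {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
        raise ValueError("matrix is not a proper orthogonal rotation")
    sx = R[2, 1]
    if abs(sx) >= _GIMBAL_TOL:
        raise GimbalLockError(
            "Z-X-Y decomposition degenerate: |sin(angle_x)| = "
            f"{abs(sx):.12f} (angle_x at +-90 deg)"
        )
    angle_x = np.arcsin(sx)
    angle_z = np.arctan2(-R[0, 1], R[1, 1])
    angle_y = np.arctan2(-R[2, 0], R[2, 2])
    return tuple(np.rad2deg([angle_z, angle_x, angle_y]))


def fit_rigid_rotation(
    reference_cluster: np.ndarray, current_cluster: np.ndarray
) -> ClusterPose:
    """Least-squares rigid rotation + translation from reference to current.

    Solves the orthogonal Procrustes problem over centered marker clouds via
    SVD (Kabsch), with the reflection guard that forces a proper rotation
    (det = +1).

    Parameters
    ----------
    reference_cluster, current_cluster : (k, 3) ndarray
        Marker positions (metres) of the same ``k >= 3`` markers, in
        corresponding row order.

    Raises
    ------
    ValueError
        For fewer than 3 markers, mismatched shapes, or a degenerate
        (collinear) reference cluster.
    """
    ref = np.asarray(reference_cluster, dtype=float)
    cur = np.asarray(current_cluster, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] < 3:
        raise ValueError(f"need a (k>=3, 3) reference cluster, got {ref.shape}")
    if cur.shape != ref.shape:
        raise ValueError(f"cluster shapes differ: {ref.shape} vs {cur.shape}")

    ref_c = ref.mean(axis=0)
    cur_c = cur.mean(axis=0)
    A = ref - ref_c
    B = cur - cur_c

    # collinearity check: a rigid rotation about the marker line is unobservable
    s_ref = np.linalg.svd(A, compute_uv=False)
    if s_ref[1] <= 1e-9 * max(s_ref[0], 1e-300):
        raise ValueError("degenerate (collinear) marker cluster: rotation unobservable")

    U, _, Vt = np.linalg.svd(B.T @ A)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])  # reflection guard
    R = U @ D @ Vt

    fitted = A @ R.T + cur_c
    residual = float(np.sqrt(np.mean(np.sum((fitted - cur) ** 2, axis=1))))
    return ClusterPose(rotation=R, translation=cur_c - ref_c, residual=residual)


def joint_angles(proximal: ClusterPose, distal: ClusterPose) -> tuple[float, float, float]:
    """Z-X-Y cardan angles of the distal segment relative to the proximal one.

    The relative rotation is ``R_prox^T @ R_dist`` (distal orientation
    expressed in the proximal segment's frame), so a frame in which both
    segments sit in their standing pose decomposes to (0, 0, 0).
    """
    R_rel = proximal.rotation.T @ distal.rotation
    return cardan_zxy(R_rel)


def trial_joint_angles(
    marker_blocks: dict[str, np.ndarray],
    standing_blocks: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Joint-angle trajectories for a whole trial.

    Parameters
    ----------
    marker_blocks : dict
        Segment name -> (frames, k, 3) marker trajectories.
    standing_blocks : dict
        Segment name -> (k, 3) standing-trial marker positions.

    Returns
    -------
    dict
        Channel name -> (frames,) angle trajectory in degrees, for the nine
        joint-angle channels of the feature table.
    """
    missing = [s for s in SEGMENTS if s not in marker_blocks or s not in standing_blocks]
    if missing:
        raise ValueError(f"missing marker blocks for segments: {missing}")
    n_frames = next(iter(marker_blocks.values())).shape[0]

    poses: dict[str, list[ClusterPose]] = {}
    for seg in SEGMENTS:
        traj = np.asarray(marker_blocks[seg], dtype=float)
        if traj.shape[0] != n_frames:
            raise ValueError("segments have inconsistent frame counts")
        ref = np.asarray(standing_blocks[seg], dtype=float)
        poses[seg] = [fit_rigid_rotation(ref, traj[t]) for t in range(n_frames)]

    out = {name: np.empty(n_frames) for name in ANGLE_CHANNELS}
    for joint, (prox, dist) in JOINT_SEGMENTS.items():
        ch_flex, ch_abad, ch_rot = JOINT_CHANNELS[joint]
        for t in range(n_frames):
            az, ax, ay = joint_angles(poses[prox][t], poses[dist][t])
            out[ch_flex][t] = ay
            out[ch_abad][t] = ax
            out[ch_rot][t] = az
    return out
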