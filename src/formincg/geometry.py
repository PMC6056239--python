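"""Rigid-body superposition helpers (Kabsch, screw transforms, filament axis)."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def kabsch(P: np.ndarray, Q: np.ndarray):
    """Least-squares rigid transform mapping Q onto P.

    Returns (R, t) with ``R @ q + t ~= p``; R is a proper rotation.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - qc).T @ (P - pc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, pc - R @ qc


def rotation_angle_deg(R: np.ndarray) -> float:
    """Total rotation angle theta = arccos((tr R - 1)/2) of a rotation
    matrix, in degrees; extracted through the quaternion representation,
    which stays well-conditioned near 180 deg where arccos loses digits."""
    return float(np.degrees(Rotation.from_matrix(R).magnitude()))


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Return ``mobile`` rigidly superposed onto ``target``."""
    R, t = kabsch(target, mobile)
    return mobile @ R.T + t


def screw_transform(axis_point, axis_dir, angle_deg: float, rise: float):
    """Rigid screw motion: rotation by ``angle_deg`` about the line through
    ``axis_point`` along ``axis_dir`` plus translation ``rise`` along it.
    Returns (R, t) acting as x -> R x + t."""
    n = np.asarray(axis_dir, float)
    n = n / np.linalg.norm(n)
    p = np.asarray(axis_point, float)
    R = Rotation.from_rotvec(np.deg2rad(angle_deg) * n).as_matrix()
    t = p - R @ p + rise * n
    return R, t


def principal_axis(points: np.ndarray):
    """Centroid and dominant direction (unit vector) of a point cloud."""
    points = np.asarray(points, float)
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    return c, vt[0]
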