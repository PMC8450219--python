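"""Batched SO(3) utilities: exponential/log maps and left Jacobians.

All functions accept arrays of rotation vectors ``(..., 3)`` or rotation
matrices ``(..., 3, 3)`` and are written with series fallbacks so that
values and derivatives stay finite at zero angle.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-8


def hat(v: np.ndarray) -> np.ndarray:
    """Skew-symmetric matrix (batch) of 3-vectors: ``hat(v) @ x = v x x``."""
    v = np.asarray(v, float)
    out = np.zeros(v.shape[:-1] + (3, 3))
    out[..., 0, 1] = -v[..., 2]
    out[..., 0, 2] = v[..., 1]
    out[..., 1, 0] = v[..., 2]
    out[..., 1, 2] = -v[..., 0]
    out[..., 2, 0] = -v[..., 1]
    out[..., 2, 1] = v[..., 0]
    return out


def vee(M: np.ndarray) -> np.ndarray:
    """Inverse of :func:`hat` applied to the skew part of ``M``."""
    M = np.asarray(M, float)
    return 0.5 * np.stack(
        [
            M[..., 2, 1] - M[..., 1, 2],
            M[..., 0, 2] - M[..., 2, 0],
            M[..., 1, 0] - M[..., 0, 1],
        ],
        axis=-1,
    )


def exp_so3(psi: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrix of rotation vector(s) ``psi``."""
    psi = np.asarray(psi, float)
    theta2 = np.sum(psi * psi, axis=-1)
    theta = np.sqrt(theta2)
    small = theta < _EPS
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(small, 1.0 - theta2 / 6.0, np.sin(theta) / np.where(small, 1.0, theta))
        b = np.where(small, 0.5 - theta2 / 24.0, (1.0 - np.cos(theta)) / np.where(small, 1.0, theta2))
    K = hat(psi)
    I = np.broadcast_to(np.eye(3), K.shape)
    return I + a[..., None, None] * K + b[..., None, None] * (K @ K)


def log_so3(R: np.ndarray, max_angle: float = 3.10) -> np.ndarray:
    """Rotation vector of rotation matrix/matrices ``R``.

    Uses the quaternion-based log (scipy), which is accurate for all
    angles, but raises once an angle exceeds ``max_angle``: at pi the
    rotation chart is singular and an element that bent that far is
    outside the validity of the strain measures (the solvers treat the
    exception as a rejected trial step).
    """
    R = np.asarray(R, float)
    c = 0.5 * (np.trace(R, axis1=-2, axis2=-1) - 1.0)  # cos(theta)
    if np.all(c > -0.3):  # fast path: all angles < ~1.88 rad
        v = 2.0 * vee(R)  # = 2 sin(theta) * axis
        s = 0.5 * np.linalg.norm(v, axis=-1)
        theta = np.arctan2(s, np.clip(c, -1.0, 1.0))
        small = s < _EPS
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(small, 0.5 + theta**2 / 12.0, theta / np.where(small, 1.0, 2.0 * s))
        return f[..., None] * v

    from scipy.spatial.transform import Rotation

    batch = R.shape[:-2]
    v = Rotation.from_matrix(R.reshape(-1, 3, 3)).as_rotvec().reshape(*batch, 3)
    if np.any(np.linalg.norm(v, axis=-1) > max_angle):
        raise ValueError("rotation angle too close to pi for the log map")
    return v


def left_jacobian(phi: np.ndarray) -> np.ndarray:
    """Left Jacobian ``J_l`` of SO(3): ``d exp(phi) = hat(J_l dphi) exp(phi)``."""
    phi = np.asarray(phi, float)
    theta2 = np.sum(phi * phi, axis=-1)
    theta = np.sqrt(theta2)
    small = theta < _EPS
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(small, 0.5 - theta2 / 24.0, (1.0 - np.cos(theta)) / np.where(small, 1.0, theta2))
        b = np.where(
            small, 1.0 / 6.0 - theta2 / 120.0, (theta - np.sin(theta)) / np.where(small, 1.0, theta2 * theta)
        )
    K = hat(phi)
    I = np.broadcast_to(np.eye(3), K.shape)
    return I + a[..., None, None] * K + b[..., None, None] * (K @ K)


def left_jacobian_inv(phi: np.ndarray) -> np.ndarray:
    """Inverse left Jacobian of SO(3)."""
    phi = np.asarray(phi, float)
    theta2 = np.sum(phi * phi, axis=-1)
    theta = np.sqrt(theta2)
    small = theta < _EPS
    with np.errstate(invalid="ignore", divide="ignore"):
        half = 0.5 * theta
        cot = np.where(small, 1.0, np.cos(half) / np.where(small, 1.0, np.sin(half)))
        eta = np.where(
            small,
            1.0 / 12.0 + theta2 / 720.0,
            (1.0 - 0.5 * theta * cot) / np.where(small, 1.0, theta2),
        )
    K = hat(phi)
    I = np.broadcast_to(np.eye(3), K.shape)
    return I - 0.5 * K + eta[..., None, None] * (K @ K)
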