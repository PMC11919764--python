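"""Euler-angle conventions for particle poses.

Every orientation in this package is an intrinsic ZYZ Euler triple
``(rot, tilt, psi)`` in degrees, composed as

    R = Rz(psi) @ Ry(tilt) @ Rz(rot)

``R`` maps coordinates expressed in the particle's local frame into
world (tomogram) coordinates: ``v_world = R @ v_local``.  The columns
of ``R`` are therefore the particle's local axes in world coordinates,
and the particle z-axis (the membrane normal for surface-picked
particles) is ``R[:, 2]``.  ``rot`` is the in-plane rotation about the
local z-axis, applied first.

Canonical ranges: ``tilt`` in [0, 180], ``rot`` and ``psi`` in
(-180, 180].
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "euler_to_matrix",
    "matrix_to_euler",
    "normalize_euler",
    "frame_from_normal",
    "random_rotations",
]


def euler_to_matrix(rot, tilt, psi):
    """Rotation matrix (or stack of matrices) for ZYZ Euler degrees.

    Accepts scalars or equal-length arrays; returns (3, 3) or (n, 3, 3).
    """
    rot = np.asarray(rot, dtype=float)
    tilt = np.asarray(tilt, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if not (np.all(np.isfinite(rot)) and np.all(np.isfinite(tilt)) and np.all(np.isfinite(psi))):
        raise ValueError("Euler angles must be finite")
    angles = np.stack(np.broadcast_arrays(psi, tilt, rot), axis=-1)
    scalar = angles.ndim == 1
    mats = Rotation.from_euler("ZYZ", np.atleast_2d(angles), degrees=True).as_matrix()
    return mats[0] if scalar else mats


def matrix_to_euler(matrix):
    """Inverse of :func:`euler_to_matrix`; returns (rot, tilt, psi) degrees.

    For a stack of matrices returns arrays.  Angles come back in the
    canonical ranges; at gimbal lock (tilt = 0 or 180) the split between
    rot and psi is degenerate and scipy's choice (rot = 0) is kept.
    """
    import warnings

    m = np.asarray(matrix, dtype=float)
    scalar = m.ndim == 2
    with warnings.catch_warnings():
        # gimbal lock (tilt = 0/180) is legitimate input; scipy's rot=0 choice is fine
        warnings.filterwarnings("ignore", message="Gimbal lock")
        angles = Rotation.from_matrix(np.atleast_3d(m).reshape(-1, 3, 3)).as_euler(
            "ZYZ", degrees=True
        )
    psi, tilt, rot = angles[:, 0], angles[:, 1], angles[:, 2]
    rot, tilt, psi = _canonicalize(rot, tilt, psi)
    if scalar:
        return float(rot[0]), float(tilt[0]), float(psi[0])
    return rot, tilt, psi


def _canonicalize(rot, tilt, psi):
    # scipy ZYZ returns tilt in [0, 180] already; fold the periodic angles
    rot = np.mod(np.asarray(rot, float) + 180.0, 360.0) - 180.0
    psi = np.mod(np.asarray(psi, float) + 180.0, 360.0) - 180.0
    rot = np.where(rot == -180.0, 180.0, rot)
    psi = np.where(psi == -180.0, 180.0, psi)
    return rot, np.asarray(tilt, float), psi


def normalize_euler(rot, tilt, psi):
    """Map an arbitrary Euler triple to the equivalent canonical one."""
    return matrix_to_euler(euler_to_matrix(rot, tilt, psi))


def frame_from_normal(normal, in_plane_deg=0.0):
    """Euler triple whose local z-axis points along ``normal``.

    ``in_plane_deg`` is the rotation about the local z-axis.  Vectorized
    over leading dimensions of ``normal`` (n, 3).
    """
    n = np.asarray(normal, dtype=float)
    single = n.ndim == 1
    n = np.atleast_2d(n)
    norms = np.linalg.norm(n, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length normal")
    n = n / norms[:, None]
    tilt = np.degrees(np.arccos(np.clip(n[:, 2], -1.0, 1.0)))
    psi = np.degrees(np.arctan2(n[:, 1], n[:, 0]))
    psi[tilt % 180.0 == 0.0] = 0.0
    rot = np.broadcast_to(np.asarray(in_plane_deg, float), tilt.shape).copy()
    rot, tilt, psi = _canonicalize(rot, tilt, psi)
    if single:
        return float(rot[0]), float(tilt[0]), float(psi[0])
    return rot, tilt, psi


def random_rotations(n, rng):
    """n uniform random rotations as canonical Euler triples."""
    q = Rotation.random(n, random_state=rng)
    return matrix_to_euler(q.as_matrix())
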