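"""Elementary rotation utilities with explicit dtype control.

The single-precision solver mode requires every arithmetic step to run in
float32, so these helpers take a ``dtype`` argument instead of delegating to
``scipy.spatial.transform`` (which always computes in double).  Quaternion
conversions, which only occur at I/O boundaries, do use scipy.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation as _R

__all__ = [
    "skew",
    "axis_angle",
    "rot_x",
    "rot_y",
    "rot_z",
    "quat_from_matrix",
    "matrix_from_quat",
]


def skew(r: np.ndarray) -> np.ndarray:
    """Cross-product (hat) matrix of a 3-vector."""
    r = np.asarray(r)
    z = r.dtype.type(0)
    return np.array(
        [[z, -r[2], r[1]], [r[2], z, -r[0]], [-r[1], r[0], z]], dtype=r.dtype
    )


def axis_angle(axis: np.ndarray, angle: float, dtype=np.float64) -> np.ndarray:
    """Rodrigues rotation matrix about a unit ``axis`` by ``angle`` radians."""
    axis = np.asarray(axis, dtype=dtype)
    angle = dtype(angle) if callable(dtype) else np.asarray(angle, dtype=dtype)
    k = skew(axis)
    c = np.cos(angle)
    s = np.sin(angle)
    one = axis.dtype.type(1)
    return np.eye(3, dtype=axis.dtype) + s * k + (one - c) * (k @ k)


def _elemental(angle, i, j, dtype):
    c = np.cos(np.asarray(angle, dtype=dtype))
    s = np.sin(np.asarray(angle, dtype=dtype))
    m = np.eye(3, dtype=dtype)
    m[i, i] = c
    m[j, j] = c
    m[i, j] = -s
    m[j, i] = s
    return m


def rot_x(angle, dtype=np.float64) -> np.ndarray:
    """Elemental rotation about basis column 1."""
    return _elemental(angle, 1, 2, dtype)


def rot_y(angle, dtype=np.float64) -> np.ndarray:
    """Elemental rotation about basis column 2."""
    return _elemental(angle, 2, 0, dtype)


def rot_z(angle, dtype=np.float64) -> np.ndarray:
    """Elemental rotation about basis column 3."""
    return _elemental(angle, 0, 1, dtype)


def quat_from_matrix(m: np.ndarray) -> np.ndarray:
    """Scalar-first unit quaternion (qw, qx, qy, qz) of a rotation matrix."""
    q = _R.from_matrix(np.asarray(m, dtype=float)).as_quat()  # xyzw
    q = np.roll(q, 1)
    if q[0] < 0:  # canonical sign
        q = -q
    return q


def matrix_from_quat(q: np.ndarray) -> np.ndarray:
    """Rotation matrix from a scalar-first quaternion.

    Raises ``ValueError`` if the quaternion norm deviates from 1 by more
    than 1e-6.
    """
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if abs(n - 1.0) > 1e-6:
        raise ValueError(f"non-unit quaternion (norm {n:.8f})")
    return _R.from_quat(np.roll(q / n, -1)).as_matrix()
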