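"""Synthetic movement generation and forward kinematics.

Simulated trials drive the seven joint coordinates along 5th-order Bezier
curves whose six control points are drawn uniformly within the model's joint
limits.  Forward kinematics turns joint angles into world-frame prototype
marker positions and per-segment orientations (the quantities an optical or
inertial measurement system would deliver).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .model import COORDINATES, MARKER_NAMES, ModelDefinition
from .rotations import axis_angle, matrix_from_quat, quat_from_matrix, rot_x, rot_y, rot_z

__all__ = [
    "JointAngles",
    "Trial",
    "MarkerFrame",
    "MarkerTrajectory",
    "OrientationFrame",
    "OrientationTrajectory",
    "bezier_curve",
    "sample_trials",
    "forward_kinematics",
    "markers_from_orientations",
    "joint_world_rotations",
]

SEGMENTS = ("humerus", "forearm", "hand")


@dataclass(frozen=True)
class JointAngles:
    """The seven joint coordinates, degrees."""

    theta_elv: float
    theta_sh_elv: float
    theta_sh_rot: float
    theta_el_flex: float
    theta_pro_sup: float
    theta_dev_c: float
    theta_flex_c: float

    @classmethod
    def from_array(cls, values) -> "JointAngles":
        values = np.asarray(values, dtype=float)
        if values.shape != (7,):
            raise ValueError("expected 7 joint coordinates")
        return cls(*values)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in COORDINATES])

    def out_of_limits(self, model: ModelDefinition, tol: float = 1e-9):
        """Names of coordinates outside the model's limits."""
        bad = []
        for coord in COORDINATES:
            lo, hi = model.joint_limits[coord]
            v = getattr(self, coord)
            if v < lo - tol or v > hi + tol:
                bad.append(coord)
        return bad


@dataclass(frozen=True)
class Trial:
    """One simulated movement: a Bezier trajectory per joint coordinate."""

    times: np.ndarray  # (n,) seconds, uniform grid
    angles: np.ndarray  # (n, 7) degrees, COORDINATES order
    control_points: np.ndarray  # (7, 6) degrees
    seed: int

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def joint_angles(self, i: int) -> JointAngles:
        return JointAngles.from_array(self.angles[i])


@dataclass(frozen=True)
class MarkerFrame:
    """Positions of the 12 prototype markers at one time sample (meters)."""

    positions: np.ndarray  # (12, 3), MARKER_NAMES order
    names: tuple = MARKER_NAMES

    def get(self, name: str) -> np.ndarray:
        return self.positions[self.names.index(name)]

    def difference_triad(self, joint: str) -> np.ndarray:
        """Rows = (axis marker - origin marker) for one joint's basis."""
        base = {"SH": 0, "EL": 4, "WR": 8}[joint]
        origin = self.positions[base]
        return self.positions[base + 1 : base + 4] - origin

    def translated(self, offset) -> "MarkerFrame":
        return MarkerFrame(self.positions + np.asarray(offset, dtype=self.positions.dtype))


@dataclass(frozen=True)
class MarkerTrajectory:
    times: np.ndarray  # (n,)
    positions: np.ndarray  # (n, 12, 3)
    names: tuple = MARKER_NAMES

    def frame(self, i: int) -> MarkerFrame:
        return MarkerFrame(self.positions[i], self.names)

    @property
    def n_samples(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class OrientationFrame:
    """World orientation of the three arm segments, scalar-first quaternions."""

    quaternions: np.ndarray  # (3, 4): humerus, forearm, hand

    def matrices(self) -> np.ndarray:
        return np.stack([matrix_from_quat(q) for q in self.quaternions])


@dataclass(frozen=True)
class OrientationTrajectory:
    times: np.ndarray  # (n,)
    quaternions: np.ndarray  # (n, 3, 4)

    def frame(self, i: int) -> OrientationFrame:
        return OrientationFrame(self.quaternions[i])


# ---------------------------------------------------------------------------
# Bezier trajectories
# ---------------------------------------------------------------------------

_BINOM5 = np.array([comb(5, i) for i in range(6)], dtype=float)


def bezier_curve(control_points, t):
    """5th-order Bezier curve value(s) at parameter t in [0, 1].

    ``control_points`` must have length 6 (P_0..P_5) along its last axis;
    ``t`` may be scalar or an array.
    """
    p = np.asarray(control_points, dtype=float)
    if p.shape != (6,):
        raise ValueError("a 5th-order Bezier curve needs exactly 6 control points")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0) or np.any(t > 1.0):
        raise ValueError("Bezier parameter t must lie in [0, 1]")
    i = np.arange(6.0)
    tt = t[..., None]
    basis = _BINOM5 * tt**i * (1.0 - tt) ** (5.0 - i)
    return (basis @ p)[()]


def sample_trials(
    model: ModelDefinition,
    n_trials: int,
    duration_s: float = 5.0,
    rate_hz: float = 100.0,
    seed: int = 0,
):
    """Draw ``n_trials`` pseudo-random Bezier trials within the joint limits.

    Each coordinate gets six control points drawn uniformly from its valid
    interval; by the convex-hull property the whole trajectory stays within
    limits.  The time grid has ``round(duration_s * rate_hz)`` samples with
    the Bezier parameter spanning [0, 1] inclusive (5 s at 100 Hz -> 500
    samples).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    times = np.arange(n) / rate_hz
    t = np.linspace(0.0, 1.0, n)
    limits = model.limits_array()
    trials = []
    for _ in range(n_trials):
        cps = rng.uniform(limits[:, 0:1], limits[:, 1:2], size=(7, 6))
        angles = np.empty((n, 7))
        for j in range(7):
            angles[:, j] = bezier_curve(cps[j], t)
        trials.append(Trial(times=times, angles=angles, control_points=cps, seed=seed))
    return trials


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------


def _shoulder_rotation_local(theta_elv, theta_sh_elv, theta_sh_rot, dtype=np.float64):
    """Shoulder compound rotation expressed in B_sh_orth coordinates.

    Four consecutive rotations: elevation plane, elevation angle, elevation
    plane (back) and axial rotation.  The elevation-plane/axial axis is basis
    column 2, the elevation axis column 3.
    """
    a = rot_y(theta_elv, dtype)
    return a @ rot_z(theta_sh_elv, dtype) @ a.T @ rot_y(theta_sh_rot, dtype)


def _shoulder_rotation_raw(model: ModelDefinition, theta_elv, theta_sh_elv, theta_sh_rot):
    """World shoulder rotation composed about the *raw* (oblique) axes."""
    u2 = model.shoulder_axes_raw[:, 1]  # shared elevation-plane / axial axis
    u3 = model.shoulder_axes_raw[:, 2]  # elevation axis
    return (
        axis_angle(u2, theta_elv)
        @ axis_angle(u3, theta_sh_elv)
        @ axis_angle(u2, -theta_elv)
        @ axis_angle(u2, theta_sh_rot)
    )


def _elbow_rotation_local(model: ModelDefinition, theta_el_flex, theta_pro_sup, dtype=np.float64):
    """Elbow compound rotation in B_pro_sup coordinates: axis-angle flexion
    about the (non-orthogonal) elbow-flexion axis followed by an elemental
    forearm rotation about basis column 1."""
    r = np.asarray(model.elbow_flex_axis, dtype=dtype)
    return axis_angle(r, theta_el_flex, dtype) @ rot_x(theta_pro_sup, dtype)


def _wrist_rotation_local(model: ModelDefinition, theta_dev_c, theta_flex_c, dtype=np.float64):
    """Wrist compound rotation in B_pdr3 coordinates.

    Deviation and flexion are distributed over the carpal rows: a fraction
    ``wrist_split`` of the deviation and exactly half of the flexion act at
    the proximal row (about the deviation and flexion axes), the remainders
    at the distal row (about the pdr1 axis and basis column 1).
    """
    s = model.wrist_split
    mu = theta_flex_c / 2.0
    e1 = np.zeros(3, dtype=dtype)
    e1[0] = 1.0
    return (
        axis_angle(np.asarray(model.wrist_dev_axis, dtype=dtype), s * theta_dev_c, dtype)
        @ axis_angle(np.asarray(model.wrist_flex_axis, dtype=dtype), mu, dtype)
        @ axis_angle(np.asarray(model.wrist_pdr1_axis, dtype=dtype), (1.0 - s) * theta_dev_c, dtype)
        @ axis_angle(e1, mu, dtype)
    )


def joint_world_rotations(
    model: ModelDefinition, angles: JointAngles, shoulder_axes: str = "orthogonalized"
):
    """World rotations of humerus, forearm and hand for a joint configuration.

    ``shoulder_axes`` selects whether the shoulder rotations are composed
    about the orthogonalized basis columns (the algorithm's idealization) or
    about the raw, slightly oblique model axes (emulating the published
    model, whose axes are only near-orthogonal).
    """
    th = np.deg2rad(angles.as_array())
    b_sh = model.shoulder_basis
    if shoulder_axes == "orthogonalized":
        s_world = b_sh @ _shoulder_rotation_local(th[0], th[1], th[2]) @ b_sh.T
    elif shoulder_axes == "raw":
        s_world = _shoulder_rotation_raw(model, th[0], th[1], th[2])
    else:
        raise ValueError("shoulder_axes must be 'orthogonalized' or 'raw'")
    e_world = model.elbow_basis @ _elbow_rotation_local(model, th[3], th[4]) @ model.elbow_basis.T
    w_world = model.wrist_basis @ _wrist_rotation_local(model, th[5], th[6]) @ model.wrist_basis.T
    hum = s_world
    fore = s_world @ e_world
    hand = fore @ w_world
    return hum, fore, hand


def forward_kinematics(
    model: ModelDefinition,
    angles,
    shoulder_axes: str = "orthogonalized",
    warn_out_of_limits: bool = True,
):
    """Compute prototype-marker positions and segment orientations.

    Each joint's four markers are the basis origin (a fixed world offset)
    plus the tips of the rotated basis columns, so the marker difference
    triads carry the joints' compound rotations.  Returns a
    ``(MarkerFrame, OrientationFrame)`` pair.
    """
    if not isinstance(angles, JointAngles):
        angles = JointAngles.from_array(angles)
    if warn_out_of_limits:
        bad = angles.out_of_limits(model)
        if bad:
            import warnings

            warnings.warn(f"angles outside model limits: {bad}", stacklevel=2)
    hum, fore, hand = joint_world_rotations(model, angles, shoulder_axes)
    positions = np.empty((12, 3))
    triads = {
        "SH": (hum @ model.shoulder_basis, model.segment_offsets["shoulder"]),
        "EL": (fore @ model.elbow_basis, model.segment_offsets["elbow"]),
        "WR": (hand @ model.wrist_basis, model.segment_offsets["wrist"]),
    }
    for j, joint in enumerate(("SH", "EL", "WR")):
        rotated, origin = triads[joint]
        base = 4 * j
        positions[base] = origin
        positions[base + 1 : base + 4] = origin + rotated.T
    quats = np.stack([quat_from_matrix(m) for m in (hum, fore, hand)])
    return MarkerFrame(positions), OrientationFrame(quats)


def markers_from_orientations(model: ModelDefinition, frame: OrientationFrame) -> MarkerFrame:
    """Reconstruct prototype-marker positions from segment orientations.

    This is the recommended path for inertial measurements: rather than
    measuring marker positions, each joint basis is rotated by its segment's
    orientation (sensor-to-segment alignment assumed identity) and the triad
    is placed at the configured origin offset.  Fed with orientations from
    :func:`forward_kinematics` it reproduces that function's marker output.
    """
    hum, fore, hand = frame.matrices()
    positions = np.empty((12, 3))
    triads = {
        "SH": (hum @ model.shoulder_basis, model.segment_offsets["shoulder"]),
        "EL": (fore @ model.elbow_basis, model.segment_offsets["elbow"]),
        "WR": (hand @ model.wrist_basis, model.segment_offsets["wrist"]),
    }
    for j, joint in enumerate(("SH", "EL", "WR")):
        rotated, origin = triads[joint]
        base = 4 * j
        positions[base] = origin
        positions[base + 1 : base + 4] = origin + rotated.T
    return MarkerFrame(positions)
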