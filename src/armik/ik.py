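"""Closed-form / root-finding inverse kinematics for the upper-limb chain.

The solver inverts one frame of prototype-marker data (or segment
orientations) into the seven anatomical joint coordinates:

* shoulder and elbow angles come from closed-form expressions on the joints'
  experimental compound rotation matrices;
* the wrist requires a scalar root find: the per-row flexion angle ``mu`` is
  the root of ``F(theta, sigma) = -theta + eta + sigma * atan2(Re(sqrt(xi -
  c(theta)^2)), c(theta))`` with ``c(theta) = x cos(theta) + y sin(theta) +
  z``, solved with Brent's method on the branch ``sigma = sign(mu - eta)``
  while avoiding the singular regions bounded by the four complex border
  points; the compound deviation angle then follows in closed form.

The chain is solved proximal to distal: the elbow and wrist experimental
matrices are obtained by reverse-rotating the extracted marker triads through
the upstream solutions.

Angles are degrees at every public interface; the math runs in radians, in
float64 (``mode="double"``) or float32 (``mode="single"``/``"single_mod"``).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model import COORDINATES, ModelDefinition
from .motion import (
    JointAngles,
    MarkerFrame,
    MarkerTrajectory,
    OrientationFrame,
    OrientationTrajectory,
    markers_from_orientations,
)
from .rotations import axis_angle, rot_y

__all__ = [
    "IKError",
    "DegenerateMarkerError",
    "WristRootError",
    "JointRotation",
    "WristRootProblem",
    "IKResult",
    "IKSolver",
    "MODES",
    "shoulder_rotation",
    "solve_shoulder",
    "elbow_rotation",
    "solve_elbow",
    "wrist_rotation",
    "wrist_problem",
    "singularity_borders",
    "solve_wrist_flexion",
    "solve_wrist",
    "continuity_filter",
    "solve_frame",
]

MODES = ("double", "single", "single_mod")

#: Per-row wrist flexion limits, degrees (the model defines +/-35 per row).
WRIST_FLEX_LIMITS = (-35.0, 35.0)

_SCAN_STEP_RAD = np.deg2rad(0.1)  # bracket-scan resolution before refinement
_GIMBAL_TOL = 1e-6  # rad distance of theta_sh_elv from 0/180 deg


class IKError(RuntimeError):
    """Base class for solver failures."""


class DegenerateMarkerError(IKError):
    """Marker triad does not form a proper rotation (determinant < 0.5)."""


class WristRootError(IKError):
    """No root of the wrist flexion function was found.

    Carries the problem constants and scan diagnostics in ``diagnostics``.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def _dtype_for(mode: str):
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    return np.float64 if mode == "double" else np.float32


@dataclass(frozen=True)
class JointRotation:
    """Experimental compound rotation of one joint, in that joint's basis."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix)
        tol = 1e-3 if m.dtype == np.float32 else 1e-6
        if np.max(np.abs(m.T @ m - np.eye(3, dtype=m.dtype))) > tol:
            raise DegenerateMarkerError("compound rotation is not orthonormal")


@dataclass
class IKResult:
    """Joint angles for one frame plus per-frame solver diagnostics."""

    angles: JointAngles
    root_count: int = 1
    sigma: int = 0
    gimbal: bool = False  # elevation within 1e-6 rad of 0/180 deg: the
    # elevation-plane and axial angles are reported by convention only
    continuity_applied: bool = False
    out_of_range: list = field(default_factory=list)
    failed: bool = False
    message: str = ""


# ---------------------------------------------------------------------------
# experimental compound rotations from marker triads
# ---------------------------------------------------------------------------


def _triad(markers: MarkerFrame, joint: str, dtype) -> np.ndarray:
    d = np.asarray(markers.difference_triad(joint), dtype=dtype)
    if np.linalg.det(np.asarray(d, dtype=np.float64)) < 0.5:
        raise DegenerateMarkerError(f"{joint} marker triad is degenerate")
    return d


def shoulder_rotation(markers: MarkerFrame, model: ModelDefinition, dtype=np.float64) -> JointRotation:
    """R_shoulder = ([rows of PM1_SH_{X,Y,Z} - PM1_SH_O] . B_sh_orth)^T."""
    b = np.asarray(model.shoulder_basis, dtype=dtype)
    return JointRotation((_triad(markers, "SH", dtype) @ b).T)


def elbow_rotation(
    markers: MarkerFrame,
    model: ModelDefinition,
    r_shoulder: JointRotation,
    dtype=np.float64,
) -> JointRotation:
    """Reverse-rotate the elbow triad through the shoulder's world rotation."""
    b_sh = np.asarray(model.shoulder_basis, dtype=dtype)
    b_el = np.asarray(model.elbow_basis, dtype=dtype)
    s_world = b_sh @ np.asarray(r_shoulder.matrix, dtype=dtype) @ b_sh.T
    return JointRotation((_triad(markers, "EL", dtype) @ s_world @ b_el).T)


def wrist_rotation(
    markers: MarkerFrame,
    model: ModelDefinition,
    r_shoulder: JointRotation,
    r_elbow: JointRotation,
    dtype=np.float64,
) -> JointRotation:
    """Reverse-rotate the wrist triad through shoulder and elbow rotations."""
    b_sh = np.asarray(model.shoulder_basis, dtype=dtype)
    b_el = np.asarray(model.elbow_basis, dtype=dtype)
    b_wr = np.asarray(model.wrist_basis, dtype=dtype)
    s_world = b_sh @ np.asarray(r_shoulder.matrix, dtype=dtype) @ b_sh.T
    e_world = b_el @ np.asarray(r_elbow.matrix, dtype=dtype) @ b_el.T
    return JointRotation((_triad(markers, "WR", dtype) @ s_world @ e_world @ b_wr).T)


# ---------------------------------------------------------------------------
# closed-form shoulder and elbow solutions
# ---------------------------------------------------------------------------


def _clip1(v):
    return np.clip(v, -1.0, 1.0)


def solve_shoulder(r: JointRotation, previous_elv_deg=None):
    """Shoulder angles (degrees) from the compound rotation.

    ``theta_sh_elv = arccos(R[2,2])``; ``theta_elv = atan2(R[3,2], -R[1,2])``;
    ``theta_sh_rot`` from the arcsine of a weighted combination of row 2.
    At the gimbal condition (elevation within 1e-6 rad of 0 or 180 degrees,
    where the elevation-plane and axial axes overlap) ``theta_elv`` is taken
    from the previous frame (or 0) and the axial rotation is solved from the
    residual rotation about basis column 2.
    """
    m = np.asarray(r.matrix)
    sh_elv = np.arccos(_clip1(m[1, 1]))
    if sh_elv < _GIMBAL_TOL or sh_elv > np.pi - _GIMBAL_TOL:
        elv = 0.0 if previous_elv_deg is None else np.deg2rad(float(previous_elv_deg))
        residual = rot_y(-elv, m.dtype) @ m
        if sh_elv < _GIMBAL_TOL:
            delta = np.arctan2(residual[0, 2], residual[0, 0])
        else:
            delta = np.arctan2(-residual[0, 2], -residual[0, 0])
        sh_rot = elv + delta
        return tuple(np.rad2deg([elv, sh_elv, sh_rot]))
    elv = np.arctan2(m[2, 1], -m[0, 1])
    a = np.sin(elv) * np.sin(sh_elv)
    b = np.cos(elv) * np.sin(sh_elv)
    sh_rot = np.arcsin(_clip1((a * m[1, 0] + b * m[1, 2]) / (a * a + b * b)))
    return tuple(np.rad2deg([elv, sh_elv, sh_rot]))


def solve_elbow(r: JointRotation, model: ModelDefinition):
    """Elbow angles (degrees): flexion from the (1,1) element corrected for
    the oblique flexion axis ``[x y z]``, forearm rotation from an arcsine of
    row 1.  At zero flexion the arcsine expression degenerates and the
    forearm rotation is read off the residual elemental rotation instead."""
    m = np.asarray(r.matrix)
    x, y, z = np.asarray(model.elbow_flex_axis, dtype=m.dtype)
    el_flex = np.arccos(_clip1((m[0, 0] - x * x) / (1.0 - x * x)))
    s, c = np.sin(el_flex), np.cos(el_flex)
    a = y * s - x * z * (c - 1.0)
    b = z * s + x * y * (c - 1.0)
    denom = a * a + b * b
    if denom < 1e-12:
        # gimbal: flexion ~ 0, compound reduces to the elemental forearm
        # rotation about basis column 1
        pro_sup = np.arctan2(m[2, 1], m[1, 1])
    else:
        pro_sup = np.arcsin(_clip1((a * m[0, 1] + b * m[0, 2]) / denom))
    return float(np.rad2deg(el_flex)), float(np.rad2deg(pro_sup))


# ---------------------------------------------------------------------------
# wrist root-finding problem
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WristRootProblem:
    """Frame constants of the wrist flexion root equation.

    ``a cos(mu) + b sin(mu) = c(mu)`` with ``c(theta) = x cos(theta) +
    y sin(theta) + z`` encodes the scalar invariant
    ``r_dev^T exp(mu r_flex^) r_pdr1 = r_dev^T R exp(-mu e1^) r_pdr1``,
    which eliminates both deviation rotations from the wrist compound.
    ``eta = atan2(b, a)`` and ``xi = a^2 + b^2``.  ``borders`` holds the four
    complex singularity border points (None when x = y = 0).
    """

    a: float
    b: float
    x: float
    y: float
    z: float
    eta: float
    xi: float
    borders: np.ndarray | None
    degenerate: bool = False

    def c(self, theta):
        theta = np.asarray(theta)
        return self.x * np.cos(theta) + self.y * np.sin(theta) + self.z

    def f(self, theta, sigma):
        """The root function F(theta, sigma); vectorized over theta.

        ``Re(sqrt(xi - c^2))`` is the real part of the square root: zero
        wherever the discriminant is negative (the singular regions).
        """
        c = self.c(theta)
        disc = self.xi - c * c
        s = np.sqrt(np.maximum(disc, 0))
        return -theta + self.eta + sigma * np.arctan2(s, c)


def wrist_problem(r: JointRotation, model: ModelDefinition, dtype=None) -> WristRootProblem:
    """Derive the root-equation constants for one frame.

    With ``d = r_dev``, ``f = r_flex``, ``p = r_pdr1`` (all in B_pdr3
    coordinates) and ``q = R^T d``:

    ``a = d.p - (d.f)(f.p)``, ``b = d.(f x p)``,
    ``x = q.p - (q.e1)(p.e1)``, ``y = -q.(e1 x p)``,
    ``z = (q.e1)(p.e1) - (d.f)(f.p)``.
    """
    m = np.asarray(r.matrix)
    if dtype is None:
        dtype = m.dtype
    m = np.asarray(m, dtype=dtype)
    d = np.asarray(model.wrist_dev_axis, dtype=dtype)
    f = np.asarray(model.wrist_flex_axis, dtype=dtype)
    p = np.asarray(model.wrist_pdr1_axis, dtype=dtype)
    e1 = np.zeros(3, dtype=dtype)
    e1[0] = 1.0
    q = m.T @ d
    df_fp = (d @ f) * (f @ p)
    a = d @ p - df_fp
    b = d @ np.cross(f, p)
    x = q @ p - (q @ e1) * (p @ e1)
    y = -q @ np.cross(e1, p)
    z = (q @ e1) * (p @ e1) - df_fp
    eta = np.arctan2(b, a)
    xi = a * a + b * b
    degenerate = bool(abs(x) < 1e-12 and abs(y) < 1e-12)
    borders = None if degenerate else _borders(float(x), float(y), float(z), float(xi))
    return WristRootProblem(
        a=a, b=b, x=x, y=y, z=z, eta=eta, xi=xi, borders=borders, degenerate=degenerate
    )


def _borders(x: float, y: float, z: float, xi: float) -> np.ndarray:
    """Four complex singularity border points of c(theta)^2 = xi."""
    sq = np.sqrt(xi)
    den = complex(x, -y)
    d1 = np.sqrt(complex(xi - 2.0 * z * sq - x * x - y * y + z * z))
    d2 = np.sqrt(complex(xi + 2.0 * z * sq - x * x - y * y + z * z))
    out = np.empty(4, dtype=complex)
    out[0] = -1j * np.log((sq - z + d1) / den)
    out[1] = -1j * np.log((sq - z - d1) / den)
    out[2] = -1j * np.log(-(sq + z + d2) / den)
    out[3] = -1j * np.log(-(sq + z - d2) / den)
    return out


def singularity_borders(p: WristRootProblem) -> np.ndarray:
    """The four border points ``theta^(1)_{1,2}, theta^(2)_{1,2}``.

    For each pair: two real values bound a singular region (where
    ``c(theta)^2 > xi`` and F sticks to its baseline); a complex-conjugate
    pair means no singular region exists for that sign of c.
    Raises :class:`WristRootError` for the degenerate x = y = 0 case.
    """
    if p.degenerate or p.borders is None:
        raise WristRootError("degenerate wrist problem: c(theta) is constant")
    return p.borders


def _real_interval(borders, k: int, tol: float = 1e-9):
    """Sorted real singular interval for pair k (0 or 1), or None."""
    pair = borders[2 * k : 2 * k + 2]
    if np.all(np.abs(pair.imag) < tol):
        lo, hi = sorted(pair.real)
        if hi - lo > 0:
            return float(lo), float(hi)
    return None


def solve_wrist_flexion(
    problem: WristRootProblem,
    limits_deg=WRIST_FLEX_LIMITS,
    previous_flex_deg=None,
    dtype=np.float64,
    xtol=None,
):
    """Locate per-row flexion roots of F by bracketed Brent iteration.

    Branch sigma = +1 is searched on (eta, max], sigma = -1 on [min, eta),
    excluding the interior of any real singular interval.  Every root found
    on branch sigma satisfies the validity condition sigma = sign(mu - eta)
    by construction.  Returns ``(theta_flex_deg, diagnostics)`` where the
    diagnostics carry all candidate roots; when several candidates exist the
    one nearest ``previous_flex_deg`` is returned if given, else the first --
    callers needing a physical disambiguation (see :func:`solve_wrist`)
    re-rank the candidates by forward-kinematics residual.
    """
    if xtol is None:
        xtol = 1e-12 if dtype == np.float64 else 1e-6
    lo, hi = np.deg2rad(limits_deg[0]), np.deg2rad(limits_deg[1])
    eta = float(problem.eta)

    def scan(step_rad):
        knots = np.arange(lo, hi, step_rad)
        extra = [hi]
        if lo < eta < hi:
            extra.append(eta)
        if problem.borders is not None:
            # real singularity borders are exact edges of the excluded
            # regions; keeping them as scan knots preserves brackets that
            # touch a region
            extra.extend(
                float(t.real)
                for t in problem.borders
                if abs(t.imag) < 1e-9 and lo <= t.real <= hi
            )
        knots = np.unique(np.concatenate([knots, np.asarray(extra)]))
        knots = knots[(knots >= lo) & (knots <= hi)].astype(dtype)

        # exclude the interior of singular regions (xi - c^2 < 0): for
        # c > +sqrt(xi) F sticks to its baseline (no roots strictly inside),
        # and for c < -sqrt(xi) the underlying equation has no solution, so
        # any zero of F there is spurious.  Testing the discriminant sign
        # handles regions that wrap around the angular domain, which
        # interval endpoints cannot.
        c_knots = problem.c(knots)
        disc_tol = 1e-10 if dtype == np.float64 else 1e-4  # keeps border
        # knots whose discriminant rounds to a tiny negative value
        nonsingular = problem.xi - c_knots * c_knots >= -disc_tol * max(problem.xi, 1.0)

        found = []
        for sigma in (1, -1):
            mask = (knots >= eta if sigma > 0 else knots <= eta) & nonsingular
            idx = np.nonzero(mask)[0]
            if idx.size == 0:
                continue
            fv = problem.f(knots, dtype(sigma))

            def f_scalar(th, s=sigma):
                return float(problem.f(dtype(th), dtype(s)))

            # split masked points into contiguous runs; never bracket across
            # an excluded singular interval
            end_tol = 1e-9 if dtype == np.float64 else 1e-4  # |F| at a run
            # endpoint small enough to count as a root (e.g. mu exactly at a
            # flexion limit or at a singularity border, with no bracket)
            runs = np.split(idx, np.nonzero(np.diff(idx) > 1)[0] + 1)
            for run in runs:
                for i, j in zip(run[:-1], run[1:]):
                    f1, f2 = float(fv[i]), float(fv[j])
                    if f1 == 0.0:
                        found.append((float(knots[i]), sigma))
                    elif f1 * f2 < 0.0:
                        mu = brentq(f_scalar, float(knots[i]), float(knots[j]), xtol=xtol)
                        found.append((float(mu), sigma))
                for i in (run[0], run[-1]):
                    if abs(float(fv[i])) < end_tol:
                        found.append((float(knots[i]), sigma))
        return found

    # near-tangent root pairs (a developing singularity) can hide between
    # two coarse knots; refine the scan before declaring failure
    candidates = []
    for step in (_SCAN_STEP_RAD, _SCAN_STEP_RAD / 10.0, _SCAN_STEP_RAD / 100.0):
        candidates = scan(step)
        if candidates:
            break

    if not candidates:
        # at a developing singularity the dip of F can graze zero more
        # shallowly than the working precision resolves: no sign change
        # exists in that arithmetic although the exact root does.  Accept
        # the |F| minimum when it is zero at working precision.
        grate = np.arange(lo, hi, _SCAN_STEP_RAD / 20.0).astype(dtype)
        dip_tol = 1e-7 if dtype == np.float64 else 2e-4  # rad; far above
        # the evaluation noise floor of each precision
        for sigma in (1, -1):
            mask = grate >= eta if sigma > 0 else grate <= eta
            if not mask.any():
                continue
            pts = grate[mask]
            fv = np.abs(problem.f(pts, dtype(sigma)))
            i = int(np.argmin(fv))
            if float(fv[i]) < dip_tol:
                candidates.append((float(pts[i]), sigma))

    # dedupe (grid-point zeros can be found twice)
    unique = []
    for mu, sigma in candidates:
        if not any(abs(mu - m0) < 1e-9 for m0, _ in unique):
            unique.append((mu, sigma))
    if not unique:
        raise WristRootError(
            "no sign change of F found in either branch",
            diagnostics={
                "eta": eta,
                "xi": float(problem.xi),
                "borders": problem.borders,
                "limits_deg": tuple(limits_deg),
            },
        )
    unique.sort(key=lambda c: c[0])
    if previous_flex_deg is not None:
        prev = np.deg2rad(previous_flex_deg)
        mu, sigma = min(unique, key=lambda c: abs(c[0] - prev))
    else:
        mu, sigma = unique[0]
    diagnostics = {
        "candidates": unique,
        "root_count": len(unique),
        "sigma": sigma,
        "eta": eta,
    }
    return float(np.rad2deg(mu)), diagnostics


def _deviation_for(r_matrix, mu_rad, model: ModelDefinition, dtype):
    """Compound deviation angle (radians) for a given per-row flexion root.

    ``v1 = exp(mu r_flex^) r_pdr1`` and ``w1 = R exp(-mu e1^) r_pdr1`` are
    the pdr1 axis seen from the proximal side and from the measured rotation;
    they differ by the proximal-row deviation rotation about ``r_dev``, whose
    angle (a fraction ``wrist_split`` of the compound deviation) follows from
    the standard two-vector/axis atan2 expression.
    """
    d = np.asarray(model.wrist_dev_axis, dtype=dtype)
    f = np.asarray(model.wrist_flex_axis, dtype=dtype)
    p = np.asarray(model.wrist_pdr1_axis, dtype=dtype)
    e1 = np.zeros(3, dtype=dtype)
    e1[0] = 1.0
    mu = dtype(mu_rad)
    v1 = axis_angle(f, mu, dtype) @ p
    w1 = np.asarray(r_matrix, dtype=dtype) @ (axis_angle(e1, -mu, dtype) @ p)
    num = w1 @ np.cross(d, v1)
    den = v1 @ w1 - (v1 @ d) * (w1 @ d)
    return float(np.arctan2(num, den)) / model.wrist_split


def _wrist_reconstruction(model: ModelDefinition, dev_rad, mu_rad, dtype):
    s = model.wrist_split
    d = np.asarray(model.wrist_dev_axis, dtype=dtype)
    f = np.asarray(model.wrist_flex_axis, dtype=dtype)
    p = np.asarray(model.wrist_pdr1_axis, dtype=dtype)
    e1 = np.zeros(3, dtype=dtype)
    e1[0] = 1.0
    return (
        axis_angle(d, s * dev_rad, dtype)
        @ axis_angle(f, mu_rad, dtype)
        @ axis_angle(p, (1.0 - s) * dev_rad, dtype)
        @ axis_angle(e1, mu_rad, dtype)
    )


def solve_wrist(
    r: JointRotation,
    model: ModelDefinition,
    previous_flex_c_deg=None,
    dtype=np.float64,
):
    """Both compound wrist angles (degrees) from the compound rotation.

    The flexion root gives ``theta_flex_c = 2 mu``; the deviation follows in
    closed form.  When the root find yields several valid candidates (a
    developing singularity), the candidate nearest the previous frame's
    flexion is used if available; otherwise each candidate's full wrist
    rotation is rebuilt and the one with the smallest reconstruction residual
    wins -- |F| cannot discriminate between exact roots.
    """
    problem = wrist_problem(r, model, dtype)
    prev_mu = None if previous_flex_c_deg is None else previous_flex_c_deg / 2.0
    mu_deg, diag = solve_wrist_flexion(
        problem, WRIST_FLEX_LIMITS, previous_flex_deg=prev_mu, dtype=dtype
    )
    candidates = diag["candidates"]
    m = np.asarray(r.matrix, dtype=dtype)
    if len(candidates) > 1 and prev_mu is None:
        best = None
        for mu_rad, sigma in candidates:
            dev_rad = _deviation_for(m, mu_rad, model, dtype)
            rec = _wrist_reconstruction(model, dtype(dev_rad), dtype(mu_rad), dtype)
            resid = float(np.max(np.abs(rec - m)))
            if best is None or resid < best[0]:
                best = (resid, mu_rad, sigma, dev_rad)
        _, mu_rad, sigma, dev_rad = best
        diag = dict(diag, sigma=sigma)
        mu_deg = float(np.rad2deg(mu_rad))
    else:
        mu_rad = np.deg2rad(mu_deg)
        dev_rad = _deviation_for(m, mu_rad, model, dtype)
    theta_flex_c = 2.0 * mu_deg
    theta_dev_c = float(np.rad2deg(dev_rad))
    return theta_dev_c, theta_flex_c, diag


def continuity_filter(current_flex_c, previous_flex_c=None, threshold=5.0, step=0.5, signed=False):
    """Wrist-flexion output continuity check.

    If the absolute difference between successive compound flexion values
    exceeds ``threshold`` degrees, the output is the previous value plus
    ``step`` degrees (the literal published rule is unsigned: always +step;
    ``signed=True`` steps toward the raw value instead).  The first frame
    (``previous_flex_c`` is None) passes through unmodified.
    """
    if previous_flex_c is None:
        return current_flex_c
    if abs(current_flex_c - previous_flex_c) > threshold:
        if signed:
            return previous_flex_c + np.sign(current_flex_c - previous_flex_c) * step
        return previous_flex_c + step
    return current_flex_c


# ---------------------------------------------------------------------------
# full-frame solve
# ---------------------------------------------------------------------------


def solve_frame(
    frame,
    model: ModelDefinition,
    mode: str = "double",
    previous: IKResult | None = None,
    saturate: bool = False,
) -> IKResult:
    """Solve one frame of markers or orientations for all seven coordinates.

    The chain order is mandatory: the elbow and wrist experimental matrices
    depend on the upstream solutions.  ``mode`` selects double or single
    precision arithmetic; ``single_mod`` additionally applies the
    wrist-flexion continuity filter against ``previous``.  A per-frame
    failure is returned as a flagged :class:`IKResult`, not raised.
    """
    dtype = _dtype_for(mode)
    if isinstance(frame, OrientationFrame):
        frame = markers_from_orientations(model, frame)
    if not isinstance(frame, MarkerFrame):
        raise TypeError("frame must be a MarkerFrame or OrientationFrame")
    frame = MarkerFrame(np.asarray(frame.positions, dtype=dtype), frame.names)
    prev_elv = None if previous is None or previous.failed else previous.angles.theta_elv
    prev_flex_c = None if previous is None or previous.failed else previous.angles.theta_flex_c
    try:
        r_sh = shoulder_rotation(frame, model, dtype)
        elv, sh_elv, sh_rot = solve_shoulder(r_sh, previous_elv_deg=prev_elv)
        r_el = elbow_rotation(frame, model, r_sh, dtype)
        el_flex, pro_sup = solve_elbow(r_el, model)
        r_wr = wrist_rotation(frame, model, r_sh, r_el, dtype)
        dev_c, flex_c, diag = solve_wrist(r_wr, model, dtype=dtype)
    except IKError as exc:
        nan = float("nan")
        return IKResult(
            angles=JointAngles(nan, nan, nan, nan, nan, nan, nan),
            failed=True,
            message=str(exc),
        )
    continuity_applied = False
    if mode == "single_mod":
        filtered = continuity_filter(flex_c, prev_flex_c)
        continuity_applied = filtered != flex_c
        flex_c = filtered
    angles = JointAngles(
        float(elv), float(sh_elv), float(sh_rot),
        float(el_flex), float(pro_sup), float(dev_c), float(flex_c),
    )
    out = angles.out_of_limits(model, tol=1e-6)
    if saturate and out:
        clipped = np.clip(
            angles.as_array(), model.limits_array()[:, 0], model.limits_array()[:, 1]
        )
        angles = JointAngles.from_array(clipped)
    gimbal = min(sh_elv, 180.0 - sh_elv) < np.rad2deg(_GIMBAL_TOL)
    return IKResult(
        angles=angles,
        root_count=diag.get("root_count", 1),
        sigma=diag.get("sigma", 0),
        gimbal=bool(gimbal),
        continuity_applied=continuity_applied,
        out_of_range=out,
    )


class IKSolver:
    """Stateful streaming solver: one frame in, one :class:`IKResult` out.

    Keeps the previous frame's result for the shoulder gimbal convention and
    the ``single_mod`` continuity filter.
    """

    def __init__(self, model: ModelDefinition, mode: str = "double", saturate: bool = False):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.model = model
        self.mode = mode
        self.saturate = saturate
        self._previous: IKResult | None = None

    def reset(self) -> None:
        self._previous = None

    def step(self, frame) -> IKResult:
        result = solve_frame(
            frame, self.model, mode=self.mode, previous=self._previous, saturate=self.saturate
        )
        self._previous = result
        return result

    def solve_trajectory(self, trajectory, return_results: bool = False, timing: bool = False):
        """Solve a full marker or orientation trajectory.

        Returns an ``(n, 7)`` array of joint angles in degrees (COORDINATES
        order); with ``return_results`` also the per-frame IKResult list, and
        with ``timing`` the mean wall-clock seconds per frame.
        """
        if isinstance(trajectory, MarkerTrajectory):
            frames = (trajectory.frame(i) for i in range(trajectory.n_samples))
            n = trajectory.n_samples
        elif isinstance(trajectory, OrientationTrajectory):
            frames = (trajectory.frame(i) for i in range(len(trajectory.times)))
            n = len(trajectory.times)
        else:
            raise TypeError("expected a MarkerTrajectory or OrientationTrajectory")
        self.reset()
        angles = np.empty((n, 7))
        results = []
        t0 = time.perf_counter()
        for i, frame in enumerate(frames):
            res = self.step(frame)
            angles[i] = res.angles.as_array()
            if return_results:
                results.append(res)
        elapsed = time.perf_counter() - t0
        out = [angles]
        if return_results:
            out.append(results)
        if timing:
            out.append(elapsed / max(n, 1))
        return out[0] if len(out) == 1 else tuple(out)
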