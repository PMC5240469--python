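"""Inverse-kinematics solver: compound-rotation extraction, closed-form
shoulder/elbow solutions, the wrist root find and the full-frame chain."""

import numpy as np
import pytest

from armik import (
    IKSolver,
    JointRotation,
    continuity_filter,
    forward_kinematics,
    singularity_borders,
    solve_elbow,
    solve_frame,
    solve_shoulder,
    solve_wrist,
    solve_wrist_flexion,
    wrist_problem,
)
from armik.ik import (
    DegenerateMarkerError,
    elbow_rotation,
    shoulder_rotation,
    wrist_rotation,
)
from armik.motion import (
    MarkerFrame,
    _elbow_rotation_local,
    _shoulder_rotation_local,
    _wrist_rotation_local,
)
from armik.rotations import axis_angle
from conftest import random_in_range_angles

FIG1 = np.array([0.0, 63.0, 15.0, 95.0, -60.0, 0.0, 20.0])


def chain(markers, model):
    r_sh = shoulder_rotation(markers, model)
    r_el = elbow_rotation(markers, model, r_sh)
    r_wr = wrist_rotation(markers, model, r_sh, r_el)
    return r_sh, r_el, r_wr


# ---------------------------------------------------------------------------
# compound-rotation extraction
# ---------------------------------------------------------------------------


class TestRotationExtraction:
    def test_reference_pose_gives_identities(self, reference_model):
        mf, _ = forward_kinematics(reference_model, np.zeros(7))
        for r in chain(mf, reference_model):
            np.testing.assert_allclose(r.matrix, np.eye(3), atol=1e-12)

    def test_matches_fk_local_rotations(self, reference_model, rng):
        """The extracted experimental matrices equal the FK compound
        rotations expressed in each joint's basis."""
        for th in random_in_range_angles(reference_model, rng, 15):
            mf, _ = forward_kinematics(reference_model, th, warn_out_of_limits=False)
            r_sh, r_el, r_wr = chain(mf, reference_model)
            rad = np.deg2rad(th)
            np.testing.assert_allclose(
                r_sh.matrix, _shoulder_rotation_local(rad[0], rad[1], rad[2]), atol=1e-9
            )
            np.testing.assert_allclose(
                r_el.matrix, _elbow_rotation_local(reference_model, rad[3], rad[4]),
                atol=1e-9,
            )
            np.testing.assert_allclose(
                r_wr.matrix, _wrist_rotation_local(reference_model, rad[5], rad[6]),
                atol=1e-9,
            )

    def test_pure_upstream_motion_leaves_downstream_identity(self, reference_model):
        mf, _ = forward_kinematics(reference_model, [30, 70, -40, 0, 0, 0, 0])
        _, r_el, r_wr = chain(mf, reference_model)
        np.testing.assert_allclose(r_el.matrix, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(r_wr.matrix, np.eye(3), atol=1e-9)
        mf, _ = forward_kinematics(reference_model, [30, 70, -40, 60, 45, 0, 0])
        *_, r_wr = chain(mf, reference_model)
        np.testing.assert_allclose(r_wr.matrix, np.eye(3), atol=1e-9)

    def test_translation_invariance(self, reference_model):
        mf, _ = forward_kinematics(reference_model, FIG1)
        shifted = mf.translated([1.23, -4.5, 0.77])
        for a, b in zip(chain(mf, reference_model), chain(shifted, reference_model)):
            np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-9)

    def test_degenerate_triad_rejected(self, reference_model):
        mf, _ = forward_kinematics(reference_model, np.zeros(7))
        pos = mf.positions.copy()
        pos[1:4] = pos[0]  # collapse the shoulder axis markers
        with pytest.raises(DegenerateMarkerError):
            shoulder_rotation(MarkerFrame(pos), reference_model)


# ---------------------------------------------------------------------------
# closed-form shoulder and elbow
# ---------------------------------------------------------------------------


class TestShoulder:
    def test_identity_is_zero_under_gimbal_convention(self):
        assert solve_shoulder(JointRotation(np.eye(3))) == pytest.approx((0, 0, 0))

    def test_fig1_configuration_round_trip(self, exact_model):
        mf, _ = forward_kinematics(exact_model, FIG1)
        r_sh = shoulder_rotation(mf, exact_model)
        elv, sh_elv, sh_rot = solve_shoulder(r_sh)
        assert (elv, sh_elv, sh_rot) == pytest.approx((0.0, 63.0, 15.0), abs=1e-9)

    def test_random_round_trips_exact_model(self, exact_model, rng):
        worst = 0.0
        for _ in range(1000):
            th = rng.uniform([-90, 1, -90], [130, 179, 20])
            r = JointRotation(_shoulder_rotation_local(*np.deg2rad(th)))
            est = np.array(solve_shoulder(r))
            worst = max(worst, np.max(np.abs(est - th)))
        assert worst < 1e-6

    def test_gimbal_uses_previous_elevation_plane(self):
        r = JointRotation(_shoulder_rotation_local(0.0, 0.0, np.deg2rad(-30.0)))
        elv, sh_elv, sh_rot = solve_shoulder(r, previous_elv_deg=42.0)
        assert elv == pytest.approx(42.0)
        assert sh_elv == pytest.approx(0.0, abs=1e-9)
        assert sh_rot == pytest.approx(-30.0, abs=1e-9)


class TestElbow:
    def test_identity_convention(self, reference_model):
        assert solve_elbow(JointRotation(np.eye(3)), reference_model) == pytest.approx((0.0, 0.0))

    def test_fig1_configuration_round_trip(self, exact_model):
        mf, _ = forward_kinematics(exact_model, FIG1)
        r_sh = shoulder_rotation(mf, exact_model)
        r_el = elbow_rotation(mf, exact_model, r_sh)
        assert solve_elbow(r_el, exact_model) == pytest.approx((95.0, -60.0), abs=1e-9)

    def test_random_round_trips_exact_model(self, exact_model, rng):
        worst = 0.0
        for _ in range(1000):
            th = rng.uniform([0.5, -90], [130, 90])
            r = JointRotation(_elbow_rotation_local(exact_model, *np.deg2rad(th)))
            est = np.array(solve_elbow(r, exact_model))
            worst = max(worst, np.max(np.abs(est - th)))
        assert worst < 1e-6


# ---------------------------------------------------------------------------
# wrist problem, borders and root find
# ---------------------------------------------------------------------------


def wrist_rotation_for(model, dev_c_deg, flex_c_deg):
    return JointRotation(
        _wrist_rotation_local(model, np.deg2rad(dev_c_deg), np.deg2rad(flex_c_deg))
    )


class TestWristProblem:
    def test_zero_pose_has_root_at_zero(self, reference_model):
        p = wrist_problem(wrist_rotation_for(reference_model, 0, 0), reference_model)
        sigma = np.sign(0.0 - p.eta) or 1.0
        assert abs(p.f(0.0, sigma)) < 1e-12

    def test_constants_match_matrix_form_oracle(self, reference_model, rng):
        """a cos(t) + b sin(t) - c(t) equals the matrix-form invariant
        d.exp(t f^)p - d.(R exp(-t e1^))p evaluated directly, on a dense grid."""
        d = reference_model.wrist_dev_axis
        f = reference_model.wrist_flex_axis
        pv = reference_model.wrist_pdr1_axis
        e1 = np.array([1.0, 0.0, 0.0])
        for _ in range(5):
            dev, flex = rng.uniform([-10, -70], [25, 70])
            r = wrist_rotation_for(reference_model, dev, flex)
            p = wrist_problem(r, reference_model)
            ts = np.linspace(-np.pi, np.pi, 1000)
            lhs = p.a * np.cos(ts) + p.b * np.sin(ts) - p.c(ts)
            direct = np.array(
                [
                    d @ (axis_angle(f, t) @ pv)
                    - d @ (r.matrix @ axis_angle(e1, -t) @ pv)
                    for t in ts
                ]
            )
            np.testing.assert_allclose(lhs, direct, atol=1e-12)

    def test_discriminant_nonnegative_at_true_root(self, reference_model, rng):
        """The root-existence condition c^2 <= xi holds at the generating
        flexion for every in-range configuration."""
        for _ in range(200):
            dev, flex = rng.uniform([-10, -70], [25, 70])
            p = wrist_problem(wrist_rotation_for(reference_model, dev, flex), reference_model)
            mu = np.deg2rad(flex / 2.0)
            assert p.xi >= 0
            assert p.c(mu) ** 2 <= p.xi + 1e-12


class TestSingularityBorders:
    def test_always_four_values(self, reference_model, rng):
        for _ in range(100):
            dev, flex = rng.uniform([-10, -70], [25, 70])
            p = wrist_problem(wrist_rotation_for(reference_model, dev, flex), reference_model)
            assert singularity_borders(p).shape == (4,)

    def test_real_borders_satisfy_c_squared_equals_xi(self, reference_model, rng):
        checked = 0
        for _ in range(300):
            dev, flex = rng.uniform([-10, -70], [25, 70])
            p = wrist_problem(wrist_rotation_for(reference_model, dev, flex), reference_model)
            for t in singularity_borders(p):
                if abs(t.imag) < 1e-9:
                    assert abs(p.c(t.real) ** 2 - p.xi) < 1e-9
                    checked += 1
        assert checked > 0  # real borders do occur in range

    def test_pairs_are_real_or_conjugate(self, reference_model, rng):
        for _ in range(100):
            dev, flex = rng.uniform([-10, -70], [25, 70])
            p = wrist_problem(wrist_rotation_for(reference_model, dev, flex), reference_model)
            b = singularity_borders(p)
            for k in (0, 1):
                pair = b[2 * k : 2 * k + 2]
                real = np.all(np.abs(pair.imag) < 1e-9)
                conj = abs(pair[0] - np.conj(pair[1])) < 1e-6
                assert real or conj

    def test_conjugate_pair_marks_branch_gap_extremum(self, reference_model):
        """When the k=1 pair is complex-conjugate (no singular region), the
        two branches of F are closest near Re(border)."""
        for dev, flex in ((5.0, 10.0), (-5.0, 30.0), (15.0, -20.0)):
            p = wrist_problem(wrist_rotation_for(reference_model, dev, flex), reference_model)
            pair = singularity_borders(p)[:2]
            if np.all(np.abs(pair.imag) < 1e-9):
                continue
            ts = np.linspace(-np.pi / 2, np.pi / 2, 20001)
            gap = p.f(ts, 1.0) - p.f(ts, -1.0)  # = 2*atan2 term >= 0
            t_min = ts[np.argmin(gap)]
            assert abs(t_min - pair[0].real) < np.deg2rad(1.0)


def bisect_oracle(problem, lo, hi, sigma, tol=1e-12):
    """Plain interval bisection, independent of Brent refinement."""
    f = lambda t: float(problem.f(t, sigma))
    a, b = lo, hi
    fa = f(a)
    for _ in range(200):
        if b - a < tol:
            break
        m = 0.5 * (a + b)
        fm = f(m)
        if fa * fm <= 0:
            b = m
        else:
            a, fa = m, fm
    return 0.5 * (a + b)


class TestWristSolve:
    def test_identity_rotation_gives_zero(self, reference_model):
        dev, flex, diag = solve_wrist(JointRotation(np.eye(3)), reference_model)
        assert dev == pytest.approx(0.0, abs=1e-9)
        assert flex == pytest.approx(0.0, abs=1e-9)

    def test_fig1_per_row_flexion_is_half_compound(self, reference_model):
        r = wrist_rotation_for(reference_model, 0.0, 20.0)
        p = wrist_problem(r, reference_model)
        mu, _ = solve_wrist_flexion(p)
        assert mu == pytest.approx(10.0, abs=1e-8)
        dev, flex, _ = solve_wrist(r, reference_model)
        assert (dev, flex) == pytest.approx((0.0, 20.0), abs=1e-8)

    def test_random_round_trips(self, reference_model, rng):
        worst = 0.0
        for _ in range(1000):
            dev, flex = rng.uniform([-10, -70], [25, 70])
            est_dev, est_flex, _ = solve_wrist(
                wrist_rotation_for(reference_model, dev, flex), reference_model
            )
            worst = max(worst, abs(est_dev - dev), abs(est_flex - flex))
        assert worst < 1e-4

    def test_branch_validity_condition(self, reference_model, rng):
        """Every returned root satisfies sigma = sign(mu - eta)."""
        for _ in range(200):
            dev, flex = rng.uniform([-10, -70], [25, 70])
            r = wrist_rotation_for(reference_model, dev, flex)
            p = wrist_problem(r, reference_model)
            mu, diag = solve_wrist_flexion(p)
            mu_rad = np.deg2rad(mu)
            if abs(mu_rad - p.eta) > 1e-9:
                assert diag["sigma"] == np.sign(mu_rad - p.eta)

    def test_brent_matches_bisection_oracle(self, reference_model, rng):
        """Brent-refined roots agree with plain bisection on the same
        bracket located by a dense independent grid scan."""
        for _ in range(50):
            dev, flex = rng.uniform([-10, -70], [25, 70])
            r = wrist_rotation_for(reference_model, dev, flex)
            p = wrist_problem(r, reference_model)
            mu, _ = solve_wrist_flexion(p)
            mu_rad = np.deg2rad(mu)
            sigma = 1.0 if mu_rad >= p.eta else -1.0
            grid = np.linspace(np.deg2rad(-35), np.deg2rad(35), 20001)
            fv = p.f(grid, sigma)
            ok = p.xi - p.c(grid) ** 2 >= -1e-12
            best = None
            for i in range(len(grid) - 1):
                if ok[i] and ok[i + 1] and fv[i] * fv[i + 1] <= 0:
                    root = bisect_oracle(p, grid[i], grid[i + 1], sigma)
                    if best is None or abs(root - mu_rad) < abs(best - mu_rad):
                        best = root
            assert best is not None
            assert abs(np.rad2deg(best) - mu) < 1e-6

    def test_previous_frame_selects_nearest_candidate(self, reference_model):
        r = wrist_rotation_for(reference_model, 2.0, 24.0)
        p = wrist_problem(r, reference_model)
        mu, _ = solve_wrist_flexion(p, previous_flex_deg=12.0)
        assert mu == pytest.approx(12.0, abs=0.5)


class TestContinuityFilter:
    def test_published_worked_example(self):
        assert continuity_filter(30.0, 10.0) == pytest.approx(10.5)

    def test_below_threshold_passes_through(self):
        assert continuity_filter(12.0, 10.0) == 12.0

    def test_first_frame_passes_through(self):
        assert continuity_filter(30.0, None) == 30.0

    def test_impulse_sequence(self):
        seq = [0.0, 0.0, 18.0, 0.0]
        out, prev = [], None
        for v in seq:
            prev = continuity_filter(v, prev)
            out.append(prev)
        assert out == [0.0, 0.0, 0.5, 0.0]

    def test_signed_variant_steps_toward_raw(self):
        assert continuity_filter(-30.0, 10.0, signed=True) == pytest.approx(9.5)


# ---------------------------------------------------------------------------
# full-frame chain
# ---------------------------------------------------------------------------


class TestSolveFrame:
    def test_fig1_all_seven_recovered(self, reference_model):
        mf, _ = forward_kinematics(reference_model, FIG1)
        res = solve_frame(mf, reference_model)
        assert not res.failed
        np.testing.assert_allclose(res.angles.as_array(), FIG1, atol=1e-6)

    def test_round_trip_double_exact_model(self, exact_model, rng):
        worst = 0.0
        for th in random_in_range_angles(exact_model, rng, 300):
            mf, _ = forward_kinematics(exact_model, th, warn_out_of_limits=False)
            res = solve_frame(mf, exact_model)
            assert not res.failed
            worst = max(worst, np.max(np.abs(res.angles.as_array() - th)))
        assert worst < 1e-4

    def test_translation_invariance_of_full_solution(self, reference_model):
        mf, _ = forward_kinematics(reference_model, FIG1)
        a = solve_frame(mf, reference_model).angles.as_array()
        b = solve_frame(mf.translated([0.4, 9.0, -2.2]), reference_model).angles.as_array()
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_orientation_input_equivalent_to_markers(self, reference_model):
        mf, of = forward_kinematics(reference_model, FIG1)
        a = solve_frame(mf, reference_model).angles.as_array()
        b = solve_frame(of, reference_model).angles.as_array()
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_wrist_only_variation_leaves_upstream_constant(self, exact_model):
        """Varying only the compound flexion changes only the wrist outputs."""
        base = np.array([20.0, 50.0, -10.0, 40.0, 30.0, 5.0, 0.0])
        ref = solve_frame(forward_kinematics(exact_model, base)[0], exact_model)
        for flex in (-40.0, -10.0, 25.0, 55.0):
            th = base.copy()
            th[6] = flex
            res = solve_frame(forward_kinematics(exact_model, th)[0], exact_model)
            np.testing.assert_allclose(
                res.angles.as_array()[:5], ref.angles.as_array()[:5], atol=1e-9
            )
            assert res.angles.theta_flex_c == pytest.approx(flex, abs=1e-6)

    def test_out_of_range_flagged_not_clamped_by_default(self, exact_model):
        # elbow hyperflexion: outside the 0-130 degree model range
        mf, _ = forward_kinematics(exact_model, [0, 63, 0, 135, 0, 0, 0],
                                   warn_out_of_limits=False)
        res = solve_frame(mf, exact_model)
        assert "theta_el_flex" in res.out_of_range
        sat = solve_frame(mf, exact_model, saturate=True)
        assert sat.angles.theta_el_flex == pytest.approx(130.0)

    def test_single_mod_applies_continuity_filter(self, reference_model):
        solver = IKSolver(reference_model, mode="single_mod")
        mf0, _ = forward_kinematics(reference_model, [0, 40, 0, 30, 0, 0, 4.0])
        mf1, _ = forward_kinematics(reference_model, [0, 40, 0, 30, 0, 0, 30.0])
        r0 = solver.step(mf0)
        r1 = solver.step(mf1)
        assert r0.angles.theta_flex_c == pytest.approx(4.0, abs=0.1)
        assert r1.continuity_applied
        assert r1.angles.theta_flex_c == pytest.approx(r0.angles.theta_flex_c + 0.5)

    def test_streaming_solver_matches_batch(self, reference_model, rng):
        ths = random_in_range_angles(reference_model, rng, 10)
        frames = [forward_kinematics(reference_model, th, warn_out_of_limits=False)[0]
                  for th in ths]
        solver = IKSolver(reference_model)
        stream = np.array([solver.step(f).angles.as_array() for f in frames])
        from armik.motion import MarkerTrajectory

        traj = MarkerTrajectory(
            times=np.arange(10) * 0.01,
            positions=np.stack([f.positions for f in frames]),
        )
        batch = IKSolver(reference_model).solve_trajectory(traj)
        np.testing.assert_allclose(stream, batch, atol=1e-12)
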