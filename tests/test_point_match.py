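"""Point-match solver: closed forms, oracles, degeneracy handling."""

import io

import numpy as np
import pytest

from fidreg import (
    DegenerateConfigurationError,
    EulerAngles6D,
    InvalidCorrespondenceError,
    MarkerCloud,
    brute_force_oracle,
    center_clouds,
    cloud_from_points,
    compose,
    euler_to_transform,
    read_marker_cloud,
    registration_cost,
    solve_point_match,
    solve_quaternion_oracle,
    write_marker_cloud,
)

from .conftest import random_transform


def _noisy_pair(rng, n=8, sigma=0.3, max_deg=3.0, max_mm=10.0):
    pts = rng.uniform(-80, 80, size=(n, 3))
    true = random_transform(rng, max_deg=max_deg, max_mm=max_mm)
    a = cloud_from_points(pts, frame="planning-CT")
    b = a.with_positions(true.apply(pts) + rng.normal(0, sigma, (n, 3)), frame="CBCT")
    return a, b, true


class TestCenterClouds:
    def test_centroid_is_arithmetic_mean(self):
        a = np.array([[0.0, 0, 0], [2, 0, 0], [1, 3, 0]])
        pair = center_clouds(a, a)
        assert np.allclose(pair.centroid_a, [1, 1, 0])
        assert np.allclose(pair.a_centered.sum(axis=0), 0, atol=1e-12)

    def test_already_centered_set_unchanged(self):
        a = np.array([[1.0, 0, 0], [-1, 1, 0], [0, -1, 0]])
        a = a - a.mean(axis=0)
        pair = center_clouds(a, a)
        assert np.allclose(pair.centroid_a, 0, atol=1e-12)
        assert np.allclose(pair.a_centered, a, atol=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(-50, 50, size=(8, 3))
        shifted = center_clouds(a + np.array([5.0, 5, 5]), a)
        plain = center_clouds(a, a)
        assert np.allclose(shifted.a_centered, plain.a_centered, atol=1e-12)

    def test_bad_input_rejected(self):
        with pytest.raises(InvalidCorrespondenceError):
            center_clouds(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(InvalidCorrespondenceError):
            center_clouds(np.zeros((2, 3)), np.zeros((2, 3)))


class TestSolvePointMatch:
    def test_identity(self, tetra_clouds):
        a, b = tetra_clouds
        sol = solve_point_match(a, b, group=None)
        assert np.allclose(sol.transform.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(sol.transform.translation, 0, atol=1e-12)
        assert sol.fre_rms < 1e-12

    def test_pure_translation(self, tetra_clouds):
        a, b = tetra_clouds
        b = b.with_positions(a.positions + np.array([1.0, 2, 3]))
        sol = solve_point_match(a, b, group=None)
        assert np.allclose(sol.transform.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(sol.transform.translation, [1, 2, 3], atol=1e-12)
        assert sol.fre_rms < 1e-12

    def test_exact_quarter_turn(self, tetra_clouds):
        a, b = tetra_clouds
        rz90 = euler_to_transform(EulerAngles6D(0, 0, 0, 0, 0, 90))
        sol = solve_point_match(a, b.with_positions(rz90.apply(a.positions)), group=None)
        assert np.allclose(sol.transform.rotation, rz90.rotation, atol=1e-9)
        assert np.allclose(sol.transform.translation, 0, atol=1e-9)
        assert sol.fre_rms < 1e-9

    def test_correspondence_is_by_id_not_order(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-50, 50, (6, 3))
        a = cloud_from_points(pts, frame="plan")
        perm = rng.permutation(6)
        b = MarkerCloud(
            tuple(a.ids[i] for i in perm), tuple(a.groups[i] for i in perm),
            pts[perm] + np.array([1.0, 2, 3]), "setup",
        )
        sol = solve_point_match(a, b, group=None)
        assert np.allclose(sol.transform.translation, [1, 2, 3], atol=1e-9)
        assert sol.fre_rms < 1e-9

    def test_mismatched_ids_rejected(self):
        a = cloud_from_points(np.eye(3) * 10, prefix="A")
        b = cloud_from_points(np.eye(3) * 10, prefix="B")
        with pytest.raises(InvalidCorrespondenceError):
            solve_point_match(a, b, group=None)

    def test_collinear_markers_rejected(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        a = cloud_from_points(pts)
        with pytest.raises(DegenerateConfigurationError):
            solve_point_match(a, a.with_positions(pts), group=None)

    def test_zero_noise_exact_recovery(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            pts = rng.uniform(-80, 80, (8, 3))
            true = random_transform(rng)
            a = cloud_from_points(pts)
            b = a.with_positions(true.apply(pts))
            sol = solve_point_match(a, b, group=None)
            assert np.linalg.norm(sol.transform.rotation - true.rotation) < 1e-9
            assert np.linalg.norm(sol.transform.translation - true.translation) < 1e-9
            assert sol.fre_rms < 1e-9

    def test_equivariance_under_common_rigid_motion(self):
        # moving both clouds by G conjugates the solution; FRE unchanged
        rng = np.random.default_rng(3)
        a, b, _ = _noisy_pair(rng)
        g = random_transform(rng, max_deg=30, max_mm=40)
        sol = solve_point_match(a, b, group=None)
        sol_g = solve_point_match(
            a.with_positions(g.apply(a.positions)),
            b.with_positions(g.apply(b.positions)),
            group=None,
        )
        conjugated = compose(compose(g, sol.transform), g.inverse())
        assert np.allclose(sol_g.transform.rotation, conjugated.rotation, atol=1e-9)
        assert np.allclose(sol_g.transform.translation, conjugated.translation, atol=1e-8)
        assert np.isclose(sol_g.fre_rms, sol.fre_rms, atol=1e-9)

    def test_global_optimality_against_random_perturbations(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a, b, _ = _noisy_pair(rng)
            sol = solve_point_match(a, b, group=None)
            best = registration_cost(sol.transform, a.positions, b.positions)
            for _ in range(20):
                d = random_transform(rng, max_deg=0.5, max_mm=0.5)
                perturbed = compose(d, sol.transform)
                assert best <= registration_cost(perturbed, a.positions, b.positions) + 1e-9


class TestOracles:
    def test_quaternion_identity(self, tetra_clouds):
        a, b = tetra_clouds
        sol = solve_quaternion_oracle(a, b, group=None)
        assert np.allclose(sol.transform.rotation, np.eye(3), atol=1e-9)

    def test_quaternion_matches_svd_on_noisy_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a, b, _ = _noisy_pair(rng, n=int(rng.integers(4, 12)))
            s = solve_point_match(a, b, group=None)
            q = solve_quaternion_oracle(a, b, group=None)
            assert np.linalg.norm(s.transform.rotation - q.transform.rotation) < 1e-9
            assert np.linalg.norm(s.transform.translation - q.transform.translation) < 1e-9

    def test_grid_zero_noise_identity(self, tetra_clouds):
        a, b = tetra_clouds
        sol = brute_force_oracle(a, b, angle_window=3.0, grid_step=0.5, group=None)
        assert registration_cost(sol.transform, a.positions, b.positions) < 1e-12

    def test_grid_finds_known_roll(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(-80, 80, (6, 3))
        a = cloud_from_points(pts)
        roll = euler_to_transform(EulerAngles6D(0, 0, 0, 0, 0, 2.0))
        b = a.with_positions(roll.apply(pts))
        sol = brute_force_oracle(a, b, angle_window=3.0, grid_step=0.1, group=None)
        assert np.allclose(sol.transform.rotation, roll.rotation, atol=1e-6)

    def test_svd_cost_below_grid_minimum(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            a, b, _ = _noisy_pair(rng, sigma=0.5)
            s = solve_point_match(a, b, group=None)
            g = brute_force_oracle(a, b, angle_window=3.0, grid_step=0.25, group=None)
            cs = registration_cost(s.transform, a.positions, b.positions)
            cg = registration_cost(g.transform, a.positions, b.positions)
            assert cs <= cg + 1e-9

    def test_grid_argument_validation(self, tetra_clouds):
        a, b = tetra_clouds
        from fidreg import InvalidArgumentError

        with pytest.raises(InvalidArgumentError):
            brute_force_oracle(a, b, angle_window=1.0, grid_step=2.0, group=None)


class TestReflectionGuard:
    def test_mirrored_near_coplanar_clouds_stay_proper(self):
        rng = np.random.default_rng(8)
        saw_reflection_case = 0
        for _ in range(50):
            pts = rng.uniform(-60, 60, (8, 3))
            pts[:, 2] *= 1e-3  # nearly coplanar
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            a = cloud_from_points(pts)
            b = a.with_positions(mirrored + rng.normal(0, 0.05, (8, 3)))
            pair_h = (pts - pts.mean(0)).T @ (b.positions - b.positions.mean(0))
            u, _, vt = np.linalg.svd(pair_h)
            if np.linalg.det(vt.T @ u.T) < 0:
                saw_reflection_case += 1
            sol = solve_point_match(a, b, group=None)
            assert np.isclose(np.linalg.det(sol.transform.rotation), 1.0, atol=1e-9)
        # the construction must actually exercise the det = -1 branch
        assert saw_reflection_case > 25


class TestMarkerCloudIO:
    def test_round_trip(self, cranial_phantom):
        cloud = cranial_phantom.layout
        buf = io.StringIO()
        write_marker_cloud(cloud, buf)
        buf.seek(0)
        back = read_marker_cloud(buf)
        assert back.ids == cloud.ids
        assert back.groups == cloud.groups
        assert back.frame == cloud.frame
        assert np.allclose(back.positions, cloud.positions)

    def test_comments_and_header(self):
        text = (
            "# fiducial export\n"
            "id,group,frame,x_mm,y_mm,z_mm\n"
            "M01,C,planning-CT,0,0,0\n"
            "M02,C,planning-CT,10,0,0\n"
            "# trailing comment\n"
            "M03,V,planning-CT,0,10,0\n"
        )
        cloud = read_marker_cloud(io.StringIO(text))
        assert len(cloud) == 3
        assert cloud.subset("V").ids == ("M03",)

    def test_duplicate_ids_rejected(self):
        text = "id,group,frame,x_mm,y_mm,z_mm\nM1,C,f,0,0,0\nM1,C,f,1,0,0\nM2,C,f,0,1,0\n"
        from fidreg import InvalidArgumentError

        with pytest.raises(InvalidArgumentError):
            read_marker_cloud(io.StringIO(text))
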