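import numpy as np
import pytest

from wmring.fixtures import make_planted_ring
from wmring.state_geometry import (FixedPoint, Plane, classify_spectrum,
                                   delay_start_seeds, dimensionality,
                                   find_fixed_points, finite_difference_jacobian,
                                   fit_plane, manifold_ring)
from wmring.training import init_params
from wmring.circular import circ_diff


class LinearDynamics:
    """F(x) = (A - I) x: a single fixed point at the origin with known
    spectrum; test-local oracle for the fixed-point machinery."""

    def __init__(self, A):
        self.A = np.asarray(A, dtype=float)

    def velocity(self, x):
        return np.asarray(x) @ (self.A - np.eye(len(self.A))).T

    def jacobian(self, x):
        return self.A - np.eye(len(self.A))

    def speed_grad(self, x):
        J = self.jacobian(x)
        return 2.0 * self.velocity(x) @ J


class TestPlane:
    def test_planar_cloud_reconstructs_exactly(self):
        rng = np.random.default_rng(0)
        basis = np.linalg.qr(rng.standard_normal((7, 2)))[0].T
        coords = rng.standard_normal((50, 2)) * [3.0, 1.5]
        states = coords @ basis + rng.standard_normal(7) * 0.0 + 5.0
        plane = fit_plane(states)
        rec = plane.lift(plane.project(states))
        assert np.max(np.abs(rec - states)) < 1e-8

    def test_lift_project_idempotent(self):
        rng = np.random.default_rng(1)
        states = rng.standard_normal((40, 6))
        plane = fit_plane(states)
        once = plane.lift(plane.project(states))
        twice = plane.lift(plane.project(once))
        assert np.allclose(once, twice, atol=1e-12)

    def test_axes_orthonormal_and_projection_centered(self):
        states = np.random.default_rng(2).standard_normal((100, 5))
        plane = fit_plane(states)
        assert np.allclose(plane.axes @ plane.axes.T, np.eye(2), atol=1e-10)
        assert np.allclose(plane.project(states).mean(axis=0), 0.0, atol=1e-10)

    def test_isotropic_cloud_explained_ratio(self):
        # two PCs of an isotropic d=10 Gaussian explain ~2/d (slightly more
        # from eigenvalue ordering; bracket set by simulation)
        states = np.random.default_rng(3).standard_normal((4000, 10))
        plane = fit_plane(states)
        assert 0.20 < plane.explained_variance_ratio.sum() < 0.24

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_plane(np.zeros((10, 4)))
        with pytest.raises(ValueError):
            fit_plane(np.random.randn(2, 4))


class TestDimensionality:
    def test_rank_two_dynamics_saturate_at_two_components(self):
        # a network whose recurrent weights are rank-2 and inputs confined to
        # the same plane produce rank-2 trajectories
        net = make_planted_ring(d=10, rng_seed=4)
        states = np.vstack([net.ring_state(a, radius=r)
                            for a in np.arange(0, 360, 10.0)
                            for r in (0.7, 1.0, 1.3)])
        plane = fit_plane(states)
        assert plane.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)


class TestFixedPoints:
    def test_linear_system_fixed_point_and_spectrum(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((6, 6)) * 0.2
        dyn = LinearDynamics(A)
        seeds = rng.standard_normal((20, 6)) * 2.0
        fps = find_fixed_points(dyn, seeds, tol_speed=1e-8, max_iters=4000,
                                lr=5e-2, dedup_radius=0.5, dt_ms=1.0)
        assert len(fps) == 1
        fp = fps[0]
        assert np.allclose(fp.x_star, 0.0, atol=1e-3)
        want = np.sort_complex(np.linalg.eigvals(A - np.eye(6)))
        got = np.sort_complex(fp.eigenvalues)
        assert np.allclose(got, want, atol=1e-3)
        assert fp.kind == "attractor"          # spectral radius of A < 1

    def test_planted_ring_recovered_with_classes(self):
        net = make_planted_ring(d=12, k_attractors=4, theta0=40.0, rng_seed=0)
        seeds = net.ring_state(np.arange(0.0, 360.0, 7.5))
        seeds = seeds + np.random.default_rng(1).normal(0, 0.02, seeds.shape)
        fps = find_fixed_points(net, seeds, tol_speed=1e-7, max_iters=4000,
                                lr=5e-3, dedup_radius=0.3, dt_ms=1.0)
        att = [fp for fp in fps if fp.kind == "attractor"]
        sad = [fp for fp in fps if fp.kind == "saddle"]
        assert len(att) == 4 and len(sad) == 4

        def plane_angle(fp):
            u, v = net.Q @ (fp.x_star - net.center)
            return np.degrees(np.arctan2(v, u)) % 360

        att_angles = np.sort([plane_angle(fp) for fp in att])
        sad_angles = np.sort([plane_angle(fp) for fp in sad])
        assert np.max(np.abs(circ_diff(att_angles,
                                       np.sort(net.attractor_angles)))) < 2.0
        assert np.max(np.abs(circ_diff(sad_angles,
                                       np.sort(net.saddle_angles)))) < 2.0
        want = np.sort(net.expected_eigenvalues(net.attractor_angles[0]).real)
        for fp in att:
            assert np.allclose(np.sort(fp.eigenvalues.real), want, atol=1e-3)

    def test_neutral_ring_not_classified_as_attractor(self):
        net = make_planted_ring(d=8, strength=0.0, rng_seed=2)
        seeds = net.ring_state(np.arange(0.0, 360.0, 30.0))
        fps = find_fixed_points(net, seeds, tol_speed=1e-7, max_iters=500,
                                lr=1e-3, dedup_radius=1e-3, dt_ms=1.0)
        assert len(fps) > 0
        assert all(fp.kind == "neutral" for fp in fps)

    def test_infinite_tolerance_returns_seeds_immediately(self):
        net = make_planted_ring(d=8, rng_seed=3)
        seeds = net.ring_state(np.array([0.0, 90.0]))
        fps = find_fixed_points(net, seeds, tol_speed=np.inf, max_iters=10,
                                dedup_radius=1e-9)
        assert len(fps) == 2

    def test_no_convergence_warns_and_returns_empty(self):
        dyn = LinearDynamics(np.eye(3) * 5.0)   # strongly expanding
        with pytest.warns(UserWarning):
            fps = find_fixed_points(dyn, np.ones((2, 3)), tol_speed=1e-12,
                                    max_iters=5, lr=1e-3)
        assert fps == []


class TestJacobians:
    def test_analytic_matches_finite_differences_network(self):
        p = init_params(12, rng=0)
        rng = np.random.default_rng(1)
        for _ in range(3):
            x = rng.standard_normal(12)
            J = p.jacobian(x)
            J_fd = finite_difference_jacobian(p.velocity, x)
            assert np.max(np.abs(J - J_fd)) < 1e-4

    def test_analytic_matches_finite_differences_planted(self):
        net = make_planted_ring(d=9, rng_seed=5)
        rng = np.random.default_rng(2)
        for _ in range(3):
            x = net.ring_state(rng.uniform(0, 360), radius=rng.uniform(0.5, 1.5))
            x = x + rng.normal(0, 0.1, 9)
            J = net.jacobian(x)
            J_fd = finite_difference_jacobian(net.velocity, x)
            assert np.max(np.abs(J - J_fd)) < 1e-4

    def test_speed_gradient_matches_finite_differences(self):
        p = init_params(10, rng=3)
        x = np.random.default_rng(4).standard_normal(10)
        g = p.speed_grad(x[None])[0]
        h = 1e-6
        for j in range(10):
            e = np.zeros(10)
            e[j] = h
            fd = (np.sum(p.velocity(x + e) ** 2)
                  - np.sum(p.velocity(x - e) ** 2)) / (2 * h)
            assert g[j] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestClassification:
    def test_rules(self):
        assert classify_spectrum(np.array([-0.5, -0.1 + 0.3j])) == "attractor"
        assert classify_spectrum(np.array([-0.5, 0.2])) == "saddle"
        assert classify_spectrum(np.array([-0.5, 0.0])) == "neutral"


class TestManifoldRing:
    def test_traces_a_curved_ring_where_plane_circle_fails(self):
        # closed curve with out-of-plane harmonic: x = (cos t, sin t, 0.8 sin 2t)
        t = np.linspace(0, 2 * np.pi, 600, endpoint=False)
        states = np.stack([np.cos(t), np.sin(t), 0.8 * np.sin(2 * t)], axis=1)
        states = states + np.random.default_rng(0).normal(0, 0.01, states.shape)
        plane = fit_plane(states)
        ring, theta = manifold_ring(states, plane, n_out=360)
        # manifold probe stays near the true curve; plane circle does not
        def dist_to_curve(pts):
            d = np.linalg.norm(pts[:, None, :] - states[None], axis=2)
            return d.min(axis=1).mean()
        assert dist_to_curve(ring) < 0.08
        assert dist_to_curve(plane.ring_states(360)) > 0.2
        assert np.all(np.diff(theta) > -1e-9)

    def test_too_sparse_coverage_rejected(self):
        states = np.random.default_rng(1).normal(0, 0.01, (50, 3)) + [5.0, 0, 0]
        plane = Plane(mean=np.zeros(3),
                      axes=np.array([[1.0, 0, 0], [0, 1.0, 0]]),
                      ring_radius=5.0, radius_spread=0.1)
        with pytest.raises(ValueError):
            manifold_ring(states, plane)
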