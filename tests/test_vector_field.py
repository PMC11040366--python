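"""Vector-field reconstruction: fit quality against the generating drift,
analytic Jacobian identity, differential geometry, and fixed-point search."""
import numpy as np
import pytest

import fluxcycle as fc
from fluxcycle.grids import StateGrid
from fluxcycle._sde import deterministic_orbit

from conftest import finite_difference_jacobian


def constant_field_samples(v=(1.0, 0.0), n=200, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-1, 1, size=(n, 2))
    vel = np.tile(np.asarray(v, float), (n, 1))
    return fc.VelocitySampleSet(pos, vel)


class TestFit:
    def test_constant_field_reproduced_exactly(self):
        model = fc.fit_vector_field(constant_field_samples(), seed=0)
        rng = np.random.default_rng(1)
        pts = rng.uniform(-0.9, 0.9, size=(100, 2))
        assert np.allclose(model.evaluate(pts), [1.0, 0.0], atol=1e-6)

    def test_hopf_heldout_error_below_noise(self, hopf):
        samples = fc.sample_velocities(hopf, 500, sampling="uniform",
                                       noise_sd=0.05, seed=7)
        model = fc.fit_vector_field(samples, seed=0)
        rng = np.random.default_rng(11)
        pts = np.column_stack([rng.uniform(-1.1, 1.1, 200), rng.uniform(-1.1, 1.1, 200)])
        err = model.evaluate(pts) - hopf.drift(pts)
        assert np.sqrt((err**2).mean()) < 0.05

    def test_fit_error_decreases_with_noise(self, hopf):
        errs = []
        for noise in [0.2, 0.05, 0.0]:
            s = fc.sample_velocities(hopf, 400, sampling="uniform",
                                     noise_sd=noise, seed=5)
            m = fc.fit_vector_field(s, seed=0, holdout_frac=0.0)
            pts = s.positions
            errs.append(np.sqrt(((m.evaluate(pts) - hopf.drift(pts)) ** 2).mean()))
        assert errs[0] > errs[1] > errs[2]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fc.fit_vector_field(constant_field_samples(n=5))


class TestEvaluateAndJacobian:
    def test_evaluation_matches_dense_expansion(self, hill_model):
        """Independent brute-force kernel expansion oracle."""
        rng = np.random.default_rng(3)
        d = hill_model.domain
        pts = np.column_stack([
            rng.uniform(d.x_min, d.x_max, 50),
            rng.uniform(d.y_min, d.y_max, 50),
        ])
        expected = np.empty((50, 2))
        for i, p in enumerate(pts):
            acc = hill_model.bias.copy()
            for c, w in zip(hill_model.centers, hill_model.coefficients):
                acc = acc + w * np.exp(-((p - c) ** 2).sum() / (2 * hill_model.bandwidth**2))
            expected[i] = acc
        assert np.allclose(hill_model.evaluate(pts), expected, atol=1e-10)

    def test_analytic_jacobian_matches_finite_differences(self, hill_model):
        rng = np.random.default_rng(8)
        d = hill_model.domain
        pts = np.column_stack([
            rng.uniform(d.x_min, d.x_max, 100),
            rng.uniform(d.y_min, d.y_max, 100),
        ])
        J = hill_model.jacobian(pts)
        Jfd = finite_difference_jacobian(hill_model.evaluate, pts)
        assert np.allclose(J, Jfd, rtol=1e-5, atol=1e-7)

    def test_linear_field_jacobian_recovered(self):
        A = np.array([[-1.0, 0.5], [-0.5, -2.0]])
        rng = np.random.default_rng(0)
        pos = rng.uniform(-1, 1, size=(800, 2))
        s = fc.VelocitySampleSet(pos, pos @ A.T)
        # wide kernels suit a globally linear field
        m = fc.fit_vector_field(s, ridge=1e-8, seed=0, bandwidth=1.0)
        pts = rng.uniform(-0.5, 0.5, size=(30, 2))
        assert np.allclose(m.jacobian(pts), A, atol=1e-2)

    def test_hill_fit_jacobian_close_to_analytic_on_cycle(self, hill_system, hill_model):
        orbit = deterministic_orbit(hill_system.drift, np.array([1.5, 0.8]),
                                    dt=0.01, n_steps=5000)[2000::300]
        J_fit = hill_model.jacobian(orbit)
        J_true = hill_system.jacobian(orbit)
        scale = np.abs(J_true).max()
        assert np.abs(J_fit - J_true).max() < 0.10 * scale * 3

    def test_model_json_round_trip(self, hill_model, tmp_path):
        path = tmp_path / "model.json"
        hill_model.to_json(path)
        m2 = fc.VectorFieldModel.from_json(path)
        pts = np.array([[1.0, 1.0], [0.5, 2.0]])
        assert np.allclose(m2.evaluate(pts), hill_model.evaluate(pts))
        assert np.allclose(m2.jacobian(pts), hill_model.jacobian(pts))


class TestDifferentialGeometry:
    def test_rigid_rotation_closed_forms(self):
        system = fc.make_linear([[0.0, -1.0], [1.0, 0.0]])
        grid = StateGrid(-1, 1, -1, 1, 16, 16)
        geo = fc.differential_geometry(system, grid)
        assert np.allclose(geo.divergence, 0.0, atol=1e-12)
        assert np.allclose(geo.curl, 2.0)
        xx, yy = grid.meshgrid()
        assert np.allclose(geo.speed, np.hypot(xx, yy))

    def test_radial_contraction_closed_forms(self):
        system = fc.make_linear([[-1.0, 0.0], [0.0, -1.0]])
        geo = fc.differential_geometry(system, StateGrid(-1, 1, -1, 1, 8, 8))
        assert np.allclose(geo.divergence, -2.0)
        assert np.allclose(geo.curl, 0.0, atol=1e-12)

    def test_acceleration_matches_trajectory_finite_differences(self, hopf):
        """a = J F along the orbit vs numerical dv/dt on an integrated path."""
        dt = 1e-3
        orbit = deterministic_orbit(hopf.drift, np.array([1.0, 0.0]),
                                    dt=dt, n_steps=2000)
        v = hopf.drift(orbit)
        a_num = (v[2:] - v[:-2]) / (2 * dt)
        J = hopf.jacobian(orbit[1:-1])
        a_ana = np.einsum("kab,kb->ka", J, v[1:-1])
        denom = np.linalg.norm(a_num, axis=1).max()
        assert np.abs(a_ana - a_num).max() < 0.02 * denom

    def test_curvature_flagged_at_stagnation(self):
        system = fc.make_linear([[-1.0, 0.0], [0.0, -1.0]])
        grid = StateGrid(-1, 1, -1, 1, 9, 9)  # odd => a center cell near 0
        geo = fc.differential_geometry(system, grid, speed_tol=1e-3)
        assert np.isnan(geo.curvature[4, 4]).all()


class TestFixedPoints:
    def test_single_stable_node(self):
        system = fc.make_linear([[-1.0, 0.0], [0.0, -1.0]])
        fps = fc.find_fixed_points(system, n_starts=20, seed=0)
        assert len(fps) == 1
        assert fps[0].kind == "stable_node"
        assert np.allclose(fps[0].location, 0.0, atol=1e-5)
        assert np.allclose(sorted(fps[0].eigenvalues.real), [-1, -1])

    def test_fitted_hill_field_has_interior_unstable_focus(self, hill_model):
        fps = fc.find_fixed_points(hill_model, n_starts=80, seed=0)
        assert any(fp.kind == "unstable_focus" for fp in fps)
        focus = next(fp for fp in fps if fp.kind == "unstable_focus")
        assert np.linalg.norm(focus.location - np.array([0.91, 1.20])) < 0.25

    def test_no_roots_warns_not_raises(self):
        samples = constant_field_samples(v=(1.0, 0.0))
        model = fc.fit_vector_field(samples, seed=0)
        with pytest.warns(UserWarning):
            fps = fc.find_fixed_points(model, n_starts=5, seed=0)
        assert fps == []

    def test_residual_below_tolerance(self, hill_model):
        tol = 1e-6
        for fp in fc.find_fixed_points(hill_model, n_starts=40, tol=tol, seed=2):
            assert fp.residual < tol
            assert 0 < fp.confidence <= 1
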