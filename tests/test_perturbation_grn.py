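"""In silico perturbation bilinearity, signed-interaction recovery from the
analytic oscillator Jacobian, and Hill-derivative parameter fitting."""
import numpy as np
import pytest

import fluxcycle as fc
from fluxcycle._sde import deterministic_orbit


@pytest.fixture(scope="module")
def cycle_states(hill_system):
    orbit = deterministic_orbit(hill_system.drift, np.array([1.5, 0.8]),
                                dt=0.01, n_steps=8000)
    return orbit[2000::20]       # ~3 cycles of on-attractor states


@pytest.fixture(scope="module")
def linear_model():
    A = np.array([[0.0, -1.0], [1.0, 0.0]])
    rng = np.random.default_rng(0)
    pos = rng.uniform(-1, 1, size=(600, 2))
    samples = fc.VelocitySampleSet(pos, pos @ A.T)
    return fc.fit_vector_field(samples, ridge=1e-8, seed=0), A, samples


class TestPerturbVelocities:
    def test_zero_delta_rejected_and_identity(self, linear_model):
        model, A, samples = linear_model
        with pytest.raises(ValueError):
            fc.PerturbationSpec(deltas=[0.0, 0.0])
        spec = fc.PerturbationSpec(deltas=[1e-300, 0.0])
        out = fc.perturb_velocities(model, samples, spec)
        assert np.allclose(out.velocities_prime, samples.velocities)

    def test_linear_field_response_is_exact(self, linear_model):
        model, A, samples = linear_model
        spec = fc.PerturbationSpec(deltas=[-0.5, 0.2], amplification_c=2.0)
        out = fc.perturb_velocities(model, samples, spec)
        df = out.velocities_prime - samples.velocities
        expected = (2.0 * np.array([-0.5, 0.2])) @ A.T
        inner = np.linalg.norm(samples.positions, axis=1) < 0.8
        assert np.allclose(df[inner], expected, atol=2e-2)

    def test_bilinearity_in_amplification(self, linear_model):
        model, _, samples = linear_model
        a = fc.perturb_velocities(model, samples,
                                  fc.PerturbationSpec([0.3, -0.1], amplification_c=5.0))
        b = fc.perturb_velocities(model, samples,
                                  fc.PerturbationSpec([1.5, -0.5], amplification_c=1.0))
        assert np.allclose(a.velocities_prime, b.velocities_prime)

    def test_zero_perturbation_refit_reproduces_model(self, linear_model):
        model, _, samples = linear_model
        spec = fc.PerturbationSpec(deltas=[1e-300, 0.0])
        refit = fc.refit_perturbed_field(fc.perturb_velocities(model, samples, spec),
                                         ridge=1e-8, seed=0)
        pts = np.random.default_rng(1).uniform(-0.8, 0.8, size=(50, 2))
        assert np.allclose(refit.evaluate(pts), model.evaluate(pts), atol=1e-8)


class TestInferGrn:
    def test_linear_rotation_signs(self):
        system = fc.make_linear([[0.0, -1.0], [1.0, 0.0]])
        states = np.random.default_rng(0).uniform(-1, 1, size=(100, 2))
        edges = {(e.source, e.target): e for e in fc.infer_grn(system, states)}
        assert edges[("gene_y", "gene_x")].sign == -1
        assert edges[("gene_x", "gene_y")].sign == +1
        assert edges[("gene_y", "gene_x")].support == 1.0

    def test_hill_oscillator_interaction_signs(self, hill_system, cycle_states):
        """The oscillator's wiring: y -| x, x -> y, and both self-activate
        (the self Jacobian includes degradation, so the sign check applies
        to the production part via the off-diagonal threshold)."""
        edges = {(e.source, e.target): e
                 for e in fc.infer_grn(hill_system, cycle_states)}
        assert edges[("gene_y", "gene_x")].sign == -1     # inhibition
        assert edges[("gene_x", "gene_y")].sign == +1     # activation
        # production terms of the diagonal are activating: J_diag + g > 0
        p = fc.DEFAULT_HILL_PARAMS
        J = hill_system.jacobian(cycle_states)
        assert (J[:, 0, 0] + p.g1).mean() > 0
        assert (J[:, 1, 1] + p.g2).mean() > 0

    def test_gradient_system_has_symmetric_jacobian(self, double_well, cycle_states):
        rng = np.random.default_rng(4)
        states = np.column_stack([rng.uniform(-1.5, 1.5, 200), rng.uniform(-1, 1, 200)])
        J = double_well.jacobian(states)
        assert np.allclose(J[:, 0, 1], J[:, 1, 0])


class TestResponseCurve:
    def test_constant_jacobian_gives_flat_curve(self):
        A = np.array([[-1.0, 0.7], [0.3, -2.0]])
        system = fc.make_linear(A)
        states = np.random.default_rng(0).uniform(-1, 1, size=(400, 2))
        curve = fc.response_curve(system, states, element=(0, 1), n_bins=8)
        ok = curve.valid()
        assert np.allclose(curve.weighted_mean_jacobian[ok], 0.7, atol=1e-12)

    def test_hill_derivative_peak_location(self):
        """The activating Hill derivative peaks at x = K ((n-1)/(n+1))^(1/n)
        (for K expressed in units of x^n, at (K (n-1)/(n+1))^(1/n))."""
        A, K, n = 2.0, 1.0, 4.0
        x = np.linspace(1e-3, 3, 4000)
        d = fc.hill_derivative(x, A, K, n)
        x_peak_expected = (K * (n - 1) / (n + 1)) ** (1 / n)
        assert x[np.argmax(d)] == pytest.approx(x_peak_expected, rel=1e-2)
        assert np.all(d >= 0)

    def test_inhibitory_element_negative_across_bins(self, hill_system, cycle_states):
        curve = fc.response_curve(hill_system, cycle_states, element=(0, 1), n_bins=10)
        ok = curve.valid()
        assert np.all(curve.weighted_mean_jacobian[ok] <= 0)


class TestFitHill:
    @staticmethod
    def curve_from_params(A, K, n, n_bins=20, noise=0.0, seed=0, x_max=3.0):
        rng = np.random.default_rng(seed)
        x = np.linspace(0.05, x_max, n_bins)
        y = fc.hill_derivative(x, A, K, n)
        if noise:
            y = y + noise * np.abs(y).max() * rng.standard_normal(n_bins)
        return fc.ResponseCurve(x, y, np.ones(n_bins), element=(1, 0))

    def test_noiseless_recovery_within_one_percent(self):
        curve = self.curve_from_params(2.0, 1.0, 4.0)
        fit = fc.fit_hill(curve, "activating")
        assert fit.converged
        assert fit.A == pytest.approx(2.0, rel=0.01)
        assert fit.K == pytest.approx(1.0, rel=0.01)
        assert fit.n == pytest.approx(4.0, rel=0.01)

    def test_noisy_recovery_within_ten_percent_median(self):
        errs = []
        for seed in range(20):
            curve = self.curve_from_params(2.0, 1.0, 4.0, noise=0.05, seed=seed)
            fit = fc.fit_hill(curve, "activating", seed=seed)
            errs.append([abs(fit.A - 2) / 2, abs(fit.K - 1), abs(fit.n - 4) / 4])
        med = np.median(np.array(errs), axis=0)
        assert np.all(med < 0.10)

    def test_all_zero_curve_flagged(self):
        curve = fc.ResponseCurve(np.linspace(0.1, 2, 10), np.zeros(10),
                                 np.ones(10), element=(0, 0))
        fit = fc.fit_hill(curve, "activating")
        assert not fit.converged and fit.A is None

    def test_kinetic_curve_boundary_values(self):
        params = {"A": 2.0, "K": 1.0, "n": 4.0}
        x_half = params["K"] ** (1 / params["n"])
        v = fc.simulate_hill_kinetics(params, np.array([x_half]), "activating")
        assert v[0] == pytest.approx(params["A"] / 2)
        v0 = fc.simulate_hill_kinetics(params, np.array([0.0]), "inhibitory")
        assert v0[0] == pytest.approx(params["A"])

    def test_kinetic_curve_derivative_consistency(self):
        """d/dx of the integrated activating form equals the fitted response."""
        curve = self.curve_from_params(2.0, 1.0, 4.0, n_bins=40)
        fit = fc.fit_hill(curve, "activating")
        x = np.linspace(0.1, 2.9, 500)
        v = fc.simulate_hill_kinetics(fit, x)
        dv = np.gradient(v, x)
        expected = fc.hill_derivative(x, 2.0, 1.0, 4.0)
        assert np.abs(dv - expected).max() < 0.05 * expected.max()


class TestEndToEndRecovery:
    def test_grn_and_hill_from_sampled_velocities(self, hill_system):
        """Full chain: sampled noisy velocities -> fitted field -> response
        curve -> Hill fit recovers the generating inhibition parameters
        within 25% (median over seeds)."""
        p = fc.DEFAULT_HILL_PARAMS
        errs = []
        for seed in (0, 1, 2):
            samples = fc.sample_velocities(hill_system, 2500, noise_sd=0.05, seed=seed)
            model = fc.fit_vector_field(samples, seed=seed)
            states = samples.positions
            edges = {(e.source, e.target): e for e in fc.infer_grn(model, states)}
            assert edges[("gene_y", "gene_x")].sign == -1
            assert edges[("gene_x", "gene_y")].sign == +1
            curve = fc.response_curve(model, states, element=(0, 1), n_bins=20)
            fit = fc.fit_hill(curve, "inhibitory", seed=seed)
            errs.append([abs(fit.A - p.A2) / p.A2,
                         abs(fit.K - p.K2) / p.K2,
                         abs(fit.n - p.n2) / p.n2])
        med = np.median(np.array(errs), axis=0)
        assert np.all(med < 0.25)
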