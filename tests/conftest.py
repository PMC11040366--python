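import numpy as np
import pytest

import fluxcycle as fc


@pytest.fixture(scope="session")
def hill_system():
    return fc.default_hill_oscillator()


@pytest.fixture(scope="session")
def double_well():
    return fc.make_double_well(barrier=1.0, well_separation=2.0)


@pytest.fixture(scope="session")
def hopf():
    return fc.make_hopf_rotator(omega=1.0, radius=1.0, relaxation=1.0)


@pytest.fixture(scope="session")
def hopf_samples(hopf):
    return fc.sample_velocities(hopf, 600, sampling="uniform", noise_sd=0.05, seed=2)


@pytest.fixture(scope="session")
def hill_samples(hill_system):
    return fc.sample_velocities(hill_system, 1200, noise_sd=0.05, seed=3)


@pytest.fixture(scope="session")
def hill_model(hill_samples):
    return fc.fit_vector_field(hill_samples, seed=0)


def finite_difference_jacobian(drift, pts, eps=1e-5):
    pts = np.atleast_2d(np.asarray(pts, float))
    J = np.empty(pts.shape[:1] + (2, 2))
    for b in range(2):
        dp = pts.copy()
        dm = pts.copy()
        dp[:, b] += eps
        dm[:, b] -= eps
        J[:, :, b] = (np.asarray(drift(dp)) - np.asarray(drift(dm))) / (2 * eps)
    return J
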