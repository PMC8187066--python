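import numpy as np
import pytest

import pasl0 as p


@pytest.fixture(scope="session")
def shepp64():
    return p.generate_shepp_logan(64)


@pytest.fixture(scope="session")
def small_pai_system():
    """A 32-px underdetermined circular-scan system with simulated data."""
    phantom = p.generate_shepp_logan(32)
    grid = p.ImageGrid(32, 30.0)
    geom = p.ScanGeometry(10, 40.0)
    freqs = p.FrequencySampling.random(10, 32, (0.2, 3.0), seed=11)
    model = p.build_measurement_matrix(grid, geom, freqs)
    basis = p.WaveletBasis(32)
    A = p.compose_sensing(model, basis)
    data = p.simulate_pressure(model, phantom)
    return phantom, model, basis, A, data


def random_sparse_instance(rng, n=64, m=32, k=4):
    """Gaussian sensing matrix with an exactly k-sparse ground truth."""
    A = rng.standard_normal((m, n))
    theta = np.zeros(n)
    support = rng.choice(n, size=k, replace=False)
    theta[support] = rng.standard_normal(k) + np.sign(rng.standard_normal(k)) * 0.5
    return A, theta, A @ theta
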