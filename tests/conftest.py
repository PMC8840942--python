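import numpy as np
import pytest

import kinetaxis as kx


@pytest.fixture
def domain():
    return kx.Domain2D(nx=32, ny=32)


@pytest.fixture
def small_domain():
    return kx.Domain2D(nx=8, ny=8)


@pytest.fixture
def dirs16():
    return kx.DirectionGrid(16)


@pytest.fixture
def dirs128():
    return kx.DirectionGrid(128)


@pytest.fixture
def psi_uniform():
    return kx.SpeedDistribution.uniform(1.0)


@pytest.fixture
def gaussian_S(domain):
    return kx.gaussian_chemoattractant(domain, 10.0, 0.1, (4.0, 4.0))


@pytest.fixture
def uniform_S(domain):
    return kx.constant_chemoattractant(domain, 1.0)


@pytest.fixture
def stripe_fibers(domain):
    return kx.stripe_alignment_map(domain, 1.8, 3.2, 700.0, np.pi / 2)


@pytest.fixture
def isotropic_fibers(domain):
    return kx.uniform_fibers(domain, 0.0)


def smooth_random_fields(domain, rng):
    """Smooth strictly positive random cue fields for oracle comparisons."""
    X, Y = domain.mesh()
    S_vals = 2.0 + np.sin(2 * np.pi * X / 5 + rng.uniform(0, 2 * np.pi)) \
        * np.cos(2 * np.pi * Y / 5) * rng.uniform(0.3, 0.8)
    S = kx.ScalarCueField(domain, "sampled", {}, values=S_vals)
    k = 1.5 + rng.uniform(0.2, 0.5) * np.sin(2 * np.pi * Y / 5) \
        * np.cos(2 * np.pi * X / 5)
    theta = np.full_like(k, rng.uniform(0, np.pi))
    fib = kx.FiberField(domain, k, theta)
    return fib, S
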