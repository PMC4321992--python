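import numpy as np
import pytest

from painbayes import IntensityGrid, SubjectParams


@pytest.fixture(scope="session")
def grid():
    return IntensityGrid()


@pytest.fixture(scope="session")
def coarse_grid():
    return IntensityGrid(0.0, 100.0, 2.0)


@pytest.fixture
def params():
    """Default subject parameters with a mid-range expectation weight."""
    return SubjectParams(w=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_force_mixture(grid, components, uniform_weight=0.0):
    """Independent density-evaluation oracle for Gaussian-mixture priors.

    ``components`` is a list of (weight, mean, sd); each component is
    evaluated with scipy's pdf at the grid points and renormalized before
    mixing, mirroring the documented discretization convention.
    """
    from scipy.stats import norm

    mass = np.full(grid.n_points, uniform_weight / grid.n_points)
    for weight, mean, sd in components:
        dens = norm.pdf(grid.points, loc=mean, scale=sd)
        mass = mass + weight * dens / dens.sum()
    return mass / mass.sum()
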