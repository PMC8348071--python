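import numpy as np
import pytest

from arrcine import PhantomSpec, truth_stack


@pytest.fixture(scope="session")
def small_phantom() -> PhantomSpec:
    """A reduced-matrix phantom used where full resolution is not at stake."""
    return PhantomSpec(grid=96, endo_radius_d=16.0, epi_radius_d=24.0)


@pytest.fixture(scope="session")
def default_phantom() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_truth(default_phantom):
    return truth_stack(default_phantom, 20)


def _erf_edge_profile(sigma: float, i_min: float = 0.0, i_max: float = 100.0,
                      half_extent_sigmas: float = 8.0, step: float = 0.1):
    """Analytic Gaussian-blurred step edge: I(x) = i_min + range * Phi(x/sigma).

    Closed-form 20-80 rise distance: d = 2 * 0.8416 * sigma = 1.6832 * sigma.
    """
    from scipy.stats import norm

    from arrcine import EdgeProfile

    half = half_extent_sigmas * sigma
    x = np.arange(-half, half + step / 2, step)
    vals = i_min + (i_max - i_min) * norm.cdf(x / sigma)
    return EdgeProfile(positions=x - x[0], intensities=vals)


@pytest.fixture(scope="session")
def erf_edge_profile():
    """Factory for analytic Gaussian-blurred step-edge profiles."""
    return _erf_edge_profile
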