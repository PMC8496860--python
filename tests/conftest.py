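import numpy as np
import pytest

from galvar import (
    SolverConfig,
    SugarGrid,
    default_grid,
    reference_parameters,
    simulate_grid,
)


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def solver_cfg():
    return SolverConfig()


@pytest.fixture(scope="session")
def small_grid():
    """Reduced twofold grid (4 glucose x 6 galactose) for fast sweeps."""
    return SugarGrid(
        glucose_levels=(0.5, 0.125, 0.03125, 0.0),
        galactose_levels=(2.0, 0.5, 0.125, 0.03125, 0.0078125, 0.0),
    )


@pytest.fixture(scope="session")
def ref_profile(ref_params):
    """Reference induction profile over the full 96-condition grid."""
    return simulate_grid(ref_params, default_grid(), SolverConfig())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def full_matrix(ref_params):
    """The complete 216-row perturbation matrix (36 free params x 6 factors)."""
    from galvar import build_matrix

    return build_matrix(ref_params)
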