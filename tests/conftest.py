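import numpy as np
import pytest

from ancmix.model_core import DesignData, MarginalizedParams
from ancmix.synthetic_data import simulate_counts


@pytest.fixture(scope="session")
def binary_design():
    """n=3000 design with an intercept and one balanced binary covariate."""
    rng = np.random.default_rng(42)
    n = 3000
    X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
    return X


@pytest.fixture(scope="session")
def true_binary_params():
    """Data-generating parameters of the two-covariate recovery study."""
    return MarginalizedParams(beta=[1.0, -0.4], alpha=[0.3, -0.2], tau=0.4)


@pytest.fixture(scope="session")
def binary_mixture_data(binary_design, true_binary_params):
    """One simulated dataset from the marginalized mixture at the recovery
    study's parameters."""
    y, latent = simulate_counts(
        binary_design, binary_design, true_binary_params, seed=202
    )
    return DesignData(
        y=y,
        X=binary_design,
        Z=binary_design.copy(),
        x_names=["intercept", "x[1]"],
        z_names=["intercept", "x[1]"],
    )


@pytest.fixture(scope="session")
def binary_fit(binary_mixture_data):
    """One converged marginalized-mixture fit, shared across test modules."""
    from ancmix.estimation import fit_mpoispois
    from ancmix.initialization import starting_values

    b0, a0, tau0, _ = starting_values(binary_mixture_data)
    return fit_mpoispois(
        binary_mixture_data, MarginalizedParams(beta=b0, alpha=a0, tau=tau0)
    )
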