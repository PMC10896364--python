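import numpy as np
import pytest

from electrotaxis import (
    POSTERIOR_MEANS,
    ExperimentDesign,
    ModelParameters,
    generate_traces,
    run_mcmc,
)


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Calibrated posterior-mean parameters used throughout."""
    return POSTERIOR_MEANS


def random_parameter_sets(n: int, seed: int = 0) -> list[ModelParameters]:
    """Well-separated random parameter draws (no near-collisions of rates)."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        gamma = rng.uniform(0.3, 5.0)
        alpha = rng.uniform(10.0, 500.0)
        tau_e = rng.uniform(0.05, 0.8)
        tau_a = rng.uniform(1.2, 8.0)
        rates = np.array([gamma, 1.0 / tau_e, 1.0 / tau_a])
        gaps = np.abs(np.subtract.outer(rates, rates))
        if np.min(gaps[np.triu_indices(3, 1)]) < 0.05:
            continue
        out.append(ModelParameters(gamma, alpha, tau_e, tau_a))
    return out


@pytest.fixture(scope="session")
def small_posterior(params):
    """A converged posterior from one reduced synthetic-data MCMC run,
    shared across tests that only need plausible correlated draws."""
    traces = generate_traces(params, ExperimentDesign(seed=2024))
    return run_mcmc(traces, params.gamma, n_chains=4, n_iterations=3000,
                    seed=11, check_every=1500)
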