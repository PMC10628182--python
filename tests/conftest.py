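import numpy as np
import pytest

from driftring import (
    GenerativeModelSpec,
    SessionConfig,
    generate_dataset,
    six_attractor_drift,
)


@pytest.fixture(scope="session")
def six_attractor_table():
    """Moderate synthetic dataset from the default six-attractor model."""
    cfg = SessionConfig(n_trials=6000, seed=101)
    return generate_dataset(cfg, GenerativeModelSpec())


@pytest.fixture(scope="session")
def ddm_table():
    """Synthetic data restricted to the modeled conditions (true delays only)."""
    w = np.zeros(9)
    w[[1, 2, 7, 8]] = 1.0  # load1 / load2-retro at short and long delays
    cfg = SessionConfig(n_trials=6000, trial_type_weights=w, seed=202)
    return generate_dataset(cfg, GenerativeModelSpec())


@pytest.fixture(scope="session")
def drift_minus_sin():
    """Basis projection of G(theta) = -sin(theta): one attractor at 0."""
    from driftring.fokker_planck import project_on_basis

    return project_on_basis(lambda th: -np.sin(th))


@pytest.fixture(scope="session")
def drift_six():
    return six_attractor_drift()
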