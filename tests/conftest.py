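import numpy as np
import pytest

import soilsem as ss


@pytest.fixture(scope="session")
def default_design():
    return ss.default_design()


@pytest.fixture(scope="session")
def default_profile():
    """Default synthetic ProfileTable (seed 1), shared read-only."""
    return ss.emit_profile_table(seed=1)


@pytest.fixture(scope="session")
def default_manifests():
    """Default synthetic ManifestTable (seed 1), shared read-only."""
    return ss.simulate_manifests(seed=1)


@pytest.fixture(scope="session")
def quick_fit(default_manifests):
    """A short but converged fit of the default model, shared by tests
    that only need plausible posterior draws."""
    cfg = ss.McmcConfig(chains=2, iterations=7000, burn_in=3000, thin=2,
                        base_seed=42)
    return ss.sample_posterior(default_manifests, ss.SemSpec.default(), cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
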