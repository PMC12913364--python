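import warnings

import numpy as np
import pytest

from gutbrain.synthetic import SyntheticConfig, simulate

warnings.filterwarnings("ignore", message="no power reached")


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic cohort shared across read-only tests."""
    return simulate(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down configuration for tests that resimulate repeatedly."""
    return SyntheticConfig(
        seed=0,
        n_taxa=60,
        n_metabolites=150,
        n_variants=60,
        depth=5000,
        module_spec=(),
        n_up_metabolites=5,
        n_down_metabolites=10,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
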