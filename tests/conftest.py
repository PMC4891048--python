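import numpy as np
import pytest

import drugsig as ds


@pytest.fixture(scope="session")
def small_panel():
    """A compact panel with planted truth, shared across read-only tests."""
    return ds.simulate_panel(
        n_drugs=10, n_cells=60, n_genes=200, k_true=3, n_types=2,
        driver_count=8, resist_count=5, outlier_count=3,
        missing_fraction=0.1, noise_sd=0.1, seed=11, n_bits=64, resist_drugs=1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
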