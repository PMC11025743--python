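import numpy as np
import pytest

import silcal as sc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def library():
    return sc.default_library(seed=1)


@pytest.fixture(scope="session")
def noiseless_dataset(library):
    """50 samples with no noise, scatter or baseline: exact linear ground truth."""
    recipe = sc.default_recipe(
        n_samples=50, seed=3, noise_sd=0.0,
        gain_range=(1.0, 1.0), offset_range=(0.0, 0.0),
        baseline_slope_range=(0.0, 0.0),
    )
    return sc.gen_spectra_dataset(library, recipe)


@pytest.fixture(scope="session")
def noisy_dataset(library):
    """Default study conditions at n=60 (noise + scatter + baseline)."""
    recipe = sc.default_recipe(n_samples=60, seed=7)
    return sc.gen_spectra_dataset(library, recipe)
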