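import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import specsieve as sv

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_seeds():
    """Simulated seed library for the separable 5-class toy (reduced grid)."""
    return sv.simulate_seed_library(
        sv.toy_band_library(), replicates_per_class=12, rng_seed=0,
        grid=sv.reduced_grid(),
    )


@pytest.fixture(scope="session")
def toy_split(toy_seeds):
    return sv.split_halves(toy_seeds, rng_seed=1)


@pytest.fixture(scope="session")
def toy_model(toy_split):
    """Dictionary learned on synthetic clean + membrane spectra of the toy."""
    train, _ = toy_split
    clean = sv.synthesize_clean_set(train, n_per_class=10, rng_seed=2)
    membrane = sv.synthesize_membrane_set(train, n=20, rng_seed=3)
    lm = sv.build_learning_matrix(membrane, clean, J=20, L=10)
    return sv.learn_dictionary(lm, K=30, rng_seed=4)


@pytest.fixture(scope="session")
def toy_heldout(toy_split):
    _, heldout = toy_split
    return heldout


@pytest.fixture(scope="session")
def toy_references(toy_heldout):
    return sv.synthesize_clean_set(toy_heldout, n_per_class=10, rng_seed=5)


def random_normalized_spectrum(rng, n=32, label=None):
    grid = np.linspace(650.0, 650.0 + 2.0 * (n - 1), n)
    vals = rng.random(n)
    vals = (vals - vals.min()) / (vals.max() - vals.min())
    return sv.Spectrum(grid, vals, label)
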