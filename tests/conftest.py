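import numpy as np
import pytest

from fmralert.synthetic import (
    generate_latent_arousal,
    make_true_template,
    make_world,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def latent():
    """A default-bandwidth latent arousal series on a short scan."""
    return generate_latent_arousal(n_volumes=200, tr=2.1, cutoff_hz=0.02,
                                   amplitude=1.0, seed=42)


@pytest.fixture(scope="session")
def small_template():
    return make_true_template((10, 10, 8))


@pytest.fixture(scope="session")
def tiny_world():
    """A reduced-size synthetic session for unit tests."""
    return make_world(n_volumes=120, tr=2.1, shape=(10, 10, 8),
                      eeg_fs=125.0, with_physio=True, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """Four subjects at reduced scan length, enough for split evaluation."""
    return simulate_cohort(n_subjects=4, seed=5, n_volumes=150,
                           shape=(10, 10, 8), eeg_fs=125.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
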