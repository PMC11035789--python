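"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from eegssl import SynthConfig, generate_dataset, segment


def pytest_configure(config):
    config.addinivalue_line("filterwarnings",
                            "ignore:band gamma.*:UserWarning")


@pytest.fixture(scope="session")
def structured_dataset():
    """Default study conditions: 12 labelled trials, 3 classes, slow
    band-amplitude drift (temporal continuity holds)."""
    return generate_dataset(SynthConfig(seed=3))


@pytest.fixture(scope="session")
def structured_windows(structured_dataset):
    return [segment(r) for r in structured_dataset]


@pytest.fixture(scope="session")
def small_dataset():
    """Cheap dataset for fast unit tests: 6 short trials, 4 channels."""
    cfg = SynthConfig(n_subjects=1, n_trials_per_subject=6,
                      trial_duration_s=90.0, n_channels=4, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_windows(small_dataset):
    return [segment(r) for r in small_dataset]


@pytest.fixture(scope="session")
def whitenoise_windows():
    """Structure-free control: stationary white noise, no class or
    envelope structure — nothing is predictable across windows."""
    cfg = SynthConfig(seed=11, band_power_profiles=np.zeros((3, 5)),
                      noise_sd=1.0, envelope_log_sd=0.0,
                      noise_color="white")
    return [segment(r) for r in generate_dataset(cfg)]
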