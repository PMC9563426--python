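import warnings

import numpy as np
import pytest

import somnospec as sp

warnings.filterwarnings("ignore", message="no REM epochs")


@pytest.fixture(scope="session")
def short_config() -> sp.SimConfig:
    """A 10-minute recording at 400 Hz with time-compressed bouts."""
    from somnospec.experiments import scaled_config

    return scaled_config(600, 400.0, 0.25)


@pytest.fixture(scope="session")
def short_recording(short_config):
    """One synthesized wild-type animal with its ground truth."""
    truth = sp.sample_hypnogram(short_config, 424242)
    rec = sp.synthesize_signals(truth, short_config, 424243)
    return rec, truth


@pytest.fixture(scope="session")
def short_spectra(short_recording):
    rec, _ = short_recording
    return sp.compute_epoch_spectra(rec)


@pytest.fixture(scope="session")
def normalized_table(short_spectra):
    table = sp.integrate_bands(short_spectra)
    table = sp.flag_outliers(table)
    return sp.normalize_power(table)


def random_hypnogram(rng: np.random.Generator, n: int) -> sp.Hypnogram:
    labels = rng.choice(["WAKE", "NREM", "REM"], size=n)
    return sp.Hypnogram(labels)
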