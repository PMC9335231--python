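"""Shared fixtures: one default synthetic session, computed once per run."""

import numpy as np
import pytest

from boldosc import (SimConfig, simulate_bold, simulate_eeg,
                     simulate_hypnogram, simulate_physio, sliding_spectrogram,
                     window_stages)
from boldosc.spectra import detect_region_bands
from boldosc.synth import draw_region_params


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def hypnogram(default_config):
    return simulate_hypnogram(default_config)


@pytest.fixture(scope="session")
def region_params(default_config):
    return draw_region_params(default_config)


@pytest.fixture(scope="session")
def bold(default_config, hypnogram, region_params):
    return simulate_bold(default_config, hypnogram, region_params)


@pytest.fixture(scope="session")
def eeg_session(default_config, hypnogram):
    eeg, fs, truth, envelopes = simulate_eeg(default_config, hypnogram)
    return {"eeg": eeg, "fs": fs, "truth": truth, "envelopes": envelopes}


@pytest.fixture(scope="session")
def physio_session(default_config):
    return simulate_physio(default_config)


@pytest.fixture(scope="session")
def spectrogram_session(bold):
    return sliding_spectrogram(bold)


@pytest.fixture(scope="session")
def stage_labels(hypnogram, spectrogram_session):
    return window_stages(hypnogram, spectrogram_session)


@pytest.fixture(scope="session")
def region_bands(spectrogram_session, stage_labels):
    return detect_region_bands(spectrogram_session, stage_labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
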