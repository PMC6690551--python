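"""Shared fixtures: synthetic songs generated once per session."""

import dataclasses

import pytest

from pulsesong import AnalysisConfig, generate_song, genotype_preset
from pulsesong.pipeline import analyze_song
from pulsesong.pulse_analysis import extract_events
from pulsesong.spectral_analysis import bandpass_filter


@pytest.fixture(scope="session")
def wildtype_clean():
    """Noise-free wild-type-like song, 30 s, ~540 pulses."""
    params = dataclasses.replace(genotype_preset("wildtype"), noise_sd=0.0)
    recording, truth = generate_song(params, 30.0, seed=11)
    return params, recording, truth


@pytest.fixture(scope="session")
def cro_clean():
    """Noise-free cro-like song, 30 s, ~490 pulses."""
    params = dataclasses.replace(genotype_preset("cro"), noise_sd=0.0)
    recording, truth = generate_song(params, 30.0, seed=11)
    return params, recording, truth


@pytest.fixture(scope="session")
def cro_noisy():
    """cro-like song at amplitude SNR 10, 45 s, >=500 pulses."""
    params = genotype_preset("cro")
    recording, truth = generate_song(params, 45.0, seed=11)
    return params, recording, truth


@pytest.fixture(scope="session")
def wildtype_noisy():
    """Wild-type-like song at amplitude SNR 10, 60 s, >=1000 pulses."""
    params = genotype_preset("wildtype")
    recording, truth = generate_song(params, 60.0, seed=11)
    return params, recording, truth


@pytest.fixture(scope="session")
def cro_clean_analyzed(cro_clean):
    _, recording, truth = cro_clean
    return analyze_song(recording), truth


@pytest.fixture(scope="session")
def wildtype_clean_events(wildtype_clean):
    """Band-passed recording plus extracted events for the clean wild-type song."""
    _, recording, truth = wildtype_clean
    config = AnalysisConfig()
    filtered = bandpass_filter(recording)
    return filtered, extract_events(filtered, config), truth
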