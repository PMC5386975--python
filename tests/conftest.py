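"""Shared fixtures: one small and one full-size synthetic session."""

import pytest

import microsep as m

SMALL_SEED = 1234
FULL_SEED = 12345


@pytest.fixture(scope="session")
def geometry():
    return m.default_geometry()


@pytest.fixture(scope="session")
def small_cfg():
    """A 30-trials-per-condition run for fast unit tests."""
    return m.SynthConfig(seed=SMALL_SEED, n_trials_per_condition=30)


@pytest.fixture(scope="session")
def small_recording(small_cfg, geometry):
    return m.generate_recording(small_cfg, geometry)


@pytest.fixture(scope="session")
def small_epochs(small_recording):
    """CAR + baseline-corrected epochs with a 600-sample visualization span."""
    rec = m.common_average_reference(small_recording)
    return m.extract_epochs(rec, span=(m.BASELINE_LEN, 600))


@pytest.fixture(scope="session")
def small_decode_epochs(small_epochs):
    """Balanced 30-per-condition decode set cut to the full-length window."""
    dec = m.select_decode_trials(small_epochs, n_per_condition=30)
    return dec


@pytest.fixture(scope="session")
def default_cfg():
    """The default study conditions (200 trials/condition, 18 uV rest noise)."""
    return m.SynthConfig(seed=FULL_SEED)


@pytest.fixture(scope="session")
def default_epochs(default_cfg, geometry):
    """Preprocessed full-size dataset shared by the acceptance tests."""
    rec = m.generate_recording(default_cfg, geometry)
    rec = m.common_average_reference(rec, copy=False)
    return m.extract_epochs(rec, span=(m.BASELINE_LEN, 600))


@pytest.fixture(scope="session")
def default_decode_features(default_epochs):
    """Z-scored full-length 94-channel features of the 1,000 decode trials."""
    dec = m.select_decode_trials(default_epochs)
    return m.build_features(dec)
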