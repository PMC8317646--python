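import numpy as np
import pytest

import eegstress as es


@pytest.fixture(scope="session")
def schedule():
    return es.build_default_schedule()


@pytest.fixture(scope="session")
def default_session(schedule):
    """One synthetic session under the default (noisy) study conditions."""
    cfg = es.SynthConfig(seed=1)
    recordings, truth = es.simulate_session(schedule, cfg)
    return cfg, recordings, truth


@pytest.fixture(scope="session")
def preprocessed(default_session):
    _, recordings, _ = default_session
    return {r.phase: es.preprocess_recording(r) for r in recordings}


@pytest.fixture(scope="session")
def session_features(schedule, default_session):
    _, recordings, _ = default_session
    return es.extract_session_features(recordings, schedule, es.RunConfig())


@pytest.fixture(scope="session")
def quiet_session(schedule):
    """Line noise and artifacts off: band powers readable straight off."""
    cfg = es.SynthConfig(seed=2, line_noise_uv=0.0, artifact_prob=0.0)
    recordings, truth = es.simulate_session(schedule, cfg)
    return cfg, recordings, truth


@pytest.fixture
def make_recording():
    """Factory for probe recordings (sinusoids, noise) on 4 channels."""

    def _make(signal_1d, fs=256.0, phase="mist_test", nominal_s=None, channels=("Fp1", "Fp2", "F5", "F6")):
        x = np.asarray(signal_1d, dtype=float)
        data = np.tile(x, (len(channels), 1))
        if nominal_s is None:
            nominal_s = len(x) / fs
        return es.Recording(
            data=data,
            sampling_rate_hz=fs,
            channels=channels,
            phase=phase,
            nominal_duration_s=nominal_s,
        )

    return _make


@pytest.fixture(scope="session")
def default_surveys(schedule, default_session):
    _, _, truth = default_session
    from eegstress.pipeline import surveys_from_truth

    return surveys_from_truth(truth, schedule)
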