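import numpy as np
import pytest

from rettnet import (CohortDesign, EpochedEEG, FeatureTable,
                     PreprocessConfig, generate_coherence_features,
                     load_reference_cohort, preprocess, response_study_design)
from rettnet.io import EEGRecording


@pytest.fixture(scope="session")
def reference_cohort():
    """The bundled 18-patient demographic table."""
    return load_reference_cohort()


@pytest.fixture(scope="session")
def study_features():
    """Feature-level responder cohort under the emulated study conditions
    (5 responders / 4 nonresponders, +0.3 O1-O2 and +0.15 fronto-occipital
    baseline coherence in responders, feature noise SD 0.05)."""
    feats, clin = generate_coherence_features(response_study_design(seed=0),
                                              noise_sd=0.05)
    return FeatureTable(feats), clin


@pytest.fixture
def white_epochs():
    """Independent white-noise epochs (no shared signal) for estimator
    floor checks."""
    rng = np.random.default_rng(123)
    return EpochedEEG(epochs=rng.normal(size=(30, 8, 256)), fs=128.0)


def sine_recording(freq=10.0, fs=128.0, duration=60.0, amp=1.0,
                   n_channels=8, phases=None):
    """Pure sinusoid on every channel (optionally phase-shifted)."""
    from rettnet.montage import MONTAGE
    t = np.arange(int(duration * fs)) / fs
    phases = np.zeros(n_channels) if phases is None else np.asarray(phases)
    data = amp * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
    return EEGRecording(data=data, fs=fs, montage=MONTAGE[:n_channels])


@pytest.fixture
def clean_epochs():
    """Epoched band-limited synthetic recording with no artifacts."""
    from rettnet import SharedSource, SimConfig, generate_recording
    cfg = SimConfig(sources=[SharedSource(band=(6.0, 20.0),
                                          weights=np.ones(8))],
                    fs=128.0, duration=60.0, noise_power=0.5)
    rec = generate_recording(cfg, 7)
    return preprocess(rec, PreprocessConfig(artifact_threshold=1e9))
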