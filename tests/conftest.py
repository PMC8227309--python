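import numpy as np
import pytest

import eegscore as es
from eegscore.spectral import attach_scores


TRUE_FEATURES = ("C3_alpha/theta", "FP1_delta")


def make_feature_matrix(spec: es.CohortSpec):
    """Generate a cohort and return its feature matrix with scores attached."""
    recordings = es.generate_cohort_recordings(spec)
    fm = es.build_feature_matrix(recordings)
    scores = es.generate_scores(spec, fm)
    return attach_scores(fm, scores), recordings, scores


@pytest.fixture(scope="session")
def full_cohort():
    """Default 10 text + 10 video cohort (score noise SD 5)."""
    spec = es.CohortSpec(seed=42)
    fm, recordings, scores = make_feature_matrix(spec)
    return {"spec": spec, "fm": fm, "recordings": recordings, "scores": scores}


@pytest.fixture(scope="session")
def full_fm(full_cohort):
    return full_cohort["fm"]


@pytest.fixture(scope="session")
def noiseless_fm():
    """Same cohort geometry with a deterministic score link (noise SD 0)."""
    spec = es.CohortSpec(seed=43, score_model=es.ScoreModel(noise_sd=0.0))
    fm, _, _ = make_feature_matrix(spec)
    return fm


@pytest.fixture(scope="session")
def one_recording():
    spec = es.CohortSpec(seed=3, n_text=1, n_video=1)
    return es.generate_recording(spec, 0, "text")


@pytest.fixture(scope="session")
def filtered_recording(one_recording):
    return es.bandpass(one_recording)


def sinusoid_recording(freq: float, amplitude: float = 10.0, fs: float = 256.0,
                       duration_s: float = 30.0, group: str = "text"):
    """A bare recording whose every channel is one pure sinusoid."""
    t = np.arange(int(duration_s * fs)) / fs
    data = np.tile(amplitude * np.sin(2 * np.pi * freq * t), (len(es.CHANNELS), 1))
    return es.EEGRecording(
        data=data, fs=fs, annotations=[], participant_id="sine", group=group
    )
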