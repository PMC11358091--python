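import numpy as np
import pytest

from ecognet import SynthConfig, PreprocessParams
from ecognet.layout import default_layout
from ecognet.preprocess import preprocess_recording
from ecognet.synth import gen_subject, scaled_config


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def tiny_config():
    """Two subjects, one day, three epochs per condition."""
    return scaled_config(SynthConfig(seed=42), n_subjects=2, n_days=1, epochs_per_day=3)


@pytest.fixture(scope="session")
def tiny_cohort_processed(tiny_config):
    """Preprocessed epochs of the tiny cohort, keyed by (subject, condition)."""
    out = {}
    for i in range(tiny_config.n_subjects):
        for condition in ("normal", "scz"):
            raw = gen_subject(tiny_config, condition, i)
            out[(raw[0].subject_id, condition)] = [
                preprocess_recording(r, PreprocessParams()) for r in raw
            ]
    return out


@pytest.fixture(scope="session")
def processed_epochs(tiny_cohort_processed):
    return [r for recs in tiny_cohort_processed.values() for r in recs]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
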