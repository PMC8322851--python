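import numpy as np
import pytest

import myoface as mf


@pytest.fixture(scope="session")
def profile():
    return mf.default_crosstalk_profile()


@pytest.fixture(scope="session")
def small_recordings(profile):
    """Four synthetic acquisition rounds (fixed seed)."""
    cfg = mf.ProtocolConfig(n_rounds=4, seed=7)
    return mf.generate_dataset(profile, cfg)


@pytest.fixture(scope="session")
def small_windows(small_recordings):
    """Preprocessed, segmented windows of the four rounds (576 windows)."""
    wins = []
    for i, rec in enumerate(small_recordings):
        wins.extend(mf.segment_recording(mf.preprocess(rec), round_index=i))
    return wins


@pytest.fixture(scope="session")
def ef_matrix(small_windows):
    return mf.assemble(small_windows, "EF")


@pytest.fixture(scope="session")
def trained_gbc(ef_matrix):
    return mf.train_classifier(ef_matrix, "GBC", seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
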