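import numpy as np
import pytest

from mindreach import blda, preprocess, synth


@pytest.fixture(scope="session")
def timing():
    return synth.SessionTiming()


@pytest.fixture(scope="session")
def trained_model(timing):
    """A discriminant fit on a small high-SNR synthetic session, shared by
    decoder-level tests."""
    spec = synth.SyntheticSessionSpec(
        n_trials=10, rounds_per_trial=10, p300_amplitude=5.0, noise_sd=2.0, seed=11
    )
    rec = synth.synthesize_recording(spec, timing)
    X, t = blda.build_training_set(preprocess.preprocess_session(rec, timing))
    return blda.fit(X, t)


@pytest.fixture(scope="session")
def test_recording(timing):
    """A small high-SNR test session (8 rounds per trial, the online cap)."""
    spec = synth.SyntheticSessionSpec(
        n_trials=10, rounds_per_trial=8, p300_amplitude=5.0, noise_sd=2.0, seed=22
    )
    return synth.synthesize_recording(spec, timing)


def make_features(values, key_id=1, trial=0, rnd=0, is_target=None):
    """FeatureVector helper for hand-built decoder inputs."""
    return preprocess.FeatureVector(
        x=np.asarray(values, dtype=float), key_id=key_id,
        round_index=rnd, trial_index=trial, is_target=is_target,
    )
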