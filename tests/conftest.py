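import numpy as np
import pytest

from rhythmdecode.cnn import MinMaxSymmetric
from rhythmdecode.preprocess import preprocess_subject
from rhythmdecode.simulate import GeneratorConfig, generate_subject


def make_toy_epochs(n=160, amplitude=0.8, seed=1):
    """Separable 60x200 toy epochs: class-specific space-time patterns in noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(200) / 100.0
    ch = np.arange(60)[:, None]
    pat0 = np.sin(2 * np.pi * 10 * t) * np.exp(-(((ch - 20) / 10.0) ** 2))
    pat1 = np.sin(2 * np.pi * 3 * t) * np.exp(-(((ch - 40) / 10.0) ** 2))
    y = rng.integers(0, 2, n)
    X = np.where(y[:, None, None] == 1, pat1, pat0) * amplitude
    X = X + rng.standard_normal((n, 60, 200))
    return X, y


@pytest.fixture(scope="session")
def toy_epochs():
    return make_toy_epochs()


@pytest.fixture(scope="session")
def toy_epochs_normalized(toy_epochs):
    X, y = toy_epochs
    return MinMaxSymmetric().fit_transform(X), y


@pytest.fixture(scope="session")
def high_snr_subject_epochs():
    """Preprocessed epochs of one strong-response, artifact-free subject."""
    cfg = GeneratorConfig(
        n_repetitions=400,
        snr=2.0,
        subject_snr_spread=0.0,
        artifact_channel_count=0,
        artifact_transient_rate=0.0,
        rng_seed=11,
    )
    subject = generate_subject(cfg, np.random.SeedSequence(42))
    epochs, _ = preprocess_subject(subject.recordings)
    return epochs
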