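import numpy as np
import pytest

from evobci.containers import EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def epochset_factory(rng):
    """Random labeled EpochSets with consistent geometry."""

    def make(n_epochs=10, n_channels=3, fs=250.0, window=(0.1, 0.3),
             n_classes=2, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        n_samp = int(round(sum(window) * fs))
        return EpochSet(
            epochs=r.normal(0.0, 5.0, size=(n_epochs, n_channels, n_samp)),
            labels=r.integers(0, n_classes, size=n_epochs),
            class_names=[f"C{i}" for i in range(n_classes)],
            fs=fs,
            window=window,
            channel_names=[f"ch{i}" for i in range(n_channels)],
        )

    return make


@pytest.fixture(scope="session")
def separable_epochs():
    """High-SNR 2-class synthetic epochs (easily decodable)."""
    from evobci.synthetic import SynthConfig, synth_epochs

    return synth_epochs(SynthConfig(effect_amplitude=20.0, noise_sd=2.0,
                                    n_epochs_per_class=40, seed=77))
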