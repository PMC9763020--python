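import numpy as np
import pytest

from eegstress.pipeline import default_wavelet_config
from eegstress.synthgen import SynthConfig
from eegstress.wavelet import WaveletConfig


@pytest.fixture(scope="session")
def small_synth_config() -> SynthConfig:
    """Tiny DEAP-shaped dataset: full sample length (needed for 8-level
    decomposition), few participants/trials/channels."""
    return SynthConfig(
        n_participants=2, n_trials=10, n_channels=12, n_samples=8064, seed=11
    )


@pytest.fixture(scope="session")
def rate_wavelet_config() -> WaveletConfig:
    return default_wavelet_config()


@pytest.fixture(scope="session")
def small_matrix(small_synth_config, rate_wavelet_config):
    """Feature matrix for the tiny synthetic dataset (built once)."""
    from eegstress.features import build_feature_matrix
    from eegstress.synthgen import iter_recordings

    return build_feature_matrix(
        iter_recordings(small_synth_config),
        wavelet_config=rate_wavelet_config,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
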