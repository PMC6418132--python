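import numpy as np
import pytest

from ecgcodec import SynthConfig, generate_synthetic_ecg
from ecgcodec.bench import synthetic_corpus


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def short_ecg():
    """~50 s clean-ish synthetic record, fast to transform."""
    cfg = SynthConfig(n_beats=60, noise_sd=3.0, seed=7, record_id="short")
    return generate_synthetic_ecg(cfg)


@pytest.fixture(scope="session")
def full_length_ecg():
    """One 650000-sample record matching the benchmark database geometry."""
    return synthetic_corpus(1, n_samples=650_000, seed=11)[0]
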