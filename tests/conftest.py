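import numpy as np
import pytest

from mcheart.synthetic_pcg import SynthSpec, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_recording():
    """Murmur-free 10 s recording at 60 bpm with no background noise."""
    return generate_recording(
        SynthSpec(heart_rate_bpm=60.0, n_seconds=10.0, murmur="none",
                  snr_db=None, seed=7)
    )


@pytest.fixture(scope="session")
def murmur_pair():
    """Matched (absent, systolic-murmur) recordings sharing seed and rhythm."""
    absent = generate_recording(SynthSpec(seed=42, murmur="none"))
    present = generate_recording(SynthSpec(seed=42, murmur="systolic"))
    return absent, present
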