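import numpy as np
import pytest

from eegvit.synth import SubjectProfile, default_bands, generate_recording


@pytest.fixture
def alpha_profile():
    """Single narrow alpha component, no noise — spectrally checkable."""
    return SubjectProfile(
        "alpha-only", 0,
        [b for b in default_bands(alpha=1.0) if b.amplitude > 0],
    )


@pytest.fixture
def small_recording():
    """12 s mixed-band recording for pipeline plumbing tests."""
    profile = SubjectProfile(
        "S-small", 1, default_bands(delta=20, theta=10, alpha=20, beta=5),
        noise_sd=2.0,
    )
    return generate_recording(profile, 12.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
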