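import numpy as np
import pytest

from taumod import CouplingSpec, Recording, extract_band_pair, generate_channel_signal


@pytest.fixture(scope="session")
def coupled_components():
    """90 s single channel with strong 1 Hz peak-max coupling (depth 0.8)."""
    return generate_channel_signal(
        CouplingSpec(depth=0.8, mod_freq_hz=1.0),
        duration_s=90.0,
        fs_hz=1000.0,
        seed=42,
        return_components=True,
    )


@pytest.fixture(scope="session")
def coupled_band_pair(coupled_components):
    rec = Recording(samples=coupled_components.signal[np.newaxis, :], fs_hz=1000.0)
    return extract_band_pair(rec)
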