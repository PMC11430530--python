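import numpy as np
import pytest
from hypothesis import HealthCheck, settings

# numba-jitted paths are slow on first call; no deadlines, fixed derandomized runs
settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_null_recording():
    """One 8-channel, 120-s null-preset recording, shared across tests."""
    from alphadyn import null_design, simulate_subject

    return simulate_subject(
        null_design(n_channels=8, duration=120.0), "s00", "high", "pre", 0, 0
    )


@pytest.fixture(scope="session")
def parameterized_null(small_null_recording):
    from alphadyn import parameterize_recording

    return parameterize_recording(small_null_recording)


def planted_spectrum(freqs, offset, exponent, peaks):
    """Noiseless model spectrum: aperiodic plus Gaussian peaks."""
    logp = offset - exponent * np.log10(freqs)
    for c, a, w in peaks:
        logp = logp + a * np.exp(-((freqs - c) ** 2) / (2 * w**2))
    return logp
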