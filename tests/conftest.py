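import numpy as np
import pytest
from scipy import signal as sps

import neurosync as ns


@pytest.fixture
def small_cohort():
    """10 subjects sharing a stimulus-locked component, one channel."""
    spec = ns.SharedResponseSpec(
        n_subjects=10, n_timepoints=600, shared_weights=0.8, noise_sd=1.0, seed=42
    )
    return ns.simulate_shared_response(spec)


def hemodynamic_like(n_channels: int, T: int, fs: float, seed: int) -> np.ndarray:
    """Low-pass filtered noise scaled to micromolar-like amplitude."""
    rng = np.random.default_rng(seed)
    sos = sps.butter(3, 0.5 / (fs / 2), btype="low", output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal((n_channels, T)), axis=-1)
    return 1e-6 * x / x.std(axis=-1, keepdims=True)
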