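import numpy as np
import pytest

from ghasort import DetectorConfig, GenConfig, generate_recording


@pytest.fixture(scope="session")
def two_neuron_recording():
    """Moderately clean two-neuron recording shared across suites."""
    cfg = GenConfig(n_neurons=2, snr_db=10.0, duration_s=10.0, seed=1)
    rec, gt = generate_recording(cfg)
    return rec, gt, cfg


@pytest.fixture
def detector_cfg():
    return DetectorConfig()


def insert_template(n, template, peak_positions, noise_sd=0.0, seed=0):
    """Build a single trace with a template inserted at given peak samples."""
    rng = np.random.default_rng(seed)
    trace = rng.standard_normal(n) * noise_sd if noise_sd > 0 else np.zeros(n)
    w = template.waveform
    for k in peak_positions:
        start = k - template.peak_index
        trace[start : start + template.m] += w
    return trace
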