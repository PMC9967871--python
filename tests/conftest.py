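import numpy as np
import pytest

import cardioflux as cf


@pytest.fixture(scope="session")
def paced_ratio():
    """Noiseless 0.5 Hz paced ratiometric trace + ground truth + ratio signal."""
    spec = cf.TransientGenSpec(seed=11, noise_sd=0.0, stim_freq_hz=0.5, n_beats=6)
    trace, truth = cf.gen_transient_trace(spec)
    return trace, truth, cf.compute_ratio(trace)


@pytest.fixture()
def flat_ratio():
    """A constant, unpaced ratio signal."""
    t = np.arange(0, 10, 1 / 400)
    return cf.RatioTrace(time=t, signal=np.full(t.size, 1.3), kind="ratio")
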