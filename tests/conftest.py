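import numpy as np
import pytest

from orcakit import synthetic


@pytest.fixture
def params():
    """Default assay parameters (noise-free)."""
    return synthetic.MechanisticParams()


@pytest.fixture
def noisy_params():
    """Assay parameters with read noise at 2% of the full-turnover amplitude."""
    p = synthetic.MechanisticParams()
    return synthetic.MechanisticParams(sigma=0.02 * p.gain * p.S0, seed=0)


@pytest.fixture
def noiseless_plate(params):
    return synthetic.simulate_plate(params)
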