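import numpy as np
import pytest

from caburst import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def indicator():
    return syn.IndicatorParams()


@pytest.fixture(scope="session")
def quiet_noise():
    """Noise model with every nuisance term switched off."""
    return syn.NoiseParams(
        white_sd_dff=0.0,
        drift_amplitude_dff=0.0,
        background_amplitude_dff=0.0,
    )


@pytest.fixture(scope="session")
def validation_template(indicator):
    """Indicator kernel truncated to the validation window (rise to +3 tau)."""
    kern = syn.indicator_kernel(indicator, 10.0)
    return kern[: int(np.argmax(kern)) + int(np.ceil(3 * indicator.decay_tau_s * 10.0)) + 1]
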