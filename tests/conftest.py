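import numpy as np
import pytest

from shufflespeller import StimulusSet, build_reference_bank
from shufflespeller.calibration import SpellerCalibration, simulate_calibration_trials

#: SNR levels spanning failure to success for the synthetic SSVEP generator:
#: 0 is signal-free, 0.1 sits near the decoding threshold for 2 s queries,
#: 1.0 is a reliably decodable response.
SNR_ZERO = 0.0
SNR_LOW = 0.1
SNR_HIGH = 1.0


@pytest.fixture(scope="session")
def stimulus_set() -> StimulusSet:
    return StimulusSet()


@pytest.fixture(scope="session")
def bank_6s(stimulus_set):
    return build_reference_bank(stimulus_set, 6.0, 256.0)


@pytest.fixture(scope="session")
def high_snr_calibration():
    """Fitted calibration at high SNR (separable), shared across tests."""
    trials = simulate_calibration_trials(snr=SNR_HIGH, seed=1)
    return trials, SpellerCalibration.from_trials(trials).fit()


@pytest.fixture(scope="session")
def noisefree_trials():
    return simulate_calibration_trials(snr=np.inf, seed=2)
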