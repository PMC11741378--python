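import warnings

import pytest

from avdopt import SubjectParams, generate_subject
from avdopt.beats import BeatDetectionWarning


@pytest.fixture(autouse=True)
def _quiet_beat_warnings():
    # dropped-transition / rate warnings are informational in bulk runs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BeatDetectionWarning)
        yield


@pytest.fixture(scope="session")
def noiseless_params():
    return SubjectParams(
        beat_noise_sd_mmHg=0.0,
        resp_amp_cvp_mmHg=0.0,
        resp_amp_abp_mmHg=0.0,
        resp_irregularity=0.0,
        replicates_per_avd=2,
        sample_rate_hz=250.0,
    )


@pytest.fixture(scope="session")
def noiseless_record(noiseless_params):
    return generate_subject(noiseless_params)


@pytest.fixture(scope="session")
def noisy_params():
    # respiratory cycle (0.3 Hz -> 5 beats) deliberately not equal to the
    # 6-beat window, so correction has something to correct
    return SubjectParams(seed=3, resp_freq_hz=0.3, sample_rate_hz=100.0)


@pytest.fixture(scope="session")
def noisy_record(noisy_params):
    return generate_subject(noisy_params)
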