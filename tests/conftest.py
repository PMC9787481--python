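import pytest

from crossmet.synth import default_truth_set
from crossmet.workflow import run_study


@pytest.fixture(scope="session")
def zero_noise_design():
    return default_truth_set(zero_noise=True, seed=1)


@pytest.fixture(scope="session")
def zero_noise_result(zero_noise_design):
    """Full pipeline output on the zero-noise study-faithful fixture."""
    return run_study(zero_noise_design)


@pytest.fixture(scope="session")
def noisy_design():
    return default_truth_set(zero_noise=False, seed=1)
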