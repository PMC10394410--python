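import numpy as np
import pytest

import polrate as pr


@pytest.fixture(scope="session")
def study():
    """One synthetic replicate of the benchmark study (truth + observations)."""
    return pr.generate_study(pr.SimulationStudyConfig(seed=3))


@pytest.fixture(scope="session")
def rate_profile(study):
    truth, _ = study
    return truth.rate_profile


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
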