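import numpy as np
import pytest

from hemedist import cyp1a2_phenacetin_study, run_study


@pytest.fixture(scope="session")
def study_config():
    """The built-in four-enzyme CYP1A2/phenacetin study."""
    return cyp1a2_phenacetin_study()


@pytest.fixture(scope="session")
def study_report(study_config):
    return run_study(study_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
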