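import pytest

from gcea.config import default_config
from gcea.survival import WeibullParams

# Fitted survival-law parameters of the two arms (time in months)
TABLE1 = {
    ("nivo_chemo", "PFS"): WeibullParams(0.047288, 1.186735, label="nivo PFS"),
    ("nivo_chemo", "OS"): WeibullParams(0.021699, 1.267705, label="nivo OS"),
    ("chemo", "PFS"): WeibullParams(0.073625, 1.170952, label="chemo PFS"),
    ("chemo", "OS"): WeibullParams(0.031801, 1.267607, label="chemo OS"),
}

ARM_SIZES = {"nivo_chemo": 473, "chemo": 482}


@pytest.fixture()
def cfg():
    """A fresh copy of the bundled base-case configuration."""
    return default_config()


@pytest.fixture(scope="session")
def base_result():
    """Deterministic base-case run, shared across read-only tests."""
    from gcea.model import run_base_case

    return run_base_case(default_config())
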