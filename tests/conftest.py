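import pytest

from itxdel.params import build_preset
from itxdel.simulator import SolverOptions


@pytest.fixture(scope="session")
def ss1p():
    return build_preset("SS1P")


@pytest.fixture(scope="session")
def lmb2():
    return build_preset("LMB2")


@pytest.fixture(scope="session")
def fast_opts():
    """Coarse but fast solver settings for unit-level simulator tests."""
    return SolverOptions(n_shells=9)


STANDARD_SCHEDULE = [(0.0, 62.0), (48.0, 62.0), (96.0, 62.0)]


@pytest.fixture(scope="session")
def standard_schedule():
    return list(STANDARD_SCHEDULE)
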