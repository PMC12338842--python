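import pytest

from pif4net import SolverOptions, default_parameters, default_registry, make_photoperiod


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def wt(registry):
    return registry["WT"]


@pytest.fixture(scope="session")
def sd_protocol():
    return make_photoperiod(8, 6)


@pytest.fixture(scope="session")
def fast_opts():
    # endpoint observables are insensitive to the sampling density cap
    return SolverOptions(max_step=2.0)
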