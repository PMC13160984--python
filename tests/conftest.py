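import numpy as np
import pytest

from osteonet import ModelParams, builtin_scenario, validate_params


@pytest.fixture()
def params() -> ModelParams:
    return validate_params(ModelParams())


# The long scenario runs are shared session-wide: several acceptance and
# property tests read different aspects of the same trajectories.

@pytest.fixture(scope="session")
def table_params() -> ModelParams:
    return validate_params(ModelParams())


@pytest.fixture(scope="session")
def overload_unload(table_params):
    return builtin_scenario("overload-unload", table_params)


@pytest.fixture(scope="session")
def unload_reload(table_params):
    return builtin_scenario("unload-reload", table_params)


@pytest.fixture(scope="session")
def disuse_stress(table_params):
    return builtin_scenario("disuse-stress", table_params)


@pytest.fixture(scope="session")
def disuse_sed(table_params):
    return builtin_scenario("disuse-sed", table_params)


@pytest.fixture(scope="session")
def gradient_run(table_params):
    return builtin_scenario("gradient", table_params)


def steady_length_at(ts, t_query: float) -> float:
    """Bone length at the sampled record closest to t_query."""
    i = int(np.argmin(np.abs(ts.t - t_query)))
    return float(ts.L[i])
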