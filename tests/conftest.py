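import numpy as np
import pytest

from carebandit import (
    AI_CALL_MARGINALS,
    CHS_PROPORTIONS,
    PopulationSpec,
    build_arm_catalog,
    build_fixture_table,
    build_model_ai_call,
)


@pytest.fixture(scope="session")
def catalog():
    return build_arm_catalog()


@pytest.fixture(scope="session")
def chs_spec():
    return PopulationSpec(mode="marginal-independent", proportions=CHS_PROPORTIONS)


@pytest.fixture(scope="session")
def ai_call_spec():
    # Smaller copula sample than the simulation default; marginals are exact
    # by construction either way.
    return build_fixture_table(AI_CALL_MARGINALS, correlation=0.2, size=20_000, seed=0)


@pytest.fixture(scope="session")
def call_model():
    return build_model_ai_call("call_success")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
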