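import numpy as np
import pytest

from medmr.simulate import scenario_presets, simulate_study, study_ld


@pytest.fixture(scope="session")
def presets():
    return scenario_presets()


@pytest.fixture(scope="session")
def study_mediation(presets):
    return simulate_study(presets["mediation_chain"])


@pytest.fixture(scope="session")
def study_shared(presets):
    return simulate_study(presets["shared_causal"])


@pytest.fixture(scope="session")
def study_linkage(presets):
    return simulate_study(presets["linkage"])


@pytest.fixture(scope="session")
def ld_mediation(study_mediation):
    return study_ld(study_mediation)


@pytest.fixture(scope="session")
def ld_shared(study_shared):
    return study_ld(study_shared)


@pytest.fixture(scope="session")
def ld_linkage(study_linkage):
    return study_ld(study_linkage)
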