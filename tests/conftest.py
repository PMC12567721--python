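import pytest
from hypothesis import HealthCheck, settings

from odorsafe import ChemicalRecord, HeadspaceScenario

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ROSE_OXIDE_SMILES = "CC1CCOC(C1)C=C(C)C"


@pytest.fixture
def rose_oxide() -> ChemicalRecord:
    """The published worked-example chemical: rose oxide, VP 0.657 mmHg at 25 degC."""
    return ChemicalRecord(
        id="rose_oxide", name="rose oxide", cas="16409-43-1",
        smiles=ROSE_OXIDE_SMILES, mw=154.25, vp_mmHg=0.657,
    )


@pytest.fixture
def default_scenario() -> HeadspaceScenario:
    return HeadspaceScenario()
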