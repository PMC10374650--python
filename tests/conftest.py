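import pytest
from hypothesis import settings

import ffdat as F

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")

#: fixture molecules whose united-atom chemistry the bundled alkane/alcohol
#: dataset fully parameterizes (the ether and the alkene type fine but have
#: no matching intermolecular records there)
BUILDABLE = [
    "methane", "ethane", "propane", "n-butane", "n-pentane", "isobutane",
    "methanol", "ethanol", "1,2-ethanediol",
]


@pytest.fixture(scope="session")
def trappe():
    return F.load_bundled("trappe-ua-alkane-alcohol")


@pytest.fixture(scope="session")
def typed():
    """name -> typed SiteGraph for every fixture molecule."""
    return {name: F.type_molecule(F.make_fixture(name)) for name in F.FIXTURE_NAMES}
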