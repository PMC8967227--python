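import pytest
from hypothesis import settings

from pestiscreen import (
    Compound,
    FrameworkConfig,
    FunctionalClass,
    Moa,
    Sensitizer,
    SensitizerPanel,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def config():
    return FrameworkConfig()


@pytest.fixture
def small_compounds():
    """Three hand-written compounds spanning safe/unsafe space."""
    return [
        Compound(id="c1", name="safe-ish", smiles="Oc1ccccc1",
                 e_homo=-7.0, e_lumo=-0.5, log_d=1.0,
                 functional_class=FunctionalClass.herbicide, moa=Moa.UOP),
        Compound(id="c2", name="average", smiles="Nc1ccccc1",
                 e_homo=-6.0, e_lumo=-0.71, log_d=2.87,
                 functional_class=FunctionalClass.insecticide),
        Compound(id="c3", name="lipophilic", smiles="COc1ccccc1",
                 e_homo=-5.5, e_lumo=-1.0, log_d=4.64, moa=Moa.ACE),
    ]


@pytest.fixture
def small_panel():
    return SensitizerPanel([
        Sensitizer(id="s1", cdom_class="aromatic_ketone", e_somo=-5.0),
        Sensitizer(id="s2", cdom_class="quinone", e_somo=-5.5),
        Sensitizer(id="s3", cdom_class="coumarin", e_somo=-6.0),
    ])
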