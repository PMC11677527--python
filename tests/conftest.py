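import numpy as np
import pytest

from spcpbpk import (
    COMPOUND_NAMES,
    DoseRegimen,
    load_compound,
    load_kp,
    load_physiology,
    simulate,
)
from spcpbpk.pbpk_core import EHCParams, ModelConfig


@pytest.fixture(scope="session")
def rat_phys():
    return load_physiology("rat")


@pytest.fixture(scope="session")
def human_phys():
    return load_physiology("human")


@pytest.fixture(scope="session")
def daidzin():
    return load_compound("daidzin")


@pytest.fixture(scope="session")
def methylretusin():
    return load_compound("8-O-methylretusin")


@pytest.fixture(scope="session")
def linear_config():
    """Fully linear configuration: saturable metabolism off, EHC off, dose
    straight into solution (dissolution's saturation term off)."""
    return ModelConfig(michaelis_menten=False,
                       ehc=EHCParams(biliary_fraction=0.0),
                       dissolution=False)


@pytest.fixture(scope="session")
def daidzin_base_run(daidzin, rat_phys):
    """Shared base-dose rat simulation of daidzin (default configuration)."""
    return simulate(daidzin, rat_phys, DoseRegimen(dose=daidzin.dose_base))
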