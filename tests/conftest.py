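import numpy as np
import pandas as pd
import pytest

from oaphys.proteomics import InjectionDesign


def make_design(treatments=("400", "2800"), oysters_per=2, injections_per=3) -> InjectionDesign:
    rows = []
    for t in treatments:
        for o in range(1, oysters_per + 1):
            oyster = f"{t}-{o}"
            for i in range(1, injections_per + 1):
                rows.append({"injection_id": f"{oyster}-inj{i}", "oyster_id": oyster, "treatment": t})
    return InjectionDesign(pd.DataFrame(rows))


@pytest.fixture
def design() -> InjectionDesign:
    return make_design()


@pytest.fixture
def full_design() -> InjectionDesign:
    """The study layout: 4 treatments × 4 oysters × 3 injections = 48."""
    return make_design(("400", "400-MechS", "2800", "2800-MechS"), oysters_per=4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140951)


def psm_frame(rows):
    return pd.DataFrame(rows, columns=["peptide", "protein_id", "probability", "injection_id"])
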