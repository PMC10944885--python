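import numpy as np
import pandas as pd
import pytest

from poppk import PKParameters, final_model, generate_trial
from poppk.model import PopulationModel, ResidualModel


@pytest.fixture(scope="session")
def final():
    return final_model()


@pytest.fixture(scope="session")
def typical_params():
    """Published typical structural parameters."""
    return PKParameters(ka=0.58, tlag=0.35, v=26.21, v2=26.60, cl=1.07, cl2=0.75)


@pytest.fixture(scope="session")
def trial_seed1():
    """One default synthetic trial, shared across tests."""
    return generate_trial(seed=1)


@pytest.fixture(scope="session")
def reduced_model():
    """Covariate-free model with IIV on V and CL only (fast to fit)."""
    return PopulationModel(
        typical={"ka": 0.58, "tlag": 0.35, "v": 26.21, "v2": 26.60,
                 "cl": 1.07, "cl2": 0.75},
        effects=[],
        iiv={"v": 0.049, "cl": 0.067},
        sigma=ResidualModel(prop_sd=0.197),
    )


@pytest.fixture()
def toy_frame():
    """Two subjects, one dose plus three observations each."""
    rows = []
    for sid, dose in (("A", 100.0), ("B", 200.0)):
        rows.append(dict(ID=sid, TIME=0.0, AMT=dose, DV=np.nan, EVID=1,
                         TBIL=10.0, LBW=45.0))
        for t, dv in ((1.0, 800.0), (4.0, 2500.0), (24.0, 1500.0)):
            rows.append(dict(ID=sid, TIME=t, AMT=0.0, DV=dv * dose / 100.0,
                             EVID=0, TBIL=10.0, LBW=45.0))
    return pd.DataFrame(rows)
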