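import numpy as np
import pandas as pd
import pytest

from kinbind import (
    GLOBAL_FIT_RATES,
    FretCalibration,
    RateConstants,
    TitrationDesign,
    generate_titration,
)


@pytest.fixture(scope="session")
def published_rates() -> RateConstants:
    return GLOBAL_FIT_RATES


@pytest.fixture(scope="session")
def acceptor3_calib() -> FretCalibration:
    # donor-quench geometry: total fluorescence falls as complex forms
    return FretCalibration(c=1.0, c_star=0.35, sc=-0.8, baseline=1.0)


@pytest.fixture(scope="session")
def noiseless_series(published_rates, acceptor3_calib):
    """Noiseless titration from the published constants, kinase fixed at 100 nM."""
    design = TitrationDesign(
        seed=0,
        titrant_multiples=(10.0, 25.0, 63.0, 100.0, 160.0, 250.0),
        duration=1.0,
        sample_rate=2000.0,
        noise_sigma=0.0,
    )
    return generate_titration(published_rates, acceptor3_calib, design)


@pytest.fixture(scope="session")
def nmr_truth() -> pd.DataFrame:
    rng = np.random.default_rng(42)
    n = 20
    return pd.DataFrame(
        {
            "residue": np.arange(1, n + 1),
            "noe": rng.uniform(0.3, 0.9, n),
            "r2_dia": rng.uniform(5.0, 25.0, n),
            "gamma2": rng.uniform(0.0, 60.0, n),
            "rex": rng.uniform(0.0, 8.0, n),
        }
    )
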