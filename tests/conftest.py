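import numpy as np
import pandas as pd
import pytest

import strokeconn as sc


@pytest.fixture(scope="session")
def registry():
    return sc.default_registry()


@pytest.fixture(scope="session")
def toy_registry():
    """Four-region toy: two 2-region networks, left hemisphere only."""
    return sc.NetworkRegistry(
        {"N1": ["A", "B"], "N2": ["C", "D"]}, hemisphere_scopes=("left",)
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort under the default study conditions."""
    return sc.simulate_cohort(sc.SimulationConfig(seed=7, target_design_r2=0.70))


@pytest.fixture
def linear_table():
    """Small regression table with a known linear signal in x1, x2."""
    rng = np.random.default_rng(3)
    n = 40
    x1, x2, x3 = rng.standard_normal((3, n))
    y = 2.0 + 3.0 * x1 - 1.5 * x2 + rng.normal(0, 0.5, n)
    return pd.DataFrame({"x1": x1, "x2": x2, "x3": x3, "nihss": y})


def make_ts(data, names, tr=1.0):
    return sc.RoiTimeSeriesSet(
        data=np.asarray(data, dtype=float), region_names=names,
        sampling_interval=tr,
    )
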