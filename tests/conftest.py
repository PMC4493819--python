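import numpy as np
import pandas as pd
import pytest

import emic


@pytest.fixture(scope="session")
def params():
    return emic.SyntheticParams()


@pytest.fixture(scope="session")
def synthetic_inputs(params):
    """Default synthetic life table, morbidity and cost schedules, ages 0-105."""
    return (emic.gompertz_lifetable(params),
            emic.synthetic_pyld(params),
            emic.synthetic_costs(params))


@pytest.fixture(scope="session")
def reference_table():
    return emic.nz2011_reference()


def constant_hazard(q, n, start=0):
    """Hazard series with q at every age over n one-year cycles."""
    return pd.Series(np.full(n, float(q)), index=np.arange(start, start + n))


def flat_series(value, n, start=0):
    return pd.Series(np.full(n, float(value)), index=np.arange(start, start + n))
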