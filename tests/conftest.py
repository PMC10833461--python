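import numpy as np
import pandas as pd
import pytest

from pocdiag import CohortTable, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic oncology cohort (MCAR ecog, MAR egfr,
    MNAR-value pdl1), n=2500, fixed seed."""
    return simulate_cohort(n=2500, seed=42)


@pytest.fixture()
def tiny_cohort():
    """Hand-built 10-row cohort with two POCs and a continuous outcome."""
    df = pd.DataFrame(
        {
            "exposure": [0, 1, 0, 1, 0, 1, 0, 1, 0, 1],
            "age": [55.0, 60.0, 62.0, 70.0, 58.0, 65.0, 61.0, 59.0, 66.0, 63.0],
            "sex": ["f", "m", "f", "f", "m", "m", "f", "m", "f", "m"],
            "lab_a": [1.2, np.nan, 3.0, np.nan, 2.2, 2.8, np.nan, 1.9, 2.5, 3.1],
            "lab_b": [np.nan, np.nan, 0.4, 0.9, np.nan, 0.7, np.nan, 0.8, 0.5, 0.6],
            "y": [2.0, 3.0, 2.5, 4.0, 2.2, 3.8, 2.9, 3.1, 2.4, 3.5],
        }
    )
    return CohortTable.from_dataframe(df, exposure="exposure", outcome="y")
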