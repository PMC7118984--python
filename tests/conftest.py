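import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from probsurv.synthetic_data import TruthParams

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_truth():
    """A quick-to-generate synthetic world with the default generative law."""
    return TruthParams(seed=42, n_survey=5_000, n_registry=1_000)


@pytest.fixture
def survey_fixture():
    """Ten hand-written survey rows: one under-25, one mixed-race, eight eligible."""
    base = dict(marital="married", state="California", weight=1.0)
    rows = [
        dict(year=2005, age_group=4, sex="male", race="White", **base),      # under 25
        dict(year=2005, age_group=8, sex="female", race="mixed", **base),    # mixed race
    ] + [
        dict(year=2001 + i, age_group=5 + i, sex="male", race="White", **base)
        for i in range(8)
    ]
    df = pd.DataFrame(rows)
    df["smoker"] = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1]
    return df
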