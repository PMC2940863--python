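import numpy as np
import pandas as pd
import pytest

from scoreboot.cohort import Cohort


def make_cohort(columns: dict, outcome, name: str = "outcome") -> Cohort:
    """Build a Cohort from plain arrays."""
    return Cohort(pd.DataFrame(columns), pd.Series(outcome, name=name))


@pytest.fixture
def rng():
    return np.random.default_rng(20251109)


@pytest.fixture
def small_cohort():
    """20 patients, one informative dichotomous and one continuous variable."""
    rng = np.random.default_rng(7)
    y = np.array([0] * 12 + [1] * 8)
    flag = np.where(y == 1, rng.random(20) < 0.8, rng.random(20) < 0.2).astype(float)
    cont = np.where(y == 1, rng.normal(2.0, 1.0, 20), rng.normal(0.0, 1.0, 20))
    return make_cohort({"flag": flag, "cont": cont}, y)
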