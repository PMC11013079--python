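import numpy as np
import pytest

from bascox.cox import SurvivalData
from bascox.preprocess import preprocess
from bascox.simulate import CohortSpec, simulate_cohort


def random_survival(rng, n=40, p=3, beta=None, ties=False):
    """Random right-censored PH dataset for solver tests."""
    X = rng.normal(size=(n, p))
    beta = np.zeros(p) if beta is None else np.asarray(beta)
    t = rng.exponential(1.0 / (0.2 * np.exp(X @ beta)))
    c = rng.uniform(0, 8, n)
    time = np.minimum(t, c)
    if ties:
        time = np.ceil(time * 4) / 4  # coarse grid forces tied times
    event = (t <= c).astype(int)
    if event.sum() == 0:
        event[np.argmin(time)] = 1
    return SurvivalData(time=time, event=event, X=X)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=309) with injected missingness."""
    return simulate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def prepped_cohort(default_cohort):
    """The same cohort after filter + imputation + INT."""
    table, report = preprocess(default_cohort, seed=11)
    return table, report
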