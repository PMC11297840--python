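import numpy as np
import pandas as pd
import pytest

from prtrees.pseudo import SurvivalDataset, TimeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def random_survival_dataset(rng, n, censor=True, rounding=None, p=1):
    """Small random right-censored dataset, optionally with heavy ties."""
    time = rng.exponential(1.0, n) + 0.01
    if rounding is not None:
        time = np.maximum(np.round(time, rounding), 0.01)
    event = rng.integers(0, 2, n) if censor else np.ones(n, dtype=int)
    cov = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{j + 1}" for j in range(p)])
    return SurvivalDataset(ids=np.arange(n), time=time, event=event, covariates=cov)


def grid_from_times(time, levels=(0.2, 0.5, 0.8)):
    pts = np.unique(np.quantile(np.asarray(time), levels))
    return TimeGrid(points=pts)


@pytest.fixture
def small_censored_dataset(rng):
    return random_survival_dataset(rng, 40)
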