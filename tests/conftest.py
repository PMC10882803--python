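import numpy as np
import pytest

from hybridps import TrialDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240222)


def make_dataset(
    n: int = 40,
    k: int = 3,
    n_historical: int = 10,
    seed: int = 0,
    p_treat: float = 0.5,
) -> TrialDataset:
    """Small random but valid dataset for structural tests."""
    g = np.random.default_rng(seed)
    source = np.full(n, -1, dtype=int)
    source[: n - n_historical] = 1
    treatment = np.where(source == 1, (g.random(n) < p_treat).astype(int), 0)
    # guarantee both treatment classes inside the RCT
    treatment[0] = 1
    treatment[1] = 0
    return TrialDataset(
        covariates=g.standard_normal((n, k)),
        source=source,
        treatment=treatment,
        outcome=(g.random(n) < 0.5).astype(int),
    )


@pytest.fixture
def small_dataset():
    return make_dataset()
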