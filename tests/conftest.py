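import numpy as np
import pytest

from noshowpricing.cohort import CohortConfig, default_effects, generate_cohort
from noshowpricing.metrics import ConfusionMatrix

# Published test-phase confusion matrices of the three classifiers
# (positive class = show-up): used throughout as known-answer fixtures.
RF_CM = ConfusionMatrix(tp=116, tn=90, fp=3, fn=5)
GB_CM = ConfusionMatrix(tp=117, tn=90, fp=3, fn=4)
AB_CM = ConfusionMatrix(tp=114, tn=87, fp=6, fn=7)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-sized cohort (n=1073) shared across tests."""
    return generate_cohort(CohortConfig(seed=7), default_effects())


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_patients=200, seed=11), default_effects())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_confusion(rng, max_count=500) -> ConfusionMatrix:
    while True:
        tp, tn, fp, fn = rng.integers(0, max_count, size=4)
        if tp + tn + fp + fn >= 1:
            return ConfusionMatrix(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))
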