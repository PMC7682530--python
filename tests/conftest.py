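import numpy as np
import pandas as pd
import pytest

from multiarm_itr.core import TrialDataset


@pytest.fixture
def toy_trial() -> TrialDataset:
    """Six subjects, arms (1,1,2,2,3,3), Y = 1..6, uniform propensity 1/3."""
    X = pd.DataFrame({"x1": np.linspace(-1, 1, 6), "x2": [0, 1, 0, 1, 0, 1.0]})
    return TrialDataset(X=X, A=np.array([1, 1, 2, 2, 3, 3]),
                        Y=np.arange(1.0, 7.0), K=3)


def random_trial(n: int, K: int = 3, seed: int = 0, p: int = 3) -> TrialDataset:
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({f"x{j}": rng.normal(size=n) for j in range(1, p + 1)})
    A = np.tile(np.arange(1, K + 1), n // K + 1)[:n]
    rng.shuffle(A)
    Y = rng.normal(size=n)
    return TrialDataset(X=X, A=A, Y=Y, K=K)
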