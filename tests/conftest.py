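import numpy as np
import pytest

from ratersim.datagen import Condition, DistortionParams
from ratersim.engine import ThresholdPolicy, run_design


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def default_params():
    return DistortionParams()


@pytest.fixture(scope="session")
def small_store():
    """Replication store over a small bias x variance slice, reused by
    the sensitivity and GLM tests (no distortion flags, n = 100)."""
    conditions = [
        Condition(100, b, v) for b in (-0.5, 0.0, 0.5)
        for v in ("low", "mid", "high")
    ]
    summary, store = run_design(conditions, reps=150, master_seed=7,
                                policy=ThresholdPolicy())
    return summary, store


def random_pair(rng, n=None, k=5):
    """A random rating pair on categories 0..k-1 with 2 <= n <= 12."""
    if n is None:
        n = int(rng.integers(2, 13))
    return rng.integers(0, k, size=n), rng.integers(0, k, size=n)
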