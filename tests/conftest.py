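import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_915)


def expand_counts(tp: int, fp: int, tn: int, fn: int):
    """Label/prediction vectors realizing the given confusion counts."""
    y = np.array([1] * (tp + fn) + [0] * (fp + tn), dtype=np.int64)
    pred = np.array([1] * tp + [0] * fn + [1] * fp + [0] * tn, dtype=np.int64)
    return y, pred
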