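import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dice.io import ExpressionMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("dice").setLevel(logging.WARNING)


def toy_matrix(values, conditions=("normal", "tumor"), paired=False):
    """Build a small ExpressionMatrix from a dict gene -> list of values.

    The first half of each row belongs to the first condition.
    """
    genes = list(values)
    n = len(values[genes[0]])
    half = n // 2
    samples = [f"s{i+1}" for i in range(n)]
    condition_of = {
        s: (conditions[0] if i < half else conditions[1]) for i, s in enumerate(samples)
    }
    pair_of = None
    if paired:
        pair_of = {s: f"p{(i % half) + 1}" for i, s in enumerate(samples)}
    df = pd.DataFrame(
        {s: [values[g][i] for g in genes] for i, s in enumerate(samples)},
        index=pd.Index(genes, name="gene"),
        dtype=float,
    )
    return ExpressionMatrix(
        values=df, condition_of=condition_of, pair_of=pair_of, conditions=conditions
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def six_sample_matrix():
    """5 genes x 6 samples, 3 normal / 3 tumor."""
    rng = np.random.default_rng(7)
    vals = {f"g{i}": list(rng.normal(8, 1, 6)) for i in range(1, 6)}
    return toy_matrix(vals)
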