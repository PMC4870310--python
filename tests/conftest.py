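import numpy as np
import pytest

from propcoda import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_matrix():
    """4 conditions x 4 genes, strictly positive, absolute scale."""
    vals = np.array(
        [
            [1.0, 2.0, 4.0, 3.0],
            [2.0, 4.1, 8.0, 1.0],
            [3.0, 6.2, 12.5, 2.0],
            [1.5, 2.9, 6.0, 5.0],
        ]
    )
    return ExpressionMatrix(
        values=vals,
        condition_ids=["c1", "c2", "c3", "c4"],
        gene_ids=["g1", "g2", "g3", "g4"],
        scale="absolute",
    )


def random_log_pair(rng, n=None):
    """Random nondegenerate pair of logged vectors, n in 3..50."""
    if n is None:
        n = int(rng.integers(3, 51))
    while True:
        a = rng.normal(scale=rng.uniform(0.2, 3.0), size=n) + rng.normal()
        b = rng.normal(scale=rng.uniform(0.2, 3.0), size=n) + rng.normal()
        mix = rng.uniform(-1, 1)
        b = mix * a + np.sqrt(1 - mix**2) * b
        if np.var(a, ddof=1) > 1e-12 and np.var(b, ddof=1) > 1e-12:
            return a, b
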