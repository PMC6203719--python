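import numpy as np
import pytest

from omiclust.io import OmicsMatrix
from omiclust.simulate import SyntheticSpec, generate


def path_block_similarity(sizes, eps=2e-3):
    """Block-diagonal row-stochastic similarity with weak, distinct
    path-topology couplings between consecutive blocks.

    The distinct couplings split the near-degenerate small eigenvalues
    deterministically into delocalized (Fourier-like) modes, so the
    separation-cost curve is well defined below the true block count.
    """
    n = sum(sizes)
    bounds = np.cumsum([0] + list(sizes))
    s = np.zeros((n, n))
    for b, sz in enumerate(sizes):
        s[bounds[b]:bounds[b + 1], bounds[b]:bounds[b + 1]] = 1.0 / sz
    for b in range(len(sizes) - 1):
        e = eps * (1.0 + 0.5 * b)
        s[bounds[b]:bounds[b + 1], bounds[b + 1]:bounds[b + 2]] = e
        s[bounds[b + 1]:bounds[b + 2], bounds[b]:bounds[b + 1]] = e
    s /= s.sum(axis=1, keepdims=True)
    return (s + s.T) / 2


def small_spec(**overrides):
    """A fast-converging cohort for unit tests (N=60, 60 genes/type)."""
    defaults = dict(
        n_samples=60,
        c_true=3,
        proportions=(0.4, 0.35, 0.25),
        genes_per_type={"mutation": 60, "cna": 60, "methylation": 60, "expression": 60},
        seed=0,
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate(small_spec())


@pytest.fixture
def tiny_matrix():
    return OmicsMatrix(
        sample_ids=("P1", "P2", "P3"),
        feature_ids=("G1", "G2"),
        values=np.array([[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]]),
        data_type="expression",
    )
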