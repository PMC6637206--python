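import numpy as np
import pandas as pd
import pytest


def make_merged(p_i, p_j, chrom=None, pos=None):
    """Build a merged two-trait panel from raw p-value vectors."""
    n = len(p_i)
    return pd.DataFrame(
        {
            "snp_id": [f"rs{k + 1}" for k in range(n)],
            "chrom": chrom if chrom is not None else ["1"] * n,
            "pos": pos if pos is not None else np.arange(1, n + 1) * 10_000,
            "p_i": np.asarray(p_i, dtype=float),
            "p_j": np.asarray(p_j, dtype=float),
        }
    )


def brute_force_cfdr(p_i, p_j, a, b):
    """Independent double-loop count of the cFDR estimator."""
    n_j = sum(1 for y in p_j if y <= b)
    n_ij = sum(1 for x, y in zip(p_i, p_j) if x <= a and y <= b)
    if n_ij == 0:
        return 1.0
    return min(a * n_j / n_ij, 1.0)


@pytest.fixture
def toy5():
    """The 5-SNP reference panel used throughout the estimator tests."""
    return make_merged(
        p_i=[0.001, 0.01, 0.02, 0.5, 0.9],
        p_j=[0.004, 0.03, 0.5, 0.01, 0.8],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
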