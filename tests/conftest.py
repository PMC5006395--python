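import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from polyssr import AlleleColumn, AlleleMatrix, SimConfig, simulate_panel


@pytest.fixture
def tiny_matrix() -> AlleleMatrix:
    """2 individuals x 3 alleles at 2 loci; second allele of M1 is private."""
    return AlleleMatrix(
        ["a", "b"],
        [AlleleColumn("M1", 100), AlleleColumn("M1", 104), AlleleColumn("M2", 200)],
        np.array([[1, 1, 0], [1, 0, 1]]),
    )


@pytest.fixture
def ovk042_like() -> AlleleMatrix:
    """One marker, two alleles with occurrence frequencies 0.50 and 1.00.

    Mirrors the worked marker-characterisation example: a biallelic locus
    with one fixed fragment and one carried by half the panel.
    """
    n = 32
    X = np.zeros((n, 2), dtype=int)
    X[:16, 0] = 1  # f = 0.50
    X[:, 1] = 1  # f = 1.00 (monomorphic fragment)
    return AlleleMatrix(
        [f"ID_{i + 1:02d}" for i in range(n)],
        [AlleleColumn("OVX001", 183), AlleleColumn("OVX001", 186)],
        X,
    )


@pytest.fixture(scope="session")
def default_panel():
    """One simulated panel at study-scale defaults (32 ind, 2x16, 101 loci)."""
    return simulate_panel(SimConfig(seed=20260924))


def random_binary_matrix(rng, n=6, n_loci=4, max_alleles=5) -> AlleleMatrix:
    """Random valid AlleleMatrix for property tests (no all-zero columns)."""
    cols, blocks = [], []
    for l in range(n_loci):
        k = int(rng.integers(1, max_alleles + 1))
        block = rng.integers(0, 2, size=(n, k))
        for j in range(k):
            if block[:, j].sum() == 0:
                block[rng.integers(0, n), j] = 1
        blocks.append(block)
        cols += [AlleleColumn(f"L{l + 1}", 100 + 10 * l + j) for j in range(k)]
    X = np.hstack(blocks)
    return AlleleMatrix([f"i{i}" for i in range(n)], cols, X)
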