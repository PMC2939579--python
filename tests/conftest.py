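"""Shared fixtures and brute-force oracles for the test suite."""

from itertools import combinations

import numpy as np
import pytest

from sweepscan.datamodel import GeneticMap, HaplotypeMatrix, SiteTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def make_matrix(alleles, positions=None) -> HaplotypeMatrix:
    alleles = np.asarray(alleles, dtype=np.int8)
    n, m = alleles.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    sites = SiteTable.simple(positions)
    return HaplotypeMatrix(alleles, [f"c{i}" for i in range(n)], sites)


def random_matrix(rng, n=10, m=8, positions=None) -> HaplotypeMatrix:
    """Random complete 0/1 matrix guaranteed to contain both alleles
    somewhere (not necessarily per column)."""
    al = rng.integers(0, 2, size=(n, m))
    return make_matrix(al, positions)


def brute_force_pair_identity(rows: np.ndarray) -> float:
    """Probability two random distinct chromosomes are identical over
    the given columns, by explicit pair enumeration."""
    n = rows.shape[0]
    hits = sum(1 for i, j in combinations(range(n), 2)
               if np.array_equal(rows[i], rows[j]))
    return hits / (n * (n - 1) / 2)


@pytest.fixture
def uniform_map():
    """1 cM/Mb uniform map over 0-2 Mb."""
    return GeneticMap.uniform(0, 2_000_000, cm_per_mb=1.0)
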