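"""Shared fixtures and independent oracles for the test suite."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from orabench.genesets import GeneList, GeneSet, GeneSetLibrary


@pytest.fixture
def toy_background() -> GeneList:
    return GeneList.from_ids("background", [f"g{i}" for i in range(1, 21)])


@pytest.fixture
def toy_foreground() -> GeneList:
    return GeneList.from_ids("foreground", ["g1", "g2", "g3"])


@pytest.fixture
def toy_library() -> GeneSetLibrary:
    """Three sets: one overlapping the foreground, one not, one off-background."""
    return GeneSetLibrary(
        [
            GeneSet("S1", "fully in foreground", tuple(f"g{i}" for i in range(1, 6))),
            GeneSet("S2", "no foreground overlap", tuple(f"g{i}" for i in range(6, 11))),
            GeneSet("S3", "outside background", tuple(f"g{i}" for i in range(21, 26))),
        ]
    )


def fisher_upper_tail_exact(k: int, n: int, K: int, N: int) -> Fraction:
    """Exact one-sided (greater) Fisher p by enumeration over overlap counts.

    Counts the draws of n genes from N with at least k hits among the K set
    members, as an exact rational — independent of any scipy machinery.
    """
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(n, K) + 1))
    return Fraction(num, comb(N, n))


def bh_stepup_hand(p_values):
    """Hand-rolled Benjamini-Hochberg step-up, independent of statsmodels."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = running
    return adjusted


def random_ora_instance(rng: np.random.Generator, max_genes: int = 50):
    """A random small ORA problem: (foreground, background, library).

    The gene pool is at most ``max_genes`` symbols; the library leaves some
    background genes unannotated so the background problem is expressible.
    """
    n_pool = int(rng.integers(15, max_genes + 1))
    pool = [f"g{i}" for i in range(n_pool)]
    bg_ids = list(rng.choice(pool, size=int(rng.integers(10, n_pool + 1)), replace=False))
    fg_size = int(rng.integers(1, max(2, len(bg_ids) // 2)))
    fg_ids = list(rng.choice(bg_ids, size=fg_size, replace=False))
    n_sets = int(rng.integers(2, 7))
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(1, max(2, n_pool // 2)))
        members = tuple(rng.choice(pool, size=size, replace=False))
        sets.append(GeneSet(f"S{i}", "random", members))
    return (
        GeneList.from_ids("foreground", fg_ids),
        GeneList.from_ids("background", bg_ids),
        GeneSetLibrary(sets),
    )


def nb_counts(mu, dispersion, n_samples, rng) -> np.ndarray:
    """Gamma-Poisson draws: columns are samples, rows follow ``mu``."""
    mu = np.asarray(mu, dtype=float)
    cols = []
    for _ in range(n_samples):
        if dispersion > 0:
            lam = rng.gamma(1.0 / dispersion, mu * dispersion)
        else:
            lam = mu
        cols.append(rng.poisson(lam))
    return np.column_stack(cols)


@pytest.fixture
def two_group_labels():
    def _make(columns):
        return pd.Series(
            ["case" if str(c).startswith("case") else "ctrl" for c in columns],
            index=columns,
        )

    return _make
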