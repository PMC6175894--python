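"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's code paths: Fisher and
Hardy-Weinberg p-values come from explicit enumeration with exact integer
combinatorics, Wilcoxon p-values from full enumeration of group
assignments, two-locus haplotype likelihoods from a 1-D grid search, and
approximate k-mer matching from a dense dynamic-programming scan.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest


# ---------------------------------------------------------------- oracles

def fisher_oracle(a: int, b: int, c: int, d: int, side: str) -> float:
    """Enumerate every 2x2 table with the observed margins exactly.

    Probabilities are exact rationals; 'two' sums tables whose point
    probability is <= the observed one (tiny relative tolerance for the
    comparison, applied on exact rationals so only true ties enter).
    """
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = math.comb(n, row1)

    def pmf(x: int) -> Fraction:
        if x < 0 or x > col1 or row1 - x < 0 or col1 - x > row2:
            return Fraction(0)
        return Fraction(math.comb(col1, x) * math.comb(n - col1, row1 - x), denom)

    p_obs = pmf(a)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    if side == "lower":
        return float(sum(pmf(x) for x in range(lo, a + 1)))
    if side == "upper":
        return float(sum(pmf(x) for x in range(a, hi + 1)))
    return float(sum(p for x in range(lo, hi + 1) if (p := pmf(x)) <= p_obs))


def hwe_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional HWE p-value by direct enumeration of heterozygote
    counts with the observed allele totals, exact rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    probs: dict[int, Fraction] = {}
    for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        naa = (n_a - het) // 2
        nAA = n - naa - het
        w = Fraction(2 ** het * math.factorial(n),
                     math.factorial(nAA) * math.factorial(het) * math.factorial(naa))
        probs[het] = w
    total = sum(probs.values())
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs) / total)


def wilcoxon_oracle(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """One-sided rank-sum p by full enumeration over all group assignments
    of the pooled (tie-free) values."""
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if alternative == "greater" and w >= w_obs:
            count += 1
        elif alternative == "less" and w <= w_obs:
            count += 1
    return count / total


def em_grid_oracle(counts: np.ndarray, grid: int = 20001) -> float:
    """Best p_AB by brute likelihood over a fine grid.

    Allele frequencies are fixed by the margins; only p_AB is free, so a
    1-D scan of the multinomial log-likelihood of the nine genotype
    classes suffices.  Returns the argmax p_AB.
    """
    n = counts.sum()
    # allele frequencies of the major alleles A and B from dosage counts
    p_A = (counts * np.array([2, 2, 2, 1, 1, 1, 0, 0, 0]).reshape(3, 3)).sum() / (2 * n)
    p_B = (counts * np.array([2, 1, 0, 2, 1, 0, 2, 1, 0]).reshape(3, 3)).sum() / (2 * n)
    lo = max(0.0, p_A + p_B - 1.0)
    hi = min(p_A, p_B)
    best_ll, best_p = -np.inf, lo
    for p_ab_major in np.linspace(lo, hi, grid):
        h = np.array([
            p_ab_major,                  # AB
            p_A - p_ab_major,            # Ab
            p_B - p_ab_major,            # aB
            1.0 - p_A - p_B + p_ab_major,  # ab
        ])
        if h.min() < 0:
            continue
        h = np.clip(h, 1e-12, None)
        # P(genotype pair) from haplotype frequencies under random union
        probs = np.zeros((3, 3))
        hh = {(0, 0): h[0], (0, 1): h[1], (1, 0): h[2], (1, 1): h[3]}
        for (a1, b1), pa in hh.items():
            for (a2, b2), pb in hh.items():
                probs[a1 + a2, b1 + b2] += pa * pb
        ll = (counts * np.log(np.clip(probs, 1e-300, None))).sum()
        if ll > best_ll:
            best_ll, best_p = ll, p_ab_major
    return best_p


def edit_distance_dp(pattern: str, text: str) -> int:
    """Minimal semi-global edit distance of pattern against any substring
    of text (full dense DP, no banding)."""
    m, n = len(pattern), len(text)
    prev = np.zeros(n + 1, dtype=np.int64)  # free start in text
    for i in range(1, m + 1):
        cur = np.empty(n + 1, dtype=np.int64)
        cur[0] = i
        pc = pattern[i - 1]
        for j in range(1, n + 1):
            cost = 0 if pc == text[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return int(prev.min())


def detect_exon_oracle(read: str, exon: str, k: int = 18, max_edits: int = 2) -> bool:
    """Dense-DP reference for approximate k-mer presence."""
    return any(
        edit_distance_dp(exon[i:i + k], read) <= max_edits
        for i in range(len(exon) - k + 1)
    )


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def exon_library():
    from raresplice.simulate import default_exon_library

    return default_exon_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
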