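"""Pairwise linkage disequilibrium and haploblock partitioning.

Unphased biallelic genotypes (minor-allele dosages 0/1/2 with missing
values) are the input.  Two-locus haplotype frequencies are estimated by
EM — only double heterozygotes are phase-ambiguous and are split each
iteration in the ratio of the current coupling/repulsion haplotype
products — and D' and r² follow from the fitted frequencies.  Contiguous
haploblocks are found with the four-gamete rule: a block may not contain
a site pair at which all four two-locus gametes exceed a frequency
threshold (default 1%), since a fourth gamete is evidence of historical
recombination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import NoCompleteSamplesError

__all__ = ["Site", "GenotypeMatrix", "PairwiseLD", "Haploblock",
           "em_hap_freqs", "ld_stats", "pairwise_ld", "four_gamete_blocks"]

MISSING = -1  # dosage code for a missing call

EM_TOL = 1e-8
EM_MAX_ITER = 1000


@dataclass(frozen=True)
class Site:
    """A biallelic site: identifier, 1-based position and allele labels."""

    id: str
    pos: int
    chrom: str = "chr"
    minor: str = "a"
    major: str = "A"


@dataclass
class GenotypeMatrix:
    """Samples x sites minor-allele dosages in {0, 1, 2}, MISSING = -1."""

    samples: list[str]
    sites: list[Site]
    calls: np.ndarray  # int8, shape (n_samples, n_sites)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError("calls shape must be (n_samples, n_sites)")
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or MISSING (-1)")
        by_chrom: dict[str, int] = {}
        for s in self.sites:
            prev = by_chrom.get(s.chrom)
            if prev is not None and s.pos <= prev:
                raise ValueError("site positions must strictly increase within a chromosome")
            by_chrom[s.chrom] = s.pos

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class PairwiseLD:
    """EM haplotype frequencies (AB, Ab, aB, ab) and derived LD statistics.

    'A'/'B' denote the major alleles at the two sites, 'a'/'b' the minor.
    ``monomorphic`` flags pairs where one site has no variation among the
    complete samples; D', r² are 0 by convention there.
    """

    hap_freqs: tuple[float, float, float, float]
    d: float
    d_prime: float
    r2: float
    n_used: int
    monomorphic: bool = False


@dataclass(frozen=True)
class Haploblock:
    """Inclusive index range [first_site_index, last_site_index] into sites."""

    first_site_index: int
    last_site_index: int

    def __post_init__(self) -> None:
        if self.first_site_index > self.last_site_index:
            raise ValueError("block indices out of order")


def _pair_counts(g: GenotypeMatrix, site_i: int, site_j: int) -> tuple[np.ndarray, int]:
    """3x3 joint dosage counts over pairwise-complete samples."""
    gi = g.calls[:, site_i]
    gj = g.calls[:, site_j]
    keep = (gi != MISSING) & (gj != MISSING)
    n = int(keep.sum())
    if n == 0:
        raise NoCompleteSamplesError(f"no complete samples for sites {site_i}, {site_j}")
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (gi[keep], gj[keep]), 1)
    return counts, n


def em_hap_freqs(g: GenotypeMatrix, site_i: int, site_j: int,
                 tol: float = EM_TOL, max_iter: int = EM_MAX_ITER) -> tuple[float, float, float, float]:
    """Maximum-likelihood two-locus haplotype frequencies (AB, Ab, aB, ab).

    Initialised at linkage equilibrium (products of allele frequencies);
    each iteration splits the double heterozygotes between the coupling
    (AB/ab) and repulsion (Ab/aB) phases in the ratio
    p_AB*p_ab : p_Ab*p_aB.  Deterministic: no random restarts.
    """
    counts, n = _pair_counts(g, site_i, site_j)
    return _em_from_counts(counts, n, tol, max_iter)


def _em_from_counts(counts: np.ndarray, n: int, tol: float = EM_TOL,
                    max_iter: int = EM_MAX_ITER) -> tuple[float, float, float, float]:
    n_hap = 2 * n
    # known haplotype contributions; dosage d at a site = copies of minor allele
    # index 0 = major (A/B), 1 = minor (a/b)
    fixed = np.zeros((2, 2))  # [site_i allele][site_j allele] haplotype counts
    dh = 0  # number of double heterozygotes (1,1): phase unknown
    for di in range(3):
        for dj in range(3):
            c = counts[di, dj]
            if c == 0:
                continue
            if di == 1 and dj == 1:
                dh = c
                continue
            # unambiguous: each individual contributes two known haplotypes
            hi = (0, 0) if di == 0 else (1, 1) if di == 2 else (0, 1)
            hj = (0, 0) if dj == 0 else (1, 1) if dj == 2 else (0, 1)
            if di == 1 or dj == 1:
                # exactly one site heterozygous: phase is still determined
                fixed[hi[0], hj[0]] += c
                fixed[hi[1], hj[1]] += c
            else:
                fixed[hi[0], hj[0]] += 2 * c
    # allele frequencies (minor) at the two sites
    p_a = (fixed[1, 0] + fixed[1, 1] + dh) / n_hap
    p_b = (fixed[0, 1] + fixed[1, 1] + dh) / n_hap
    freqs = np.array([
        (1 - p_a) * (1 - p_b),  # AB
        (1 - p_a) * p_b,        # Ab
        p_a * (1 - p_b),        # aB
        p_a * p_b,              # ab
    ])
    if dh == 0:
        out = np.array([fixed[0, 0], fixed[0, 1], fixed[1, 0], fixed[1, 1]]) / n_hap
        return tuple(out.tolist())
    for _ in range(max_iter):
        coup = freqs[0] * freqs[3]
        rep = freqs[1] * freqs[2]
        tot = coup + rep
        frac = 0.5 if tot <= 0 else coup / tot
        new = np.array([
            fixed[0, 0] + dh * frac,
            fixed[0, 1] + dh * (1 - frac),
            fixed[1, 0] + dh * (1 - frac),
            fixed[1, 1] + dh * frac,
        ]) / n_hap
        if np.abs(new - freqs).max() < tol:
            freqs = new
            break
        freqs = new
    return tuple(freqs.tolist())


def ld_stats(hap_freqs: Sequence[float]) -> tuple[float, float, float, bool]:
    """D, D' and r² from two-locus haplotype frequencies (AB, Ab, aB, ab).

    D = p_AB - p_A p_B (with p measured on the first-listed, major alleles);
    D' = |D| / Dmax; r² = D² / (p_A q_A p_B q_B).  For a monomorphic site
    all three are 0 by convention and the flag is set.
    Returns (d, d_prime, r2, monomorphic).
    """
    f = np.asarray(hap_freqs, dtype=float)
    if f.min() < -1e-9 or abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("haplotype frequencies must be non-negative and sum to 1")
    p_A = f[0] + f[1]
    p_B = f[0] + f[2]
    q_A, q_B = 1 - p_A, 1 - p_B
    if min(p_A, q_A, p_B, q_B) <= 1e-12:
        return 0.0, 0.0, 0.0, True
    d = f[0] - p_A * p_B
    if d >= 0:
        dmax = min(p_A * q_B, q_A * p_B)
    else:
        dmax = min(p_A * p_B, q_A * q_B)
    d_prime = 0.0 if dmax <= 0 else min(1.0, abs(d) / dmax)
    r2 = min(1.0, d * d / (p_A * q_A * p_B * q_B))
    return float(d), float(d_prime), float(r2), False


def pairwise_ld(g: GenotypeMatrix, site_i: int, site_j: int) -> PairwiseLD:
    """EM haplotype frequencies and LD statistics for one site pair."""
    counts, n = _pair_counts(g, site_i, site_j)
    freqs = _em_from_counts(counts, n)
    d, dp, r2, mono = ld_stats(freqs)
    return PairwiseLD(freqs, d, dp, r2, n, mono)


def _four_gametes_exceed(freqs: Sequence[float], threshold: float) -> bool:
    """True iff all four gametes are above the frequency threshold."""
    return all(f > threshold for f in freqs)


def four_gamete_blocks(g: GenotypeMatrix, freq_threshold: float = 0.01,
                       all_pairs: bool = True) -> list[Haploblock]:
    """Greedy left-to-right four-gamete partition of the site list.

    The current block is extended to the next site iff no site pair within
    the candidate block shows all four EM-estimated gametes at frequency
    strictly above ``freq_threshold``.  With ``all_pairs=False`` only the
    adjacent pair is checked.  Blocks tile the sites without overlap.
    """
    m = g.n_sites
    if m == 0:
        return []
    blocks: list[Haploblock] = []
    cache: dict[tuple[int, int], tuple[float, float, float, float]] = {}

    def freqs(i: int, j: int) -> tuple[float, float, float, float]:
        key = (i, j)
        if key not in cache:
            cache[key] = em_hap_freqs(g, i, j)
        return cache[key]

    start = 0
    for nxt in range(1, m):
        partners = range(start, nxt) if all_pairs else range(nxt - 1, nxt)
        broken = any(_four_gametes_exceed(freqs(i, nxt), freq_threshold) for i in partners)
        if broken:
            blocks.append(Haploblock(start, nxt - 1))
            start = nxt
    blocks.append(Haploblock(start, m - 1))
    return blocks
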