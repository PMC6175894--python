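"""Single-cohort allelic association statistics for a biallelic SNP.

The unit of observation is the allele (2 per genotyped individual), not
the genotype: a cohort is summarised as a 2x2 table of minor/major allele
counts in cases and controls.  The module provides the allelic odds ratio
with a Wald (log-scale) confidence interval, Fisher exact tests in both
tails, reconstruction of allele counts from published sample sizes and
rounded allele frequencies, and the exact conditional Hardy-Weinberg test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import AmbiguousCountError, DegenerateTableError

__all__ = [
    "AlleleTable2x2",
    "CohortSummary",
    "AssociationResult",
    "HweResult",
    "counts_from_summary",
    "allelic_or",
    "fisher_exact",
    "hwe_exact",
]


@dataclass(frozen=True)
class AlleleTable2x2:
    """Minor/major allele counts in cases and controls for one SNP.

    ``case_minor + case_major`` equals twice the number of genotyped cases
    (two alleles per diploid individual), and likewise for controls.
    """

    case_minor: int
    case_major: int
    ctrl_minor: int
    ctrl_major: int

    def __post_init__(self) -> None:
        for name in ("case_minor", "case_major", "ctrl_minor", "ctrl_major"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.case_minor + self.case_major <= 0:
            raise ValueError("case allele total must be positive")
        if self.ctrl_minor + self.ctrl_major <= 0:
            raise ValueError("control allele total must be positive")

    @property
    def n_case_alleles(self) -> int:
        return self.case_minor + self.case_major

    @property
    def n_ctrl_alleles(self) -> int:
        return self.ctrl_minor + self.ctrl_major

    def swapped_groups(self) -> "AlleleTable2x2":
        """Exchange case and control rows (inverts the odds ratio)."""
        return AlleleTable2x2(self.ctrl_minor, self.ctrl_major, self.case_minor, self.case_major)


@dataclass(frozen=True)
class CohortSummary:
    """Published per-cohort sample sizes and minor-allele frequencies."""

    n_cases: int
    n_ctrls: int
    maf_cases: float
    maf_ctrls: float
    label: str = ""
    phenotype: str = ""

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_ctrls <= 0:
            raise ValueError("sample sizes must be positive")
        if not (0.0 <= self.maf_cases <= 1.0 and 0.0 <= self.maf_ctrls <= 1.0):
            raise ValueError("minor-allele frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class AssociationResult:
    """Allelic odds ratio with log-scale SE, Wald CI and Fisher p-values."""

    odds_ratio: float
    se_log_or: float
    p_fisher_two_sided: float
    p_fisher_one_sided: float
    ci95_low: float
    ci95_high: float
    haldane_correction: bool = False


@dataclass(frozen=True)
class HweResult:
    """Genotype counts and the exact conditional Hardy-Weinberg p-value."""

    n_AA: int
    n_Aa: int
    n_aa: int
    p_exact: float


# Two tables whose point probabilities differ by less than this relative
# amount are treated as tied in the two-sided Fisher sum.
_FISHER_TIE_REL = 1e-7


def _candidate_counts(maf: float, n_alleles: int, decimals: int = 3) -> list[int]:
    """Integers c such that round(c / n_alleles, decimals) == maf.

    The printed frequency is assumed rounded half-up to ``decimals`` places,
    so admissible counts lie in the half-open interval
    [(maf - 5e-4) * n, (maf + 5e-4) * n).
    """
    half = 0.5 * 10 ** (-decimals)
    lo = (maf - half) * n_alleles
    hi = (maf + half) * n_alleles
    first = math.ceil(lo - 1e-12)
    out = [c for c in range(max(first, 0), math.floor(hi) + 1) if lo - 1e-12 <= c < hi - 1e-12]
    return [c for c in out if 0 <= c <= n_alleles]


def counts_from_summary(s: CohortSummary, decimals: int = 3) -> AlleleTable2x2:
    """Reconstruct allele counts from sample sizes and rounded frequencies.

    Raises
    ------
    AmbiguousCountError
        If more than one integer count is consistent with the printed
        precision for either group, or none is.
    """
    tables = []
    for n_ind, maf, grp in ((s.n_cases, s.maf_cases, "cases"), (s.n_ctrls, s.maf_ctrls, "controls")):
        n_alleles = 2 * n_ind
        cands = _candidate_counts(maf, n_alleles, decimals)
        if len(cands) != 1:
            raise AmbiguousCountError(
                f"{s.label or 'cohort'} {grp}: {len(cands)} counts consistent with "
                f"maf={maf} at {decimals} decimals over {n_alleles} alleles: {cands}"
            )
        minor = cands[0]
        tables.append((minor, n_alleles - minor))
    (cm, cM), (um, uM) = tables
    return AlleleTable2x2(cm, cM, um, uM)


def allelic_or(t: AlleleTable2x2, protective_direction: bool = True) -> AssociationResult:
    """Allelic odds ratio, SE of log OR, 95% Wald CI and Fisher p-values.

    OR = (case_minor * ctrl_major) / (case_major * ctrl_minor).  When any
    cell is zero the Haldane-Anscombe correction (+0.5 to every cell) is
    applied for the OR/SE/CI and flagged in the result; tables with all
    cells positive are left untouched.  The one-sided Fisher p-value tests
    the lower tail of ``case_minor`` (a protective minor allele) unless
    ``protective_direction`` is False.
    """
    if min(t.case_minor + t.ctrl_minor, t.case_major + t.ctrl_major) == 0:
        raise DegenerateTableError("a column margin is zero; OR undefined")
    cells = (t.case_minor, t.case_major, t.ctrl_minor, t.ctrl_major)
    haldane = any(c == 0 for c in cells)
    a, b, c, d = (x + 0.5 for x in cells) if haldane else cells
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    lo, hi = math.exp(log_or - 1.96 * se), math.exp(log_or + 1.96 * se)
    p2 = fisher_exact(t, side="two")
    p1 = fisher_exact(t, side="lower" if protective_direction else "upper")
    return AssociationResult(or_, se, p2, p1, lo, hi, haldane_correction=haldane)


def fisher_exact(t: AlleleTable2x2, side: str = "two") -> float:
    """Exact hypergeometric p-value for a 2x2 allele table.

    ``side='two'`` sums the probabilities of all tables (with the observed
    margins) whose point probability does not exceed the observed one, up
    to a small relative tie tolerance.  ``side='lower'`` is
    P(case_minor <= observed); ``side='upper'`` is P(case_minor >= observed).
    """
    if side not in ("two", "lower", "upper"):
        raise ValueError(f"side must be 'two', 'lower' or 'upper', got {side!r}")
    n_case = t.n_case_alleles
    total = n_case + t.n_ctrl_alleles
    k_minor = t.case_minor + t.ctrl_minor
    # case_minor ~ Hypergeom(total, k_minor, n_case) under the null
    rv = stats.hypergeom(total, k_minor, n_case)
    x = t.case_minor
    if side == "lower":
        return float(rv.cdf(x))
    if side == "upper":
        return float(rv.sf(x - 1))
    support = np.arange(max(0, k_minor - (total - n_case)), min(k_minor, n_case) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(x)
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_TIE_REL)].sum())
    return min(p, 1.0)


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> HweResult:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums, over all
    heterozygote counts of the same parity, the probabilities of
    configurations no more probable than the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa == 0:
        raise ValueError("genotype counts must be non-negative with positive total")
    from scipy.special import gammaln

    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa  # one allele's total count; the label choice cancels
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    # log P(het | allele counts) up to a common constant:
    #   2^het / (nAA! * het! * naa!)  with nAA, naa determined by het
    n_aa_vec = (n_a - hets) // 2
    n_AA_vec = n - n_aa_vec - hets
    logp = (
        hets * math.log(2.0)
        - gammaln(n_AA_vec + 1)
        - gammaln(hets + 1)
        - gammaln(n_aa_vec + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    p = float(probs[probs <= p_obs * (1.0 + _FISHER_TIE_REL)].sum())
    return HweResult(n_AA, n_Aa, n_aa, min(p, 1.0))
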