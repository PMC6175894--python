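"""Pooling of per-study allelic effects across cohorts.

Three combination schemes are provided, matching the standard toolbox for
case-control replication studies:

* **fixed effects** — inverse-variance weighting of log odds ratios,
  with Cochran's Q and the I² heterogeneity percentage;
* **random effects** — DerSimonian-Laird moment estimate of the
  between-study variance tau², then inverse-variance pooling with the
  inflated weights 1/(se² + tau²);
* **weighted Z** — a signed Stouffer combination with weights
  proportional to the square root of the effective sample size
  Neff = 4 / (1/N_cases + 1/N_ctrls).

All p-values are two-sided from |Z| unless a one-sided value is requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .assoc import AlleleTable2x2, allelic_or
from .errors import MissingDirectionError, TooFewStudiesError

__all__ = ["StudyEffect", "MetaResult", "fixed_effects", "random_effects",
           "weighted_z", "heterogeneity_test", "meta_analyze", "effective_n",
           "study_from_table"]


@dataclass(frozen=True)
class StudyEffect:
    """One cohort's log odds ratio, its SE, p-value and sample sizes."""

    label: str
    log_or: float
    se: float
    p_two_sided: float | None = None
    direction: str | None = None  # "+" or "-"
    n_cases: int | None = None
    n_ctrls: int | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"study {self.label!r}: se must be positive")
        if self.p_two_sided is not None and not (0.0 < self.p_two_sided <= 1.0):
            raise ValueError(f"study {self.label!r}: p must lie in (0, 1]")
        if self.direction is not None and self.direction not in ("+", "-"):
            raise ValueError(f"study {self.label!r}: direction must be '+' or '-'")


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimates under all three schemes plus heterogeneity metrics.

    ``q_stat`` is Cochran's Q statistic and ``q_pvalue`` its chi-squared
    p-value; some tools print the p-value under the bare name "Q", so both
    are carried explicitly.
    """

    or_fixed: float
    p_fixed: float
    or_random: float
    p_random: float
    tau2: float
    z_weighted: float
    p_weighted_z: float
    q_stat: float
    q_pvalue: float
    i2: float
    n_eff_per_study: tuple[float, ...]


def study_from_table(label: str, t: AlleleTable2x2) -> StudyEffect:
    """Build a StudyEffect from raw allele counts (preferred over rounded
    published OR/SE pairs when counts are available)."""
    res = allelic_or(t)
    log_or = math.log(res.odds_ratio)
    return StudyEffect(
        label=label,
        log_or=log_or,
        se=res.se_log_or,
        p_two_sided=res.p_fisher_two_sided,
        direction="+" if log_or > 0 else "-",
        n_cases=t.n_case_alleles // 2,
        n_ctrls=t.n_ctrl_alleles // 2,
    )


def effective_n(n_cases: int, n_ctrls: int) -> float:
    """Effective sample size of an unbalanced case-control study."""
    return 4.0 / (1.0 / n_cases + 1.0 / n_ctrls)


def _check(studies: Sequence[StudyEffect]) -> None:
    if len(studies) < 2:
        raise TooFewStudiesError(f"need >= 2 studies, got {len(studies)}")


def _pool(studies: Sequence[StudyEffect], extra_var: float = 0.0) -> tuple[float, float, float]:
    """Inverse-variance pool; returns (pooled log OR, pooled SE, two-sided p)."""
    weights = [1.0 / (s.se ** 2 + extra_var) for s in studies]
    sw = sum(weights)
    pooled = sum(w * s.log_or for w, s in zip(weights, studies)) / sw
    se = math.sqrt(1.0 / sw)
    z = pooled / se
    p = 2.0 * stats.norm.sf(abs(z))
    return pooled, se, p


def heterogeneity_test(studies: Sequence[StudyEffect]) -> tuple[float, float, float]:
    """Cochran's Q, its chi-squared p-value (k-1 df) and I² in percent.

    I² = max(0, (Q - (k-1)) / Q) * 100, capped at 100.
    """
    _check(studies)
    k = len(studies)
    weights = [1.0 / s.se ** 2 for s in studies]
    sw = sum(weights)
    pooled = sum(w * s.log_or for w, s in zip(weights, studies)) / sw
    q = sum(w * (s.log_or - pooled) ** 2 for w, s in zip(weights, studies))
    q_p = float(stats.chi2.sf(q, k - 1))
    i2 = 0.0 if q <= 0 else max(0.0, min(100.0, (q - (k - 1)) / q * 100.0))
    return q, q_p, i2


def fixed_effects(studies: Sequence[StudyEffect]) -> tuple[float, float, float, float, float]:
    """Inverse-variance fixed-effects pooled OR with heterogeneity metrics.

    Returns (or_fixed, p_fixed, q_stat, q_pvalue, i2).
    """
    _check(studies)
    pooled, _, p = _pool(studies)
    q, q_p, i2 = heterogeneity_test(studies)
    return math.exp(pooled), p, q, q_p, i2


def random_effects(studies: Sequence[StudyEffect]) -> tuple[float, float, float]:
    """DerSimonian-Laird random-effects pooled OR.

    tau² = max(0, (Q - (k-1)) / (Σw - Σw²/Σw)) with fixed-effects weights w,
    then pooling with weights 1/(se² + tau²).  Returns (or_random, p_random,
    tau2); when tau² truncates to 0 the estimate equals fixed effects.
    """
    _check(studies)
    k = len(studies)
    weights = [1.0 / s.se ** 2 for s in studies]
    sw = sum(weights)
    sw2 = sum(w * w for w in weights)
    q, _, _ = heterogeneity_test(studies)
    denom = sw - sw2 / sw
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    pooled, _, p = _pool(studies, extra_var=tau2)
    return math.exp(pooled), p, tau2


def weighted_z(studies: Sequence[StudyEffect], one_sided: bool = False) -> tuple[float, float]:
    """Sample-size-weighted Z combination (signed Stouffer scheme).

    Each study contributes z_i = sign(direction) * Phi^-1(1 - p_i/2) with
    weight sqrt(Neff_i); the combined Z = Σ sqrt(Neff_i) z_i / sqrt(Σ Neff_i).
    Returns (z, p) with p two-sided from |Z| by default.  A single study
    is allowed (the combination degenerates to that study's own z and p).
    """
    if len(studies) < 1:
        raise TooFewStudiesError("need >= 1 study")
    num = 0.0
    denom = 0.0
    for s in studies:
        if s.direction is None or s.p_two_sided is None:
            raise MissingDirectionError(f"study {s.label!r} lacks p-value or direction")
        if s.n_cases is None or s.n_ctrls is None:
            raise MissingDirectionError(f"study {s.label!r} lacks sample sizes")
        z_i = stats.norm.isf(s.p_two_sided / 2.0)
        if s.direction == "-":
            z_i = -z_i
        neff = effective_n(s.n_cases, s.n_ctrls)
        num += math.sqrt(neff) * z_i
        denom += neff
    z = num / math.sqrt(denom)
    p = float(stats.norm.sf(abs(z)) if one_sided else 2.0 * stats.norm.sf(abs(z)))
    return z, p


def meta_analyze(studies: Sequence[StudyEffect]) -> MetaResult:
    """Run all three pooling schemes and return a combined result."""
    or_f, p_f, q, q_p, i2 = fixed_effects(studies)
    or_r, p_r, tau2 = random_effects(studies)
    z_w, p_w = weighted_z(studies)
    neff = tuple(
        effective_n(s.n_cases, s.n_ctrls) if s.n_cases and s.n_ctrls else float("nan")
        for s in studies
    )
    return MetaResult(or_f, p_f, or_r, p_r, tau2, z_w, p_w, q, q_p, i2, neff)
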