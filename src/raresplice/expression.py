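"""Expression-level statistics for the minor-isoform analyses.

Input is a tidy pandas DataFrame with one row per sample:

    sample_id, diagnosis, expression, [<snp>_carrier ...], [age_years], [region]

Expression values are relative units (normalised qPCR ratios with the
control mean near 1.0).  Carrier columns hold "carrier" / "non-carrier" /
"missing" under a dominant coding of the minor allele.

Provided tests:

* diagnosis-group differential expression (one-sided Welch t, fold change
  vs controls), optionally excluding carriers of a named SNP;
* high-expressor enrichment (Fisher exact on expression > threshold);
* carrier-vs-non-carrier rank-sum eQTL tests with fold change;
* age-split rank-sum tests per brain region with optional Bonferroni.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import AlleleTable2x2, allelic_or
from .errors import DegenerateTableError, EmptyGroupError

__all__ = ["DIAGNOSES", "DEResult", "de_by_group", "high_expressor_test",
           "eqtl_wilcoxon", "age_group_wilcoxon", "rank_sum_one_sided"]

# the closed diagnosis set; CTRL is the reference group
DIAGNOSES = ("CTRL", "MIX", "SCZ", "BDNOS", "BDI", "BDII")
# pooled psychosis-spectrum meta-group reported alongside the six groups
COMBINED_GROUP = "BDI&SCZ"
_COMBINED_MEMBERS = ("BDI", "SCZ")

EXACT_WILCOXON_MAX_N = 20


@dataclass(frozen=True)
class DEResult:
    """Differential expression of one diagnosis group vs controls."""

    group: str
    n: int
    mean_expr: float
    fold_change: float
    p_one_sided: float


def _carrier_mask(df: pd.DataFrame, snp_id: str) -> pd.Series:
    col = f"{snp_id}_carrier" if f"{snp_id}_carrier" in df.columns else snp_id
    if col not in df.columns:
        raise KeyError(f"no carrier column for SNP {snp_id!r}")
    return df[col].astype(str) == "carrier"


def rank_sum_one_sided(x: np.ndarray, y: np.ndarray, alternative: str = "greater") -> float:
    """One-sided Wilcoxon rank-sum p-value for x vs y.

    Exact enumeration when both groups have <= 20 observations and the
    pooled values are tie-free; otherwise the normal approximation with
    tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    small = len(x) <= EXACT_WILCOXON_MAX_N and len(y) <= EXACT_WILCOXON_MAX_N
    method = "exact" if (tie_free and small) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.pvalue)


def de_by_group(records: pd.DataFrame, exclude_carriers_of: str | None = None,
                include_combined: bool = True) -> list[DEResult]:
    """Per-diagnosis mean expression, fold change vs CTRL and one-sided
    Welch t-test of higher expression in the group than in controls.

    With ``exclude_carriers_of`` set, carriers of that SNP's minor allele
    are dropped from every group (controls included) before testing.
    """
    df = records
    if exclude_carriers_of is not None:
        df = df[~_carrier_mask(df, exclude_carriers_of)]
    ctrl = df.loc[df["diagnosis"] == "CTRL", "expression"].to_numpy(float)
    if ctrl.size == 0:
        raise EmptyGroupError("control group is empty")
    ctrl_mean = ctrl.mean()
    groups = [g for g in DIAGNOSES if g != "CTRL"]
    out = [DEResult("CTRL", ctrl.size, ctrl_mean, 1.0, math.nan)]
    for group in groups + ([COMBINED_GROUP] if include_combined else []):
        members = _COMBINED_MEMBERS if group == COMBINED_GROUP else (group,)
        vals = df.loc[df["diagnosis"].isin(members), "expression"].to_numpy(float)
        if vals.size == 0:
            raise EmptyGroupError(f"diagnosis group {group!r} is empty")
        t = stats.ttest_ind(vals, ctrl, equal_var=False, alternative="greater")
        out.append(DEResult(group, vals.size, vals.mean(), vals.mean() / ctrl_mean,
                            float(t.pvalue)))
    return out


def high_expressor_test(records: pd.DataFrame, group: str,
                        threshold: float = 1.5) -> tuple[float, float]:
    """Fisher exact test of high expression (> threshold) in a diagnosis
    group vs controls; returns (odds_ratio, p_two_sided).

    The OR measures enrichment of high expressors in the group; zero cells
    receive the Haldane-Anscombe correction inside the OR machinery.
    """
    members = _COMBINED_MEMBERS if group == COMBINED_GROUP else (group,)
    g = records.loc[records["diagnosis"].isin(members), "expression"].to_numpy(float)
    c = records.loc[records["diagnosis"] == "CTRL", "expression"].to_numpy(float)
    if g.size == 0 or c.size == 0:
        raise EmptyGroupError("group and CTRL must both be non-empty")
    table = AlleleTable2x2(
        int((g > threshold).sum()), int((g <= threshold).sum()),
        int((c > threshold).sum()), int((c <= threshold).sum()),
    )
    try:
        res = allelic_or(table, protective_direction=False)
    except DegenerateTableError:
        # no high expressor in either group: no evidence of enrichment
        return 1.0, 1.0
    return res.odds_ratio, res.p_fisher_two_sided


def eqtl_wilcoxon(records: pd.DataFrame, snp_id: str, direction: str = "greater",
                  exclude_carriers_of: str | None = None) -> tuple[float, float]:
    """Carrier-vs-non-carrier expression test for one SNP.

    Returns (fold_change, p) where the fold change is
    mean(carriers) / mean(non-carriers) and p is the one-sided rank-sum
    p-value in the stated direction ("greater" for risk alleles expected
    to raise expression, "less" for the protective splice-site allele).
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    df = records
    if exclude_carriers_of is not None:
        df = df[~_carrier_mask(df, exclude_carriers_of)]
    col = f"{snp_id}_carrier" if f"{snp_id}_carrier" in df.columns else snp_id
    known = df[df[col].astype(str).isin(["carrier", "non-carrier"])]
    carriers = known.loc[known[col] == "carrier", "expression"].to_numpy(float)
    noncar = known.loc[known[col] == "non-carrier", "expression"].to_numpy(float)
    if carriers.size == 0 or noncar.size == 0:
        raise EmptyGroupError(f"{snp_id}: empty carrier or non-carrier group")
    fc = carriers.mean() / noncar.mean()
    p = rank_sum_one_sided(carriers, noncar, alternative=direction)
    return float(fc), p


def age_group_wilcoxon(records: pd.DataFrame, split_age: float = 10.0,
                       by_region: bool = True,
                       correction: str = "bonferroni") -> pd.DataFrame:
    """Rank-sum tests of higher expression in the older age stratum.

    Samples aged > ``split_age`` years form the older group (i.e. ages 11+
    with the default split against ages 0-10).  With ``by_region`` a test
    is run per region plus a pooled all-region row; regions with an empty
    stratum are skipped.  ``correction`` in {"none", "bonferroni"} controls
    the adjusted p-value across regions.

    Returns a DataFrame with columns region, n_young, n_old, p, p_adjusted.
    """
    if correction not in ("none", "bonferroni"):
        raise ValueError("correction must be 'none' or 'bonferroni'")
    df = records.dropna(subset=["age_years"])
    regions = sorted(df["region"].dropna().unique()) if by_region else []
    rows = []
    for region in regions:
        sub = df[df["region"] == region]
        young = sub.loc[sub["age_years"] <= split_age, "expression"].to_numpy(float)
        old = sub.loc[sub["age_years"] > split_age, "expression"].to_numpy(float)
        if young.size == 0 or old.size == 0:
            continue  # empty stratum: nothing to test in this region
        p = rank_sum_one_sided(old, young, alternative="greater")
        rows.append({"region": region, "n_young": young.size, "n_old": old.size, "p": p})
    n_tests = max(len(rows), 1)
    for r in rows:
        r["p_adjusted"] = r["p"] if correction == "none" else min(1.0, r["p"] * n_tests)
    young = df.loc[df["age_years"] <= split_age, "expression"].to_numpy(float)
    old = df.loc[df["age_years"] > split_age, "expression"].to_numpy(float)
    if young.size and old.size:
        p_all = rank_sum_one_sided(old, young, alternative="greater")
        rows.append({"region": "ALL", "n_young": young.size, "n_old": old.size,
                     "p": p_all, "p_adjusted": p_all})
    return pd.DataFrame(rows, columns=["region", "n_young", "n_old", "p", "p_adjusted"])
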