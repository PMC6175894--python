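"""Expression statistics: Welch t differential expression, high-expressor
Fisher test, carrier rank-sum eQTL tests and age-split tests, with exact
enumeration oracles and null calibration."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import wilcoxon_oracle
from raresplice.errors import EmptyGroupError
from raresplice.expression import (age_group_wilcoxon, de_by_group,
                                   eqtl_wilcoxon, high_expressor_test,
                                   rank_sum_one_sided)


def _frame(groups: dict[str, list[float]], carrier: dict[str, str] | None = None):
    rows = []
    for g, vals in groups.items():
        for i, v in enumerate(vals):
            sid = f"{g}_{i}"
            rows.append({"sample_id": sid, "diagnosis": g, "expression": v,
                         "snp1_carrier": (carrier or {}).get(sid, "non-carrier")})
    return pd.DataFrame(rows)


def test_de_fold_change_is_mean_ratio():
    rng = np.random.default_rng(0)
    df = _frame({"CTRL": list(rng.normal(0.982, 0.2, 50)),
                 "BDI": list(rng.normal(1.064, 0.2, 40)),
                 "MIX": [1.0] * 5, "SCZ": [1.1] * 5, "BDNOS": [1.0] * 5,
                 "BDII": [0.9] * 5})
    res = {r.group: r for r in de_by_group(df)}
    ctrl_mean = df.loc[df.diagnosis == "CTRL", "expression"].mean()
    for g, r in res.items():
        if g == "CTRL":
            continue
        assert r.fold_change == pytest.approx(r.mean_expr / ctrl_mean, abs=1e-9)


def test_de_identical_groups_null():
    vals = list(np.linspace(0.8, 1.2, 20))
    df = _frame({"CTRL": vals, "BDI": vals, "MIX": vals, "SCZ": vals,
                 "BDNOS": vals, "BDII": vals})
    res = {r.group: r for r in de_by_group(df)}
    assert res["BDI"].fold_change == pytest.approx(1.0)
    assert res["BDI"].p_one_sided >= 0.5


def test_de_welch_matches_closed_form():
    """One-sided Welch p for two small vectors equals the closed-form t
    with Satterthwaite degrees of freedom."""
    from scipy import stats

    x = np.array([1.2, 1.4, 1.1, 1.3])
    y = np.array([1.0, 0.9, 1.05, 0.95, 1.0])
    df = _frame({"CTRL": list(y), "BDI": list(x), "MIX": [1.0] * 3,
                 "SCZ": [1.0] * 3, "BDNOS": [1.0] * 3, "BDII": [1.0] * 3})
    res = {r.group: r for r in de_by_group(df, include_combined=False)}
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    dof = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))
    assert res["BDI"].p_one_sided == pytest.approx(stats.t.sf(t, dof), rel=1e-9)


def test_de_excluding_carriers_drops_them_everywhere():
    carrier = {"CTRL_0": "carrier", "BDI_0": "carrier"}
    df = _frame({"CTRL": [0.2, 1.0, 1.0], "BDI": [0.2, 1.1, 1.1],
                 "MIX": [1.0], "SCZ": [1.0], "BDNOS": [1.0], "BDII": [1.0]},
                carrier)
    with_all = {r.group: r for r in de_by_group(df)}
    excl = {r.group: r for r in de_by_group(df, exclude_carriers_of="snp1")}
    assert excl["CTRL"].n == with_all["CTRL"].n - 1
    assert excl["BDI"].n == with_all["BDI"].n - 1
    assert excl["BDI"].mean_expr > with_all["BDI"].mean_expr


def test_de_empty_group_raises():
    df = _frame({"CTRL": [1.0, 1.1], "BDI": [1.0], "MIX": [1.0],
                 "SCZ": [1.0], "BDNOS": [1.0], "BDII": [1.0]})
    with pytest.raises(EmptyGroupError):
        de_by_group(df[df.diagnosis != "BDII"])


def test_high_expressor_none_above_threshold():
    df = _frame({"CTRL": [1.0] * 10, "BDI": [1.1] * 10, "MIX": [1.0],
                 "SCZ": [1.0], "BDNOS": [1.0], "BDII": [1.0]})
    or_, p = high_expressor_test(df, "BDI")
    assert (or_, p) == (1.0, 1.0)


def test_high_expressor_doubling_invariance():
    vals = {"CTRL": [1.0] * 266 + [1.6] * 3, "BDI": [1.0] * 132 + [1.6] * 8,
            "MIX": [1.0], "SCZ": [1.0], "BDNOS": [1.0], "BDII": [1.0]}
    df = _frame(vals)
    doubled = _frame({g: v * 2 for g, v in vals.items()})
    or1, _ = high_expressor_test(df, "BDI")
    or2, _ = high_expressor_test(doubled, "BDI")
    assert or1 == pytest.approx(or2)


def test_high_expressor_counts_match_fisher_oracle():
    from conftest import fisher_oracle

    df = _frame({"CTRL": [1.0] * 266 + [1.6] * 3, "BDI": [1.0] * 132 + [1.6] * 8,
                 "MIX": [1.0], "SCZ": [1.0], "BDNOS": [1.0], "BDII": [1.0]})
    or_, p = high_expressor_test(df, "BDI")
    assert or_ == pytest.approx((8 * 266) / (132 * 3))
    assert p == pytest.approx(fisher_oracle(8, 132, 3, 266, side="two"), rel=1e-9)


def test_eqtl_carriers_at_half_expression():
    carrier = {f"CTRL_{i}": "carrier" for i in range(4)}
    df = _frame({"CTRL": [0.5] * 4 + [1.0] * 8, "BDI": [1.0], "MIX": [1.0],
                 "SCZ": [1.0], "BDNOS": [1.0], "BDII": [1.0]}, carrier)
    fc, p = eqtl_wilcoxon(df, "snp1", direction="less")
    assert fc == pytest.approx(0.5)
    # all carriers rank below all non-carriers (ties within groups):
    # the asymptotic tail probability is small
    assert p < 0.01


def test_eqtl_identical_groups():
    vals = np.linspace(0.8, 1.2, 12)
    carrier = {f"CTRL_{i}": "carrier" for i in range(0, 12, 2)}
    df = _frame({"CTRL": list(vals), "BDI": [1.0], "MIX": [1.0],
                 "SCZ": [1.0], "BDNOS": [1.0], "BDII": [1.0]}, carrier)
    _, p = eqtl_wilcoxon(df, "snp1", direction="less")
    assert 0.3 < p < 0.7


def test_eqtl_six_vs_six_full_enumeration():
    rng = np.random.default_rng(4)
    vals = list(rng.normal(1.0, 0.2, 12))
    carrier = {f"CTRL_{i}": "carrier" for i in range(6)}
    # samples with unknown genotype stay out of both groups
    carrier.update({f"{g}_0": "missing" for g in ("BDI", "MIX", "SCZ", "BDNOS", "BDII")})
    df = _frame({"CTRL": vals, "BDI": [1.0], "MIX": [1.0],
                 "SCZ": [1.0], "BDNOS": [1.0], "BDII": [1.0]}, carrier)
    fc, p = eqtl_wilcoxon(df, "snp1", direction="less")
    x, y = np.array(vals[:6]), np.array(vals[6:])
    assert p == pytest.approx(wilcoxon_oracle(x, y, "less"), rel=1e-9)


def test_eqtl_empty_group_raises():
    df = _frame({"CTRL": [1.0, 1.1], "BDI": [1.0], "MIX": [1.0],
                 "SCZ": [1.0], "BDNOS": [1.0], "BDII": [1.0]})
    with pytest.raises(EmptyGroupError):
        eqtl_wilcoxon(df, "snp1", direction="less")


@given(n1=st.integers(2, 7), n2=st.integers(2, 7), seed=st.integers(0, 10_000))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_wilcoxon_matches_enumeration_small_samples(n1, n2, seed):
    """Exact rank-sum p equals full enumeration for all n1+n2 <= 14."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n1)
    y = rng.normal(0.3, 1, n2)
    for alt in ("greater", "less"):
        assert rank_sum_one_sided(x, y, alt) == pytest.approx(
            wilcoxon_oracle(x, y, alt), rel=1e-9)


def test_one_sided_tests_uniform_under_null():
    """Type-I error at alpha = 0.05 stays within [0.03, 0.07] when both
    groups are drawn from the same distribution (2000 simulations)."""
    rng = np.random.default_rng(77)
    rejections = 0
    n_sim = 2000
    for _ in range(n_sim):
        x = rng.normal(1.0, 0.25, 12)
        y = rng.normal(1.0, 0.25, 12)
        if rank_sum_one_sided(x, y, "greater") < 0.05:
            rejections += 1
    assert 0.03 <= rejections / n_sim <= 0.07


def _age_frame(rng, regions, effect=0.0, n=20):
    rows = []
    for region in regions:
        for age, shift in ((5.0, 0.0), (20.0, effect)):
            for v in rng.normal(1.0 + shift, 0.25, n):
                rows.append({"sample_id": f"{region}_{age}_{len(rows)}",
                             "diagnosis": "CTRL", "expression": v,
                             "age_years": age, "region": region})
    return pd.DataFrame(rows)


def test_age_split_detects_simulated_effect():
    """Older-group shift of 1.5 sd is detected at 5% in >= 90% of 200
    seeded replicates (n = 20 per stratum)."""
    hits = 0
    for seed in range(200):
        rng = np.random.default_rng(seed)
        df = _age_frame(rng, ["ROI"], effect=1.5 * 0.25)
        res = age_group_wilcoxon(df, by_region=False)
        hits += float(res.loc[res.region == "ALL", "p"].iloc[0]) < 0.05
    assert hits >= 180


def test_age_split_null_and_bonferroni():
    rng = np.random.default_rng(123)
    regions = [f"R{i:02d}" for i in range(16)]
    df = _age_frame(rng, regions, effect=0.0)
    # inject one real effect in the last region
    df.loc[(df.region == "R15") & (df.age_years > 10), "expression"] += 1.5 * 0.25
    res = age_group_wilcoxon(df, by_region=True, correction="bonferroni")
    by_region = res[res.region != "ALL"].set_index("region")
    assert by_region.loc["R15", "p_adjusted"] < 0.05
    others = by_region.drop("R15")
    assert (others["p_adjusted"] > 0.05).mean() > 0.9


def test_age_split_identical_strata():
    df = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(20)],
        "diagnosis": ["CTRL"] * 20,
        "expression": list(np.linspace(0.8, 1.2, 10)) * 2,
        "age_years": [5.0] * 10 + [20.0] * 10,
        "region": ["ROI"] * 20,
    })
    res = age_group_wilcoxon(df, by_region=False)
    assert 0.3 < res.loc[res.region == "ALL", "p"].iloc[0] < 0.7
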