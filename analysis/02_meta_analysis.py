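"""Pool the seven published per-study effects (four bipolar, three
schizophrenia cohorts) with fixed-effects, DerSimonian-Laird random-effects
and sample-size-weighted-Z models, plus Cochran's Q and I² heterogeneity.

Inputs are the printed per-study OR/SE/p rows; the pooled estimates land
on the printed values (fixed 0.60/0.74, random ~0.50/0.53) with I² around
52% (BD) and 79% (SCZ), and the weighted-Z p-values in the 1e-4/1e-3
range that flags both phenotypes as significant.

Writes results/meta_report.tsv and results/forest.tsv.
"""

from pathlib import Path

from raresplice.io import write_tsv
from raresplice.reproduce import forest_data, meta_report

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rep = meta_report()
    write_tsv(rep, OUT / "meta_report.tsv",
              "q_stat is Cochran's Q; q_pvalue its chi-squared p-value")
    write_tsv(forest_data(), OUT / "forest.tsv", "per-study OR with 95% Wald CI")
    for r in rep.itertuples():
        print(f"{r.phenotype}: fixed OR {r.or_fixed:.2f} (p {r.p_fixed:.1e}), "
              f"random OR {r.or_random:.2f}, I2 {r.i2:.1f}%, "
              f"weighted-Z p {r.p_weighted_z:.1e}")
    assert bool(rep[["or_fixed_pass", "or_random_pass", "i2_pass"]].all().all())


if __name__ == "__main__":
    main()
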