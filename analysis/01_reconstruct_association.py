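"""Reconstruct per-cohort allele counts from the published sample sizes and
3-decimal minor-allele frequencies, and recompute the allelic association
statistics for the protective splice-site allele.

Counts are unique for three of the seven cohorts (Norway BD, Norway SCZ,
Denmark BD); for the larger cohorts the frequency rounding admits several
integers, so the recomputed columns stay NA and the printed OR/SE carry
through to the meta-analysis instead.

Writes results/association_report.tsv.
"""

from pathlib import Path

from raresplice.io import write_tsv
from raresplice.reproduce import association_report

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rep = association_report()
    write_tsv(rep, OUT / "association_report.tsv",
              "recomputed allelic OR/SE from reconstructed counts vs printed values")
    uniq = rep[rep["unique_counts"]]
    print(f"{len(uniq)}/{len(rep)} cohorts admit unique count reconstruction")
    for r in uniq.itertuples():
        print(f"  {r.cohort} {r.phenotype}: OR {r.or_recomputed:.2f} "
              f"(printed {r.or_printed}), SE {r.se_recomputed:.2f} (printed {r.se_printed})")
    assert bool(uniq["or_pass"].all() and uniq["se_pass"].all()), \
        "recomputed OR/SE disagree with printed values"


if __name__ == "__main__":
    main()
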