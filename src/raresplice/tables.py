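"""Published case-control summaries for the protective splice-site allele.

Seven independent North-European cohorts (four bipolar disorder, three
schizophrenia) with printed sample sizes and 3-decimal minor-allele
frequencies for rs41283526*G, plus the printed per-cohort odds ratios,
standard errors and Fisher p-values used as plausibility anchors.  These
printed values are the pipeline's input for the reproduction run: allele
counts are reconstructed from n and frequency where the rounding admits a
unique integer, and the published OR/SE are used for cohorts where it
does not (frequency rounding makes counts ambiguous for the two largest
cohorts).
"""

from __future__ import annotations

import math

from .assoc import CohortSummary
from .meta import StudyEffect

__all__ = ["COHORTS", "PRINTED", "cohort_summaries", "printed_study_effects"]

# label, phenotype, n_cases, n_ctrls, maf_cases, maf_ctrls,
# printed OR, printed SE(log OR), printed two-sided p, printed one-sided p
COHORTS = [
    ("Norway", "BD", 504, 369, 0.008, 0.031, 0.25, 0.41, 3.6e-4, 2.8e-4),
    ("Sweden", "BD", 2286, 5412, 0.012, 0.016, 0.72, 0.16, 4.0e-2, 2.1e-2),
    ("Denmark", "BD", 193, 696, 0.008, 0.016, 0.49, 0.62, 3.3e-1, 1.7e-1),
    ("Germany", "BD", 895, 2367, 0.006, 0.012, 0.51, 0.33, 4.0e-2, 2.1e-2),
    ("Norway", "SCZ", 411, 369, 0.005, 0.031, 0.15, 0.54, 5.4e-5, 4.6e-5),
    ("Sweden", "SCZ", 4822, 6088, 0.014, 0.018, 0.81, 0.11, 6.6e-2, 3.3e-2),
    ("Denmark", "SCZ", 1872, 1091, 0.009, 0.014, 0.64, 0.25, 8.7e-2, 5.0e-2),
]

# printed meta-analysis values (plausibility anchors for the reproduction
# report): fixed OR, random OR, weighted-Z p, Q p-value, I2
PRINTED = {
    "BD": {"or_fixed": 0.60, "p_fixed": 1.2e-4, "or_random": 0.50, "p_random": 5.1e-3,
           "p_weighted_z": 6.8e-5, "q_pvalue": 0.10, "i2": 52.20},
    "SCZ": {"or_fixed": 0.74, "p_fixed": 2.5e-3, "or_random": 0.53, "p_random": 5.4e-2,
            "p_weighted_z": 8.2e-4, "q_pvalue": 0.01, "i2": 79.10},
}


def cohort_summaries(phenotype: str | None = None) -> list[CohortSummary]:
    """CohortSummary objects for the published cohorts, optionally filtered."""
    return [
        CohortSummary(n_cases, n_ctrls, maf_ca, maf_co, label=f"{label} {pheno}",
                      phenotype=pheno)
        for label, pheno, n_cases, n_ctrls, maf_ca, maf_co, *_ in COHORTS
        if phenotype is None or pheno == phenotype
    ]


def printed_study_effects(phenotype: str) -> list[StudyEffect]:
    """StudyEffect rows built from the printed OR, SE, p and sample sizes.

    The protective allele makes every direction '-'.
    """
    out = []
    for label, pheno, n_cases, n_ctrls, _, _, or_, se, p2, _ in COHORTS:
        if pheno != phenotype:
            continue
        out.append(StudyEffect(
            label=f"{label} {pheno}", log_or=math.log(or_), se=se,
            p_two_sided=p2, direction="-", n_cases=n_cases, n_ctrls=n_ctrls,
        ))
    return out
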