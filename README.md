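# raresplice

Analysis pipeline around a rare protective splice-site allele
(rs41283526\*G) of a minor *ANK3* isoform and its role in bipolar
disorder (BD) and schizophrenia (SCZ): rare-allele case-control
association with meta-analysis across cohorts, linkage-disequilibrium
haploblock structure, genotype- and diagnosis-stratified expression
tests, and splice-pattern classification of noisy full-length cDNA long
reads. It is written for statistical geneticists who want each stage as
a tested, reusable library function rather than a chain of external
tools.

The raw genotype, qPCR and sequencing data behind the original analyses
were never deposited, so the package ships seeded generators
(`raresplice.simulate`) that produce every input with the statistical
structure the analyses assume, together with the hidden ground truth
needed to validate each stage. The published cohort summary table
(sample sizes, 3-decimal allele frequencies, per-study OR/SE) is packaged
as data and drives a full reproduction of the association and
meta-analysis results.

## What it computes

**Allelic association** (`raresplice.assoc`). For a biallelic SNP the
cohort is a 2×2 table of minor/major allele counts in cases and
controls. The allelic odds ratio and its log-scale standard error are

    OR = (a·d)/(b·c),    SE(log OR) = √(1/a + 1/b + 1/c + 1/d),

with a Wald 95% CI `exp(log OR ± 1.96·SE)`, exact Fisher tests in both
tails (two-sided by the point-probability rule), the Haldane–Anscombe
+0.5 correction only when a cell is zero, and the exact conditional
Hardy–Weinberg test. `counts_from_summary` reconstructs integer allele
counts from published n and rounded frequencies, refusing when the
rounding admits more than one integer.

**Meta-analysis** (`raresplice.meta`). Inverse-variance fixed effects,
DerSimonian–Laird random effects

    τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)),   w* = 1/(se² + τ²),

Cochran's Q with I² = max(0, (Q−(k−1))/Q)·100, and the sample-size
weighted-Z combination with weights √Neff, Neff = 4/(1/N_cases +
1/N_ctrls).

**LD and haploblocks** (`raresplice.ld`). Two-locus haplotype
frequencies from unphased dosages by EM (double heterozygotes split in
the ratio p_AB·p_ab : p_Ab·p_aB), D′ and r² from the fitted
frequencies, and a greedy four-gamete-rule partition into haploblocks
(a block may not contain a site pair with all four gametes above 1%).

**Expression tests** (`raresplice.expression`). One-sided Welch t tests
of elevated expression per diagnosis group with fold changes vs
controls, a Fisher test of high-expressor (>1.5) enrichment,
carrier-vs-non-carrier Wilcoxon eQTL tests (exact for small tie-free
groups), and age-split rank-sum tests per brain region.

**Long-read isoforms** (`raresplice.isoform`). QC (length 2.7–3.3 kbp,
mean per-base accuracy ≥ 85%), approximate exon detection (any 18-mer
of the exon within edit distance 2 of the read, indels included),
TSS assignment from first-exon markers, splice patterns alt-0 / alt-1 /
alt-2 over the two cassette exons (“medium”, 54-nt “little”), and
per-sample abundance summaries with a 1% reporting threshold.

## Worked example

```python
from raresplice.assoc import CohortSummary, counts_from_summary, allelic_or
from raresplice.meta import meta_analyze
from raresplice.tables import printed_study_effects

t = counts_from_summary(CohortSummary(504, 369, 0.008, 0.031))
print(t)                       # case 8/1000, control 23/715 minor/major alleles
r = allelic_or(t)
print(round(r.odds_ratio, 2), round(r.se_log_or, 2))   # 0.25 0.41
print(f"{r.p_fisher_one_sided:.1e}")                   # 2.8e-04

m = meta_analyze(printed_study_effects("BD"))
print(round(m.or_fixed, 2), round(m.or_random, 2), round(m.i2, 1))
# 0.6 0.51 51.7
```

The first block reconstructs the Norwegian BD cohort's allele counts
from its printed sizes and frequencies and recovers the published
allelic OR 0.25 (SE 0.41) with a one-sided Fisher p of 2.8×10⁻⁴ — the
protective direction. The second pools the four BD cohorts: fixed
effects 0.60, random effects ≈0.50 with I² ≈ 52% (substantial
heterogeneity, so the random-effects estimate is the one to trust).

The numbered drivers under `analysis/` run each stage end to end and
write their tables to `results/`:

```sh
python analysis/01_reconstruct_association.py
python analysis/02_meta_analysis.py
python analysis/03_ld_blocks.py
python analysis/04_expression_tests.py
python analysis/05_isoform_abundance.py
```

For instance `05_isoform_abundance.py` simulates 1500 noisy ~3 kbp
reads at an alt-1-dominant mixture and reports the recovered fractions
(`alt-1 0.834` vs simulated 0.84, `alt-2 0.157` vs 0.15).

There is also a CLI (`raresplice --help`) with subcommands `simulate`,
`assoc`, `meta`, `ld`, `blocks`, `express`, `eqtl`, `isoform` and
`reproduce`.

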