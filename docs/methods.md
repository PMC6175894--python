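# Methods

This note records the statistical models, the parameter choices and
their rationale, what the synthetic data do and do not emulate, and the
numerical conventions the implementation commits to.

## Allelic association

The unit of analysis is the allele: a diploid cohort of N cases and M
controls contributes 2N and 2M alleles, summarised as a 2×2 table of
minor/major counts. This matches the allelic (not genotypic) test that
is standard for variants too rare for genotype-level models.

*Count reconstruction.* Published tables print sample sizes and allele
frequencies rounded to three decimals. A frequency f over 2n alleles is
consistent with every integer c in [(f−0.0005)·2n, (f+0.0005)·2n);
`counts_from_summary` accepts the reconstruction only when that
interval contains exactly one integer and raises `AmbiguousCountError`
otherwise. Of the seven packaged cohorts, three reconstruct uniquely
(Norway BD, Norway SCZ, Denmark BD); the larger Swedish, German and
Danish-SCZ cohorts do not, which is why the meta-analysis consumes the
printed per-study OR/SE rows rather than reconstructed counts.

*OR, SE, CI.* Woolf's SE on the log scale and a Wald 95% CI; the CI is
symmetric on the log scale, matching how the original intervals were
drawn. The Haldane–Anscombe +0.5 correction is applied to all four
cells only when some cell is zero, and the result carries a flag saying
the correction fired; tables with all cells positive are untouched.

*Fisher tests.* The two-sided p-value sums hypergeometric point
probabilities ≤ the observed one, with a relative tie tolerance of
1e−7 (floating-point near-ties are common in this sum; the tolerance
matches the dominant convention). The one-sided test defaults to the
lower tail of the case minor-allele count because the allele under
study was pre-specified as protective. The p-values are computed by a
vectorised scan of the hypergeometric support; the test suite checks
them against an independent exact-rational enumeration for all table
sizes up to total 200.

*Hardy–Weinberg.* The exact conditional test: given the allele counts,
heterozygote counts of the same parity are enumerated, and
configurations no more probable than the observed one are summed
(log-gamma weights, normalised in a numerically safe way). No mid-p
correction.

## Meta-analysis

Fixed effects use inverse-variance weights w = 1/se²; Cochran's
Q = Σw(θ̂ᵢ − θ̂)² has k−1 degrees of freedom and
I² = max(0, (Q−(k−1))/Q)·100, floored at 0 and capped at 100. Random
effects use the DerSimonian–Laird moment estimator of τ² with
re-weighting w* = 1/(se²+τ²); when τ² truncates to zero the estimate
coincides with fixed effects by construction. The weighted-Z scheme
converts each study's two-sided p to a signed quantile
zᵢ = sign·Φ⁻¹(1−p/2) and combines with weights √Neff,
Neff = 4/(1/N_cases+1/N_ctrls); it deliberately ignores the effect
magnitudes, so it is the model least sensitive to rounding of the
printed ORs. All pooled p-values are two-sided from |Z|.

Because some tools print the heterogeneity p-value under the bare
heading "Q", the result object and all outputs carry `q_stat` and
`q_pvalue` as separate, unambiguous fields.

One caveat discovered while testing: I² is *not* invariant under
rescaling the weights alone (Q scales linearly with them and the k−1
term does not); it is invariant under a change of effect units, i.e.
rescaling log-OR and SE together, and that is the invariance the suite
asserts.

The implementation is cross-checked in the tests against the R
`metafor` package (FE and DL models) on the packaged BD rows.

## LD and haploblocks

Two-locus haplotype frequencies are estimated from unphased dosages by
EM. Only double heterozygotes are phase-ambiguous; each iteration
splits them between the coupling (AB/ab) and repulsion (Ab/aB)
resolutions in the ratio p_AB·p_ab : p_Ab·p_aB. Initialisation is at
linkage equilibrium (products of allele frequencies) with no random
restarts — the two-locus likelihood is well behaved and a
deterministic start keeps results reproducible. Convergence: max
|Δfreq| < 1e−8 or 1000 iterations. Missing data are handled
pairwise-complete per site pair. The suite checks the EM optimum
against a 1-D grid search of the multinomial likelihood (all other
frequencies are fixed by the allele-frequency margins) and checks
recovery of true pool frequencies on phased synthetic data (max error
< 3/√n at n = 500).

D = p_AB − p_A·p_B with D′ = |D|/D_max (D_max = min(p_A q_B, q_A p_B)
for D>0, else min(p_A p_B, q_A q_B)) and r² = D²/(p_A q_A p_B q_B).
Monomorphic pairs return zeros with an explicit flag rather than NaN.

Haploblocks follow the four-gamete rule: a pair of sites showing all
four gametes above a frequency threshold (default 1%, strict >) is
evidence of historical recombination, and a greedy left-to-right scan
closes the current block just before any site that would create such a
pair. The rule is applied to **all** pairs within the candidate block
(conservative reading; an adjacent-only variant is available via
`all_pairs=False`), and gamete frequencies are the EM estimates, since
only unphased data exist in the emulated study. Blocks tile the site
list without overlap by construction.

## Expression tests

Inputs are tidy per-sample records on a relative scale normalised so
the control mean is ≈1.0; the six diagnosis labels (CTRL, MIX, SCZ,
BDNOS, BDI, BDII) are closed, with a pooled BDI&SCZ meta-group
reported alongside. Differential expression uses one-sided Welch t
tests (group > CTRL); the equal-variance assumption is avoided because
group sizes and spreads differ visibly in this design. Fold change is
the ratio of group means and is recomputed from the reported means to
1e−9 in the suite. Excluding carriers of a named SNP drops them from
both the group and the controls before testing.

The high-expressor test dichotomises at 1.5 (on the normalised scale)
and runs the same Fisher machinery as the association module; a table
with no high expressor in either group returns OR 1, p 1.

eQTL tests are one-sided Wilcoxon rank-sum comparisons of carriers vs
non-carriers under a dominant coding — exact when both groups have ≤20
tie-free observations, otherwise the normal approximation with tie and
continuity corrections. Risk alleles are tested for higher expression
in carriers; the protective splice-site allele for lower. Age-split
tests compare samples above vs at-or-below a 10-year cut per brain
region, with optional Bonferroni across regions (the original
correction method is unstated; Bonferroni is our choice and is flagged
as such).

## Long-read splice-pattern classification

Quality semantics: per-base accuracy is 1 − 10^(−Q/10) from Phred+33,
and "mean read quality ≥ 85%" means mean per-base accuracy ≥ 0.85.
Both QC bounds are inclusive (length 2700–3300 bp; the accuracy bound
gets a 1e−9 tolerance so that repeated-value float summation cannot
flip the boundary case).

An exon is "present" when at least one of its 18-mers occurs in the
read within edit distance 2 — true edit distance including indels,
because indels dominate the platform's error profile. One hit suffices
by default (the 54-nt little exon yields only 37 k-mers, so demanding
more would cost sensitivity); a stricter `min_hits` is exposed. The
search runs exon-k-mers-against-the-read (the direction is a
convention we fix and document). Implementation: banded semi-global
alignment via edlib, pruned by a pigeonhole seed index — a k-mer
within 2 edits of a read window must share one of its three 6-mer
thirds with the window exactly, so only seeded windows are aligned.
The suite proves equality with a dense dynamic-programming scan on
reads up to 500 nt.

Chance matches are a property of the criterion itself: for random
54-nt exons vs random 3-kbp reads the measured hit rate is ≈2% per
read (oracle-confirmed), which bounds how cleanly absent exons can be
declared absent at these settings.

Classification scans both the forward read and its reverse complement
and keeps the orientation detecting more exons (ties → forward). The
TSS is the unique first-exon marker detected (none/ambiguous for 0/≥2);
splice patterns follow the grammar alt-0 (neither cassette exon), alt-1
(medium only), alt-2 (medium+little), with little-without-medium
flagged inconsistent. Reads with unresolved TSS or inconsistent
patterns are excluded from abundance denominators but counted in the QC
report. Abundance reporting keeps the union of patterns reaching 1% in
at least one sample (threshold applied after exclusions) and pools the
rest as "other".

## Synthetic data

The generators produce the study's input shapes with known truth:

* **Cohorts** — control allele draws Binomial(2n, maf); the case MAF
  solves odds(p) = OR·odds(maf); genotypes in Hardy–Weinberg
  proportions. Default reproduction scenario: 2000/2000 samples, control
  MAF 2%, OR 0.5.
* **Expression** — expression = ctrl_mean × FC(diagnosis) ×
  (carrier_effect if carrier) × noise, with truncated-normal noise on
  the ratio scale (the observed spread is roughly symmetric around 1.0;
  a log-normal mode supplies the heavy right tail the high-expressor
  test needs). Defaults follow the blood cohort layout (269 CTRL, 123
  MIX, 309 SCZ, 19 BDNOS, 140 BDI, 59 BDII), fold changes 0.96–1.08,
  sd 0.25, carrier effect 0.5 at carrier MAF 1.5% (dominant coding).
* **Haplotypes** — two haplotypes per sample per block drawn from
  stated within-block pools; blocks independent (optional coupling
  emulates long-range LD). Phase is returned for oracle tests.
* **Long reads** — isoform templates concatenated from the exon
  library (alt-2 transcribed from the second TSS marker, others from
  the first), per-base substitution/insertion/deletion errors (defaults
  0.08/0.05/0.02 giving mean accuracy ≈0.85), random strand, and flat
  per-base qualities equal to the realised accuracy. The default exon
  library is a deterministic synthetic stand-in: TSS markers 300 nt,
  medium 100 nt, little 54 nt (reverse-translated from its 18-residue
  peptide), constitutive/downstream filler sized so alt-2 reads are
  ~3 kbp. Sequence content is random, not genomic.

What passing tests on these data show: the estimators recover the
parameters they target under the model they assume. What they do not
show: robustness to real-data features the generators omit — population
stratification and relatedness in the cohorts, qPCR normalisation
artefacts and batch effects in expression, recombination within blocks
and genotyping error in the LD panel, and non-uniform, context-dependent
error profiles or chimeric molecules in the long reads.

## Problem sizes

The packaged analyses run at sizes chosen to make sampling error small
relative to the tolerances being checked while keeping each driver and
the suite fast: LD/block simulations at 500–2000 samples (block-recovery
calibration: 200 seeds at n = 1000), CI-coverage calibration at
200–500 replicates, null calibration of the rank-sum test at 2000
simulations, and isoform mixtures at 1500–5000 reads. Each is stated
in the corresponding driver or test.

## Known limitations

* Counts cannot be reconstructed for cohorts where 3-decimal rounding
  is ambiguous; the pipeline falls back to printed OR/SE rows, so
  pooled estimates inherit two-decimal rounding error (reflected in the
  ±0.01–0.02 reproduction tolerances).
* The EM is two-locus only; no multi-site phasing, and no
  Gabriel-style confidence-interval block definition.
* Published p-values were computed from unrounded source data and are
  treated as order-of-magnitude anchors, never exact targets.
* No covariate-adjusted (logistic) association, meta-regression, or
  publication-bias diagnostics.
* The classifier assigns reads only to the annotated exon set; it does
  not discover novel exons, correct errors, or align against a genome.
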