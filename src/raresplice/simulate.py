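"""Seeded generators for every input the analysis pipeline consumes.

The study whose analyses this package reproduces did not deposit raw
genotype, qPCR or sequencing data, so each stage is exercised on
synthetic data with the statistical structure the analyses assume:

* case-control cohorts with a prescribed control minor-allele frequency
  and allelic odds ratio, genotypes drawn in Hardy-Weinberg proportions;
* relative expression values on the qPCR ratio scale (control mean 1.0)
  with diagnosis-specific fold changes around 1.06-1.08 and a carrier
  effect (default 0.5x, matching the halving of minor-isoform
  expression seen in splice-site loss-of-function carriers);
* LD-block-structured haplotype pools with known phase, blocks drawn
  independently (or with optional coupling) so recombination is confined
  to block junctions;
* ~3 kbp noisy long reads concatenated from an exon library at given
  isoform mixture fractions, with substitution/insertion/deletion errors
  and qualities consistent with the realised per-base accuracy.

Every generator takes a seed and also emits the ground truth needed by
oracle tests downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import AlleleTable2x2
from .isoform import ExonLibrary, LongRead, reverse_complement
from .ld import GenotypeMatrix, Site

__all__ = ["CohortSimSpec", "ExpressionSimSpec", "HaplotypePoolSpec", "ReadSimSpec",
           "simulate_cohort", "simulate_expression", "simulate_haplotypes",
           "simulate_reads", "default_exon_library", "case_maf_for_or",
           "LITTLE_EXON_PEPTIDE"]

# the 18-residue peptide encoded by the 54-nt "little" cassette exon
LITTLE_EXON_PEPTIDE = "GNRCTWYKIPKVQEFTVK"

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


@dataclass(frozen=True)
class CohortSimSpec:
    """A case-control cohort with a target allelic odds ratio."""

    n_cases: int
    n_ctrls: int
    maf_ctrl: float
    target_or: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_ctrl < 1.0):
            raise ValueError("maf_ctrl must lie in (0, 1)")
        if self.target_or <= 0:
            raise ValueError("target_or must be positive")


@dataclass
class ExpressionSimSpec:
    """Relative-expression data on the qPCR ratio scale.

    Group sizes default to the blood-expression cohort layout (269
    controls, 123 MIX, 309 SCZ, 19 BDNOS, 140 BDI, 59 BDII); diagnosis
    fold changes default to the observed ~1.03-1.08 range with BDII
    slightly below 1.  Carriers of the protective splice-site allele
    express at ``carrier_effect`` (default 0.5) times the non-carrier
    level under a dominant coding.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: {
        "CTRL": 269, "MIX": 123, "SCZ": 309, "BDNOS": 19, "BDI": 140, "BDII": 59,
    })
    ctrl_mean: float = 1.0
    ctrl_sd: float = 0.25
    diagnosis_fc: dict[str, float] = field(default_factory=lambda: {
        "CTRL": 1.0, "MIX": 1.03, "SCZ": 1.08, "BDNOS": 1.08, "BDI": 1.08, "BDII": 0.96,
    })
    carrier_effect: float = 0.5
    carrier_maf: float = 0.015
    snp_id: str = "rs41283526"
    lognormal: bool = False
    seed: int = 0


@dataclass
class HaplotypePoolSpec:
    """Block-structured haplotype pool.

    ``blocks`` is a list of (haplotypes, frequencies): each haplotype is
    a 0/1 tuple over the block's sites (1 = minor allele) and the
    frequencies sum to 1 within the block.  Blocks recombine freely by
    default (``coupling`` = 0); ``coupling`` in [0, 1] makes a sample
    reuse the same haplotype index across blocks with that probability,
    emulating long-range LD.
    """

    blocks: list[tuple[list[tuple[int, ...]], list[float]]]
    n_samples: int = 1000
    coupling: float = 0.0
    seed: int = 0


@dataclass
class ReadSimSpec:
    """Long-read simulation: isoform mixture and error profile.

    Mixture fractions are over the splice patterns (alt-0, alt-1, alt-2)
    and must sum to 1.  Error rates are per consumed template base; the
    defaults give a mean read accuracy near the platform's ~85-88%.
    """

    mixture: dict[str, float] = field(default_factory=lambda: {
        "alt-0": 0.01, "alt-1": 0.84, "alt-2": 0.15,
    })
    n_reads: int = 1000
    sub_rate: float = 0.08
    ins_rate: float = 0.05
    del_rate: float = 0.02
    tss_by_pattern: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise ValueError("mixture fractions must sum to 1")
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not (0.0 <= r < 1.0):
                raise ValueError("error rates must lie in [0, 1)")


def case_maf_for_or(maf_ctrl: float, target_or: float) -> float:
    """Case MAF whose allelic odds against the control MAF equal target_or."""
    odds = target_or * maf_ctrl / (1.0 - maf_ctrl)
    return odds / (1.0 + odds)


def _hwe_genotypes(rng: np.random.Generator, n: int, maf: float) -> np.ndarray:
    return rng.binomial(2, maf, size=n).astype(np.int8)


def simulate_cohort(spec: CohortSimSpec) -> tuple[AlleleTable2x2, GenotypeMatrix]:
    """Draw genotypes in HWE for cases and controls.

    Control genotypes use ``maf_ctrl``; the case MAF solves
    odds(p_case) = target_or * odds(maf_ctrl).  Returns the allele table
    and a GenotypeMatrix at a single site (cases listed first).
    """
    rng = np.random.default_rng(spec.seed)
    maf_case = case_maf_for_or(spec.maf_ctrl, spec.target_or)
    g_case = _hwe_genotypes(rng, spec.n_cases, maf_case)
    g_ctrl = _hwe_genotypes(rng, spec.n_ctrls, spec.maf_ctrl)
    cm = int(g_case.sum())
    um = int(g_ctrl.sum())
    table = AlleleTable2x2(cm, 2 * spec.n_cases - cm, um, 2 * spec.n_ctrls - um)
    samples = [f"case{i}" for i in range(spec.n_cases)] + [f"ctrl{i}" for i in range(spec.n_ctrls)]
    calls = np.concatenate([g_case, g_ctrl])[:, None]
    gm = GenotypeMatrix(samples, [Site("snp1", 1)], calls)
    return table, gm


def simulate_expression(spec: ExpressionSimSpec) -> pd.DataFrame:
    """Relative expression records for the diagnosis-group layout.

    expression = ctrl_mean * diagnosis_fc * (carrier_effect if carrier)
    * noise, with multiplicative truncated-normal noise Normal(1, ctrl_sd)
    clipped at 0 (or log-normal with matching log-sd when requested, to
    produce the heavy right tail used by the high-expressor test).
    Carrier status is drawn at ``carrier_maf`` under a dominant coding.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    p_carrier = 1.0 - (1.0 - spec.carrier_maf) ** 2
    for group, n in spec.group_sizes.items():
        fc = spec.diagnosis_fc.get(group, 1.0)
        carriers = rng.random(n) < p_carrier
        if spec.lognormal:
            noise = rng.lognormal(mean=-0.5 * math.log1p(spec.ctrl_sd ** 2),
                                  sigma=math.sqrt(math.log1p(spec.ctrl_sd ** 2)), size=n)
        else:
            noise = np.clip(rng.normal(1.0, spec.ctrl_sd, size=n), 0.0, None)
        expr = spec.ctrl_mean * fc * np.where(carriers, spec.carrier_effect, 1.0) * noise
        for i in range(n):
            rows.append({
                "sample_id": f"{group}_{i}",
                "diagnosis": group,
                "expression": float(expr[i]),
                f"{spec.snp_id}_carrier": "carrier" if carriers[i] else "non-carrier",
            })
    return pd.DataFrame(rows)


def simulate_haplotypes(spec: HaplotypePoolSpec) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw two haplotypes per sample per block; emit unphased dosages.

    Returns (genotypes, phase) where phase has shape (n_samples, 2,
    n_sites) holding the true haplotypes for oracle tests.  Sites are
    named ``b{block}s{site}`` with positions spaced 1 kb apart.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    site_list: list[Site] = []
    hap_cols: list[np.ndarray] = []
    pos = 0
    prev_choice: np.ndarray | None = None
    for b, (haps, freqs) in enumerate(spec.blocks):
        haps_arr = np.asarray(haps, dtype=np.int8)
        freqs_arr = np.asarray(freqs, dtype=float)
        if abs(freqs_arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"block {b}: haplotype frequencies must sum to 1")
        if haps_arr.ndim != 2 or haps_arr.shape[0] != len(freqs_arr):
            raise ValueError(f"block {b}: haplotype/frequency shape mismatch")
        choice = rng.choice(len(freqs_arr), size=(n, 2), p=freqs_arr)
        if prev_choice is not None and spec.coupling > 0:
            same = rng.random((n, 2)) < spec.coupling
            reuse = prev_choice % len(freqs_arr)
            choice = np.where(same, reuse, choice)
        prev_choice = choice
        hap_cols.append(haps_arr[choice])  # (n, 2, block_sites)
        for s in range(haps_arr.shape[1]):
            pos += 1000
            site_list.append(Site(f"b{b}s{s}", pos))
    phase = np.concatenate(hap_cols, axis=2)  # (n, 2, n_sites)
    calls = phase.sum(axis=1).astype(np.int8)
    samples = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(samples, site_list, calls), phase


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def default_exon_library(seed: int = 2024) -> ExonLibrary:
    """Deterministic synthetic exon library for the ~3 kbp amplicon.

    Two 300-nt TSS-marker first exons (one per transcript model), 5'
    constitutive filler, the 100-nt medium exon, the 54-nt little exon
    (reverse-translated from its 18-residue peptide), and downstream
    filler sized so that an alt-2 read is ~3 kbp.  Synthetic stand-in
    sequences: lengths and roles match the real amplicon design, the
    bases do not.
    """
    rng = np.random.default_rng(seed)
    little = "".join(_CODON[a] for a in LITTLE_EXON_PEPTIDE)
    assert len(little) == 54
    entries = {
        "tss_NM_001204404": _random_seq(rng, 300),
        "tss_NM_020987": _random_seq(rng, 300),
        "const5": _random_seq(rng, 1200),
        "medium": _random_seq(rng, 100),
        "little": little,
        "downstream": _random_seq(rng, 1400),
    }
    roles = {
        "tss_NM_001204404": "tss_marker",
        "tss_NM_020987": "tss_marker",
        "const5": "constitutive",
        "medium": "roi_medium",
        "little": "roi_little",
        "downstream": "downstream",
    }
    return ExonLibrary(entries, roles)


PATTERN_EXONS = {
    "alt-0": (),
    "alt-1": ("medium",),
    "alt-2": ("medium", "little"),
}


def isoform_template(pattern: str, lib: ExonLibrary, tss: str) -> str:
    """Exon concatenation for a splice pattern transcribed from ``tss``."""
    med = lib.by_role("roi_medium")[0]
    lit = lib.by_role("roi_little")[0]
    parts = [lib.entries[tss]]
    parts += [lib.entries[n] for n in lib.by_role("constitutive")]
    if pattern in ("alt-1", "alt-2"):
        parts.append(lib.entries[med])
    if pattern == "alt-2":
        parts.append(lib.entries[lit])
    parts += [lib.entries[n] for n in lib.by_role("downstream")]
    return "".join(parts)


def _mutate(rng: np.random.Generator, seq: str, sub: float, ins: float,
            dele: float) -> tuple[str, int]:
    """Apply per-base substitution/insertion/deletion; returns (read, n_errors)."""
    out = []
    n_err = 0
    bases = "ACGT"
    for ch in seq:
        if rng.random() < dele:
            n_err += 1
            continue
        if rng.random() < ins:
            out.append(bases[rng.integers(0, 4)])
            n_err += 1
        if rng.random() < sub:
            out.append(bases[(bases.index(ch) + rng.integers(1, 4)) % 4])
            n_err += 1
        else:
            out.append(ch)
    return "".join(out), n_err


def simulate_reads(spec: ReadSimSpec, lib: ExonLibrary | None = None
                   ) -> tuple[list[LongRead], list[dict]]:
    """Noisy long reads from the exon library at the mixture fractions.

    Each read draws a splice pattern, builds the isoform template (alt-2
    from the second TSS marker, others from the first unless overridden
    in ``tss_by_pattern``), applies the error model, reverse-complements
    half the reads, and attaches flat per-base accuracies equal to the
    realised accuracy (errors / template length).  Returns (reads, truth)
    with one truth dict per read: pattern, tss, orientation, n_errors.
    """
    if lib is None:
        lib = default_exon_library()
    rng = np.random.default_rng(spec.seed)
    markers = lib.by_role("tss_marker")
    default_tss = {
        "alt-0": markers[0],
        "alt-1": markers[0],
        "alt-2": markers[-1],
    }
    tss_map = {**default_tss, **spec.tss_by_pattern}
    patterns = list(spec.mixture)
    probs = np.array([spec.mixture[p] for p in patterns])
    choices = rng.choice(len(patterns), size=spec.n_reads, p=probs)
    reads: list[LongRead] = []
    truth: list[dict] = []
    templates = {p: isoform_template(p, lib, tss_map[p]) for p in patterns}
    for i, ci in enumerate(choices):
        pattern = patterns[ci]
        template = templates[pattern]
        seq, n_err = _mutate(rng, template, spec.sub_rate, spec.ins_rate, spec.del_rate)
        orientation = "forward"
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
            orientation = "reverse"
        accuracy = max(0.0, 1.0 - n_err / max(len(template), 1))
        quals = np.full(len(seq), accuracy)
        reads.append(LongRead(f"read{i}", seq, qualities=quals))
        truth.append({"read_id": f"read{i}", "pattern": pattern, "tss": tss_map[pattern],
                      "orientation": orientation, "n_errors": n_err})
    return reads, truth
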