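"""Readers and writers for the pipeline's on-disk formats.

Tabular inputs/outputs are TSV (pandas); genotypes come from a VCF
(v4.2 subset, GT field, biallelic records; read with cyvcf2) or a dosage
TSV; exon libraries from FASTA plus a sidecar role TSV (Biopython);
long reads from FASTQ with Phred+33 qualities or FASTA with an assumed
accuracy.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .assoc import CohortSummary
from .isoform import ExonLibrary, LongRead, phred_to_accuracy
from .ld import MISSING, GenotypeMatrix, Site
from .meta import StudyEffect

__all__ = [
    "read_cohort_tsv", "read_study_tsv", "read_expression_tsv",
    "read_genotypes_vcf", "read_genotypes_tsv", "read_exon_library",
    "read_fastq", "write_fastq", "write_exon_library", "write_genotypes_vcf",
    "write_tsv", "write_json",
]


def read_cohort_tsv(path: str | Path) -> list[CohortSummary]:
    """Cohort summaries: columns cohort, phenotype, n_cases, n_ctrls,
    maf_cases, maf_ctrls."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        CohortSummary(int(r.n_cases), int(r.n_ctrls), float(r.maf_cases),
                      float(r.maf_ctrls), label=str(r.cohort), phenotype=str(r.phenotype))
        for r in df.itertuples()
    ]


def read_study_tsv(path: str | Path) -> list[StudyEffect]:
    """Per-study effects: label, log_or, se, p_two_sided, direction,
    n_cases, n_ctrls (the last five optional)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for r in df.itertuples():
        out.append(StudyEffect(
            label=str(r.label), log_or=float(r.log_or), se=float(r.se),
            p_two_sided=float(r.p_two_sided) if "p_two_sided" in df.columns else None,
            direction=str(r.direction) if "direction" in df.columns else None,
            n_cases=int(r.n_cases) if "n_cases" in df.columns else None,
            n_ctrls=int(r.n_ctrls) if "n_ctrls" in df.columns else None,
        ))
    return out


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Expression records; requires sample_id, diagnosis, expression."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("sample_id", "diagnosis", "expression"):
        if col not in df.columns:
            raise ValueError(f"expression TSV missing column {col!r}")
    return df


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Biallelic GT-only VCF to a minor-allele dosage matrix.

    The ALT allele is taken as the minor allele; multi-allelic records
    are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    sites: list[Site] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic record at {var.CHROM}:{var.POS}")
        # with gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        cols.append(g)
        sites.append(Site(var.ID or f"{var.CHROM}:{var.POS}", var.POS, var.CHROM,
                          minor=var.ALT[0], major=var.REF))
    calls = np.stack(cols, axis=1) if cols else np.zeros((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(samples, sites, calls)


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    """Dosage TSV: first column sample_id, remaining columns one site each
    named ``id@chrom:pos`` (or plain id with implicit positions), values
    0/1/2 or NA."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    sites = []
    for i, col in enumerate(df.columns):
        if "@" in col:
            sid, loc = col.split("@", 1)
            chrom, pos = loc.split(":")
            sites.append(Site(sid, int(pos), chrom))
        else:
            sites.append(Site(col, (i + 1) * 1000))
    calls = df.to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    return GenotypeMatrix([str(s) for s in df.index], sites, calls)


def write_genotypes_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 with GT-only genotype fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, site in enumerate(g.sites):
            gts = "\t".join(code[int(d)] for d in g.calls[:, j])
            fh.write(f"{site.chrom}\t{site.pos}\t{site.id}\t{site.major}\t{site.minor}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


def read_exon_library(fasta: str | Path, roles_tsv: str | Path) -> ExonLibrary:
    """Exon FASTA plus sidecar TSV with columns exon_name, role."""
    entries = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    roles_df = pd.read_csv(roles_tsv, sep="\t", comment="#")
    roles = dict(zip(roles_df["exon_name"].astype(str), roles_df["role"].astype(str)))
    return ExonLibrary(entries, roles)


def write_exon_library(lib: ExonLibrary, fasta: str | Path, roles_tsv: str | Path) -> None:
    with open(fasta, "w") as fh:
        for name, seq in lib.entries.items():
            fh.write(f">{name}\n{seq}\n")
    pd.DataFrame(
        [{"exon_name": n, "role": r} for n, r in lib.roles.items()]
    ).to_csv(roles_tsv, sep="\t", index=False)


def read_fastq(path: str | Path) -> list[LongRead]:
    """FASTQ with Phred+33 qualities mapped to per-base accuracies."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        acc = phred_to_accuracy(rec.letter_annotations["phred_quality"])
        reads.append(LongRead(rec.id, str(rec.seq).upper(), qualities=acc))
    return reads


def read_fasta_reads(path: str | Path, assume_accuracy: float) -> list[LongRead]:
    """FASTA reads with a single assumed mean accuracy."""
    return [
        LongRead(rec.id, str(rec.seq).upper(), mean_accuracy_value=assume_accuracy)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fastq(reads: Iterable[LongRead], path: str | Path) -> None:
    """Phred+33 FASTQ; accuracies are converted back to integer Phred
    scores (capped at Q60)."""
    with open(path, "w") as fh:
        for r in reads:
            if r.qualities is not None:
                acc = np.clip(r.qualities, 0.0, 1.0 - 1e-7)
            else:
                acc = np.full(len(r.sequence), min(r.mean_accuracy, 1.0 - 1e-7))
            q = np.minimum(60, np.round(-10.0 * np.log10(1.0 - acc))).astype(int)
            qual = "".join(chr(33 + int(v)) for v in q)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def write_tsv(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
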