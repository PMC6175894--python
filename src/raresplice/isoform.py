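"""Splice-pattern classification of noisy full-length cDNA long reads.

Single-molecule long reads covering the alternatively spliced region of
interest are (1) filtered on length and mean per-base accuracy, (2)
scanned for the presence of each exon of an annotated library by
approximate k-mer matching (18-mers at edit distance <= 2, which the
platform's high indel rate makes necessary), and (3) assigned a
transcription start site (from which TSS-marker first exon is detected)
and a splice pattern over the two cassette exons:

    alt-0  neither the "medium" nor the "little" exon
    alt-1  the "medium" exon only
    alt-2  both exons

A read showing the little exon without the medium one violates the known
splicing grammar and is flagged ``inconsistent``.  Abundances are
summarised per sample over cleanly classified reads, with patterns below
a reporting threshold (default 1%) pooled into "other".

The approximate search delegates banded edit-distance alignment to
``edlib`` and prunes the quadratic k-mer x window scan with an exact
6-mer pigeonhole seed index: any 18-mer within edit distance 2 of a read
window must share one of its three 6-mer thirds with the window exactly.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np

from .errors import NoClassifiedReadsError

__all__ = ["ExonLibrary", "LongRead", "KmerMatchParams", "IsoformCall",
           "AbundanceSummary", "qc_filter", "detect_exon", "classify_read",
           "summarize_abundance", "reverse_complement", "phred_to_accuracy"]

EXON_ROLES = ("tss_marker", "roi_medium", "roi_little", "constitutive", "downstream")

_COMPL = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


def phred_to_accuracy(quals: Sequence[int]) -> np.ndarray:
    """Per-base accuracy 1 - 10^(-Q/10) from Phred quality scores."""
    q = np.asarray(quals, dtype=float)
    return 1.0 - np.power(10.0, -q / 10.0)


@dataclass(frozen=True)
class KmerMatchParams:
    """Approximate-match parameters: k-mer length and edit-distance budget."""

    k: int = 18
    max_edits: int = 2

    def __post_init__(self) -> None:
        if self.k < self.max_edits + 1:
            raise ValueError("k must exceed max_edits")


@dataclass
class ExonLibrary:
    """Named exon sequences with their classification roles.

    Roles: ``tss_marker`` (first exon of a transcript model, identifies
    the TSS), ``roi_medium`` / ``roi_little`` (the two cassette exons),
    ``constitutive`` and ``downstream`` (always-present context exons).
    """

    entries: dict[str, str]
    roles: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.entries.items():
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"exon {name!r}: sequence must be non-empty uppercase ACGT")
            if name not in self.roles:
                raise ValueError(f"exon {name!r} has no role")
        for name, role in self.roles.items():
            if role not in EXON_ROLES:
                raise ValueError(f"exon {name!r}: unknown role {role!r}")

    def by_role(self, role: str) -> list[str]:
        return [n for n, r in self.roles.items() if r == role]

    def validate_for_classification(self, k: int = 18) -> None:
        if not self.by_role("tss_marker"):
            raise ValueError("library needs at least one tss_marker exon")
        for role in ("roi_medium", "roi_little"):
            if len(self.by_role(role)) != 1:
                raise ValueError(f"library needs exactly one {role} exon")
        short = [n for n, s in self.entries.items() if len(s) < k]
        if short:
            raise ValueError(f"exons shorter than k={k}: {short}")


@dataclass
class LongRead:
    """A read with per-base error information.

    ``qualities`` holds per-base accuracies in [0, 1] (length-matched to
    the sequence); alternatively a single ``mean_accuracy`` may be given
    for quality-less input.
    """

    id: str
    sequence: str
    qualities: np.ndarray | None = None
    mean_accuracy_value: float | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None:
            self.qualities = np.asarray(self.qualities, dtype=float)
            if len(self.qualities) != len(self.sequence):
                raise ValueError(f"read {self.id}: quality/sequence length mismatch")
            if self.qualities.size and (self.qualities.min() < 0 or self.qualities.max() > 1):
                raise ValueError(f"read {self.id}: accuracies must lie in [0, 1]")
        elif self.mean_accuracy_value is None:
            raise ValueError(f"read {self.id}: needs qualities or a mean accuracy")

    @property
    def mean_accuracy(self) -> float:
        if self.qualities is not None:
            return float(self.qualities.mean()) if self.qualities.size else 0.0
        return float(self.mean_accuracy_value)


@dataclass(frozen=True)
class IsoformCall:
    """TSS and splice-pattern assignment for one read."""

    read_id: str
    tss: str                # a tss_marker exon name, "none" or "ambiguous"
    roi_pattern: str        # "alt-0", "alt-1", "alt-2" or "inconsistent"
    orientation: str        # "forward" or "reverse"
    exons_detected: frozenset[str]

    @property
    def classified(self) -> bool:
        return self.tss not in ("none", "ambiguous") and self.roi_pattern != "inconsistent"


@dataclass
class AbundanceSummary:
    """Per-sample isoform fractions over cleanly classified reads."""

    sample: str
    n_classified: int
    fractions: dict[str, float]          # pattern key -> fraction, sums to 1
    reported: dict[str, float] = field(default_factory=dict)  # thresholded view
    threshold: float = 0.01


def qc_filter(reads: Iterable[LongRead], min_len: int = 2700, max_len: int = 3300,
              min_mean_accuracy: float = 0.85) -> tuple[list[LongRead], list[tuple[str, str]]]:
    """Keep reads inside the expected size range with adequate mean accuracy.

    Both bounds are inclusive.  Returns (kept, rejected) where rejected is
    a list of (read_id, reason) with reason in {"length", "quality"}; a
    read failing both is reported once, for length.
    """
    kept: list[LongRead] = []
    rejected: list[tuple[str, str]] = []
    for r in reads:
        if not (min_len <= len(r.sequence) <= max_len):
            rejected.append((r.id, "length"))
        # tiny tolerance keeps the inclusive bound robust to float summation
        elif r.mean_accuracy < min_mean_accuracy - 1e-9:
            rejected.append((r.id, "quality"))
        else:
            kept.append(r)
    return kept, rejected


def _seed_index(text: str, seed_len: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(text) - seed_len + 1):
        index[text[i:i + seed_len]].append(i)
    return index


def detect_exon(read_seq: str, exon_seq: str, params: KmerMatchParams = KmerMatchParams(),
                min_hits: int = 1,
                seed_index: dict[str, list[int]] | None = None) -> bool:
    """True iff >= ``min_hits`` k-mers of the exon occur in the read within
    ``max_edits`` edit distance (substitutions and indels).

    Matching is semi-global: the whole k-mer against any window of the
    read.  The scan is pruned by pigeonhole seeding — a k-mer within e
    edits of a window shares at least one of e+1 exact seed blocks with
    it — then candidates are verified by banded alignment on a small
    window around the seed.  ``seed_index`` may be passed to reuse the
    read's seed table across exons.
    """
    k, e = params.k, params.max_edits
    if len(exon_seq) < k:
        raise ValueError("exon shorter than k")
    if len(read_seq) < 1:
        return False
    seed_len = k // (e + 1)
    if seed_index is None:
        seed_index = _seed_index(read_seq, seed_len)
    n = len(read_seq)
    hits = 0
    for i in range(len(exon_seq) - k + 1):
        kmer = exon_seq[i:i + k]
        found = False
        for b in range(e + 1):
            off = b * seed_len
            for pos in seed_index.get(kmer[off:off + seed_len], ()):
                lo = max(0, pos - off - e)
                hi = min(n, pos - off + k + 2 * e)
                res = edlib.align(kmer, read_seq[lo:hi], mode="HW", task="distance", k=e)
                if res["editDistance"] != -1:
                    found = True
                    break
            if found:
                break
        if found:
            hits += 1
            if hits >= min_hits:
                return True
    return False


def _detect_all(seq: str, lib: ExonLibrary, params: KmerMatchParams,
                min_hits: int) -> set[str]:
    seed_len = params.k // (params.max_edits + 1)
    index = _seed_index(seq, seed_len)
    return {
        name for name, exon in lib.entries.items()
        if detect_exon(seq, exon, params, min_hits=min_hits, seed_index=index)
    }


def classify_read(read: LongRead, lib: ExonLibrary,
                  params: KmerMatchParams = KmerMatchParams(),
                  min_hits: int = 1) -> IsoformCall:
    """Assign TSS and splice pattern; strand is resolved automatically.

    Both the forward sequence and its reverse complement are scanned; the
    orientation detecting more exons wins (ties go to forward).  The TSS
    is the unique tss_marker detected ("none"/"ambiguous" for 0 / >= 2);
    the splice pattern follows from presence of the medium/little exons,
    with "little without medium" flagged inconsistent.
    """
    lib.validate_for_classification(params.k)
    fwd = _detect_all(read.sequence, lib, params, min_hits)
    rev = _detect_all(reverse_complement(read.sequence), lib, params, min_hits)
    if len(rev) > len(fwd):
        detected, orientation = rev, "reverse"
    else:
        detected, orientation = fwd, "forward"
    markers = [n for n in lib.by_role("tss_marker") if n in detected]
    tss = markers[0] if len(markers) == 1 else ("none" if not markers else "ambiguous")
    medium = lib.by_role("roi_medium")[0] in detected
    little = lib.by_role("roi_little")[0] in detected
    if little and not medium:
        pattern = "inconsistent"
    elif little:
        pattern = "alt-2"
    elif medium:
        pattern = "alt-1"
    else:
        pattern = "alt-0"
    return IsoformCall(read.id, tss, pattern, orientation, frozenset(detected))


def summarize_abundance(calls_by_sample: dict[str, Sequence[IsoformCall]],
                        threshold: float = 0.01,
                        by_tss: bool = False) -> dict[str, AbundanceSummary]:
    """Per-sample isoform fractions over cleanly classified reads.

    Reads with an unresolved TSS or an inconsistent splice pattern are
    excluded from the denominators.  The reported view keeps the union of
    patterns reaching ``threshold`` in at least one sample; the rest are
    pooled as "other".  With ``by_tss`` the pattern key is "<tss>:<alt-x>".
    """
    fractions: dict[str, dict[str, float]] = {}
    n_classified: dict[str, int] = {}
    for sample, calls in calls_by_sample.items():
        good = [c for c in calls if c.classified]
        if not good:
            raise NoClassifiedReadsError(f"sample {sample!r}: no classified reads")
        counts: dict[str, int] = defaultdict(int)
        for c in good:
            key = f"{c.tss}:{c.roi_pattern}" if by_tss else c.roi_pattern
            counts[key] += 1
        n = len(good)
        fractions[sample] = {k: v / n for k, v in counts.items()}
        n_classified[sample] = n
    reportable = sorted({
        k for fr in fractions.values() for k, v in fr.items() if v >= threshold
    })
    out: dict[str, AbundanceSummary] = {}
    for sample, fr in fractions.items():
        reported = {k: fr.get(k, 0.0) for k in reportable}
        other = 1.0 - sum(reported.values())
        if other > 1e-12:
            reported["other"] = other
        out[sample] = AbundanceSummary(sample, n_classified[sample], fr, reported, threshold)
    return out
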