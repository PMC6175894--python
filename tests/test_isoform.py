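"""Long-read QC, approximate exon detection against a dense-DP oracle,
splice-pattern classification and abundance summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import detect_exon_oracle
from raresplice.errors import NoClassifiedReadsError
from raresplice.isoform import (ExonLibrary, KmerMatchParams, LongRead,
                                classify_read, detect_exon, phred_to_accuracy,
                                qc_filter, reverse_complement,
                                summarize_abundance)
from raresplice.simulate import (ReadSimSpec, default_exon_library,
                                 isoform_template, simulate_reads)


def _read(seq, acc=0.99, rid="r"):
    return LongRead(rid, seq, qualities=np.full(len(seq), acc))


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# ------------------------------------------------------------------- QC

def test_qc_filter_boundaries():
    reads = [
        _read("A" * 2500, 0.99, "short"),
        _read("A" * 3000, 0.84, "lowq"),
        _read("A" * 2700, 0.85, "edge_ok"),
        _read("A" * 3300, 0.99, "long_edge_ok"),
        _read("A" * 3301, 0.99, "too_long"),
    ]
    kept, rejected = qc_filter(reads)
    assert [r.id for r in kept] == ["edge_ok", "long_edge_ok"]
    assert dict(rejected) == {"short": "length", "lowq": "quality", "too_long": "length"}


def test_qc_filter_order_preserving_and_idempotent(rng):
    reads = [_read(_random_seq(rng, int(n)), float(a), f"r{i}")
             for i, (n, a) in enumerate(zip(rng.integers(2500, 3500, 30),
                                            rng.uniform(0.8, 1.0, 30)))]
    kept, _ = qc_filter(reads)
    assert all(2700 <= len(r.sequence) <= 3300 and r.mean_accuracy >= 0.85
               for r in kept)
    ids = [r.id for r in reads]
    assert [r.id for r in kept] == [i for i in ids if i in {r.id for r in kept}]
    kept2, rej2 = qc_filter(kept)
    assert kept2 == kept and rej2 == []


def test_phred_conversion():
    acc = phred_to_accuracy([10, 20, 30])
    assert acc == pytest.approx([0.9, 0.99, 0.999])


# ------------------------------------------------------- exon detection

def test_detect_exon_verbatim(rng):
    exon = _random_seq(rng, 54)
    read = _random_seq(rng, 200) + exon + _random_seq(rng, 200)
    assert detect_exon(read, exon)


def test_detect_exon_two_substitutions(rng):
    exon = _random_seq(rng, 54)
    kmer = list(exon[:18])
    kmer[3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[kmer[3]]
    kmer[11] = {"A": "C", "C": "A", "G": "T", "T": "G"}[kmer[11]]
    read = _random_seq(rng, 100) + "".join(kmer) + _random_seq(rng, 100)
    assert detect_exon(read, exon) == detect_exon_oracle(read, exon)
    assert detect_exon(read, exon)


def test_detect_exon_indels_count_as_edits(rng):
    exon = _random_seq(rng, 54)
    # embed an 18-mer with one deletion and one insertion: still <= 2 edits
    kmer = exon[18:36]
    mutated = kmer[:5] + kmer[6:12] + "A" + kmer[12:]
    read = _random_seq(rng, 100) + mutated + _random_seq(rng, 100)
    assert detect_exon(read, exon)


def test_detect_exon_absent_random(rng):
    exon = _random_seq(rng, 54)
    read = _random_seq(rng, 400)
    assert detect_exon(read, exon) == detect_exon_oracle(read, exon)


def test_detect_exon_false_positive_rate(rng):
    """Chance matches of a random 54-nt exon against random 3 kbp reads
    are rare.  At 18-mer / 2-edit settings the chance-hit rate of the
    criterion itself (confirmed by the dense-DP oracle) is about 2% per
    read, so the bound is set at 5%."""
    hits = 0
    trials = 100
    for _ in range(trials):
        exon = _random_seq(rng, 54)
        read = _random_seq(rng, 3000)
        hits += detect_exon(read, exon)
    assert hits <= 5


@given(seed=st.integers(0, 10_000), read_len=st.integers(30, 400),
       n_mut=st.integers(0, 25))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_detect_exon_agrees_with_dp_oracle(seed, read_len, n_mut):
    """Seeded pigeonhole search equals the dense-DP scan on short reads
    carrying a randomly mutated copy of the exon."""
    rng = np.random.default_rng(seed)
    exon = _random_seq(rng, 54)
    read = list(_random_seq(rng, read_len))
    insert_at = int(rng.integers(0, max(1, read_len - 54)))
    copy = list(exon)
    for _ in range(n_mut):
        op = rng.integers(0, 3)
        pos = int(rng.integers(0, len(copy))) if copy else 0
        if op == 0 and copy:
            copy[pos] = "ACGT"[rng.integers(0, 4)]
        elif op == 1 and copy:
            del copy[pos]
        else:
            copy.insert(pos, "ACGT"[rng.integers(0, 4)])
    read[insert_at:insert_at] = copy
    read = "".join(read)
    assert detect_exon(read, exon) == detect_exon_oracle(read, exon)


def test_min_hits_parameter(rng):
    exon = _random_seq(rng, 54)
    read = _random_seq(rng, 100) + exon[:18] + _random_seq(rng, 100)
    assert detect_exon(read, exon, min_hits=1)
    assert not detect_exon(read, exon, min_hits=10)


# -------------------------------------------------------- classification

def test_classify_clean_alt2_read(exon_library):
    seq = isoform_template("alt-2", exon_library, "tss_NM_020987")
    call = classify_read(_read(seq), exon_library)
    assert call.tss == "tss_NM_020987"
    assert call.roi_pattern == "alt-2"
    assert call.orientation == "forward"
    assert call.classified


def test_classify_reverse_complement_invariance(exon_library):
    seq = isoform_template("alt-1", exon_library, "tss_NM_001204404")
    fwd = classify_read(_read(seq), exon_library)
    rev = classify_read(_read(reverse_complement(seq)), exon_library)
    assert (fwd.tss, fwd.roi_pattern) == (rev.tss, rev.roi_pattern)
    assert fwd.orientation == "forward" and rev.orientation == "reverse"


def test_classify_little_without_medium_inconsistent(exon_library):
    lib = exon_library
    seq = (lib.entries["tss_NM_020987"] + lib.entries["const5"]
           + lib.entries["little"] + lib.entries["downstream"])
    call = classify_read(_read(seq), lib)
    assert call.roi_pattern == "inconsistent"
    assert not call.classified


def test_classify_no_tss_marker(exon_library):
    lib = exon_library
    seq = lib.entries["const5"] + lib.entries["medium"] + lib.entries["downstream"]
    call = classify_read(_read(seq), lib)
    assert call.tss == "none"
    assert not call.classified


# ------------------------------------------------------------ abundance

def _call(rid, pattern, tss="tss_NM_020987"):
    from raresplice.isoform import IsoformCall

    return IsoformCall(rid, tss, pattern, "forward", frozenset())


def test_abundance_single_pattern():
    calls = [_call(f"r{i}", "alt-1") for i in range(100)]
    s = summarize_abundance({"s1": calls})["s1"]
    assert s.fractions == {"alt-1": 1.0}
    assert s.n_classified == 100


def test_abundance_threshold_pools_rare_patterns():
    calls = [_call(f"r{i}", "alt-1") for i in range(995)]
    calls += [_call(f"x{i}", "alt-2") for i in range(5)]  # 0.5% < threshold
    s = summarize_abundance({"s1": calls})["s1"]
    assert "alt-2" not in s.reported
    assert s.reported["other"] == pytest.approx(0.005)
    assert sum(s.fractions.values()) == pytest.approx(1.0)


def test_abundance_excludes_unclassified():
    calls = [_call(f"r{i}", "alt-1") for i in range(10)]
    calls.append(_call("bad1", "inconsistent"))
    calls.append(_call("bad2", "alt-1", tss="none"))
    s = summarize_abundance({"s1": calls})["s1"]
    assert s.n_classified == 10


def test_abundance_no_classified_reads_raises():
    with pytest.raises(NoClassifiedReadsError):
        summarize_abundance({"s1": [_call("r0", "inconsistent")]})


# ----------------------------------------------------------- end-to-end

def test_zero_error_reads_classified_perfectly(exon_library):
    spec = ReadSimSpec(mixture={"alt-0": 0.2, "alt-1": 0.5, "alt-2": 0.3},
                       n_reads=60, sub_rate=0.0, ins_rate=0.0, del_rate=0.0, seed=1)
    reads, truth = simulate_reads(spec, exon_library)
    for read, t in zip(reads, truth):
        call = classify_read(read, exon_library)
        assert call.roi_pattern == t["pattern"]
        assert call.tss == t["tss"]
        assert call.orientation == t["orientation"]
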