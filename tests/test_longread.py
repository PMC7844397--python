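"""CCS filtering, primer/polyA detection and FLNC classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dna
from oracles import brute_polya, brute_primer_hits

from isogrow.longread import (
    CCSRead,
    ccs_filter,
    classify_read,
    classify_reads,
    detect_polya,
    detect_primer,
)

P5 = "AAGCAGTGGTATCAACGCAGAGTAC"
P3 = "TCTAGACGTGTAGCCATCGGAACTT"


@pytest.mark.parametrize(
    "passes,quality,kept",
    [
        (3, 0.95, True),  # at the pass floor, above the quality cut
        (2, 0.99, False),  # below the pass floor
        (5, 0.90, False),  # quality cut is strict
        (3, 0.9000001, True),
        (100, 0.0, False),
    ],
)
def test_ccs_filter_thresholds(passes, quality, kept):
    res = ccs_filter([CCSRead("r", "ACGT", passes, quality)])
    assert (res.n_retained == 1) == kept


def test_ccs_filter_preserves_order_and_counts_malformed():
    reads = [
        CCSRead("a", "ACGT", 5, 0.99),
        CCSRead("bad", "", 5, 0.99),
        CCSRead("b", "ACGT", 5, 0.95),
        CCSRead("low", "ACGT", 1, 0.95),
    ]
    res = ccs_filter(reads)
    assert [r.id for r in res.retained] == ["a", "b"]
    assert res.n_rejected == 1 and res.n_malformed == 1


def test_detect_primer_verbatim_and_empty(rng):
    seq = P5 + random_dna(rng, 200)
    hits = detect_primer(seq, P5, max_mismatch=0)
    assert [(h.start, h.strand, h.mismatches) for h in hits] == [(0, "+", 0)]
    assert detect_primer(random_dna(rng, 100), P5, max_mismatch=0) == []


def test_detect_primer_rejects_short_primer():
    with pytest.raises(ValueError):
        detect_primer("ACGTACGTACGT", "ACGTACG")


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 2**32 - 1), st.integers(0, 3))
def test_detect_primer_matches_bruteforce(seed, max_mm):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, 300)
    # plant one mutated copy so positives occur
    copy = list(P5)
    for pos in rng.choice(len(copy), rng.integers(0, 3), replace=False):
        copy[pos] = "ACGT"[rng.integers(0, 4)]
    seq = seq[:100] + "".join(copy) + seq[100:]
    got = {(h.start, h.strand, h.mismatches) for h in detect_primer(seq, P5, max_mm)}
    assert got == brute_primer_hits(seq, P5, max_mm)


@pytest.mark.parametrize(
    "tail,min_len,expected_len",
    [
        ("A" * 30, 20, 30),
        ("A" * 19, 20, None),
        ("A" * 20, 20, 20),
    ],
)
def test_detect_polya_terminal_runs(rng, tail, min_len, expected_len):
    # A-free pad so the tolerant window cannot absorb upstream bases
    pad = "".join("CGT"[i] for i in rng.integers(0, 3, 100))
    seq = pad + tail
    iv = detect_polya(seq, min_len=min_len)
    if expected_len is None:
        assert iv is None
    else:
        assert iv == (len(seq) - expected_len, len(seq))


def test_detect_polya_tolerates_interior_nonA():
    run = "A" * 10 + "G" + "A" * 8 + "G" + "A" * 5  # 25 bases, 2 interior G
    seq = "C" * 50 + run
    assert detect_polya(seq, min_len=20, max_nonA=2) == (50, 75)


@settings(max_examples=60, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_detect_polya_matches_exhaustive_scan(seed):
    rng = np.random.default_rng(seed)
    # A-rich alphabet so qualifying windows actually occur
    seq = "".join("AAACGT"[i] for i in rng.integers(0, 6, 120))
    assert detect_polya(seq, min_len=15, max_nonA=2) == brute_polya(seq, 15, 2)


def _fl_read(transcript: str, rc: bool = False) -> str:
    raw = P5 + transcript + "A" * 30 + P3
    if rc:
        comp = str.maketrans("ACGT", "TGCA")
        raw = raw.translate(comp)[::-1]
    return raw


def test_classify_clean_fl_read_trims_exactly(rng):
    t = random_dna(rng, 800).rstrip("A") + "G"
    for rc in (False, True):
        rec = classify_read(CCSRead("r", _fl_read(t, rc), 5, 0.99), P5, P3)
        assert rec.read_class == "FL"
        assert rec.seq == t
        assert rec.reverse_complemented == rc


def test_classify_missing_polya_is_nfl(rng):
    t = random_dna(rng, 800)
    rec = classify_read(CCSRead("r", P5 + t + P3, 5, 0.99), P5, P3)
    assert rec.read_class == "nFL"


def test_classify_internal_primer_is_chimeric(rng):
    t1, t2 = random_dna(rng, 600), random_dna(rng, 700)
    raw = _fl_read(t1) + _fl_read(t2)
    rec = classify_read(CCSRead("r", raw, 5, 0.99), P5, P3)
    assert rec.read_class == "chimeric"


def test_classification_partitions_reads(clean_read_sim):
    cfg, transcripts, reads = clean_read_sim
    recs = classify_reads([r.ccs for r in reads], cfg.primer5, cfg.primer3)
    by_class = {c: sum(r.read_class == c for r in recs) for c in ("FL", "nFL", "chimeric")}
    assert sum(by_class.values()) == len(reads)


def test_classification_matches_truth_on_clean_reads(clean_read_sim):
    cfg, transcripts, reads = clean_read_sim
    recs = classify_reads([r.ccs for r in reads], cfg.primer5, cfg.primer3)
    for rec, read in zip(recs, reads):
        assert rec.read_class == read.truth_class
        if rec.read_class == "FL":
            assert rec.seq == transcripts.seqs[read.truth_transcript]


def test_fl_records_have_polya_only_at_3prime(clean_read_sim):
    cfg, transcripts, reads = clean_read_sim
    recs = classify_reads([r.ccs for r in reads], cfg.primer5, cfg.primer3)
    for rec in recs:
        if rec.read_class != "FL":
            continue
        iv = detect_polya(rec.seq + "A" * 0, min_len=20)
        # trimmed FL sequence ends on a non-A base: no terminal tail remains
        assert iv is None or iv[1] != len(rec.seq)
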