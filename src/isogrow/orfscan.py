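"""Six-frame ORF prediction and consensus lncRNA filtering.

ORFs are scanned in all six frames with ATG as the only start codon and
TAA/TAG/TGA as stops. Completeness mirrors the usual ORF-caller classes:
start and stop present -> complete; stop only (reading from the transcript
edge) -> 5prime_partial; start only (running off the 3' edge) ->
3prime_partial; an open frame spanning the whole transcript -> internal.

Coding potential is judged by a consensus of three independent predicates
(longest-ORF length, ORF coverage of the transcript, and a Fickett
TESTCODE-style composition statistic); a transcript is a lncRNA candidate
only when it is longer than 200 bp and every predicate votes non-coding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from ._util import revcomp

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

DEFAULT_MIN_AA = 100
MIN_LNCRNA_LENGTH = 200  # strict: candidates must exceed this
DEFAULT_ORF_COVERAGE = 0.30
DEFAULT_FICKETT_THRESHOLD = 0.95

COMPLETE = "complete"
FIVE_PRIME_PARTIAL = "5prime_partial"
THREE_PRIME_PARTIAL = "3prime_partial"
INTERNAL = "internal"


@dataclass
class ORF:
    transcript_id: str
    strand: str  # '+' or '-'
    frame: int  # 0, 1, 2 offset on its strand
    start: int  # transcript (forward-strand) coordinates, half-open
    end: int
    aa_length: int  # protein length, stop codon excluded
    completeness: str


def _scan_strand(s: str, strand: str, seq_len: int, min_aa: int, tid: str) -> list[ORF]:
    orfs: list[ORF] = []
    n = len(s)
    for frame in range(3):
        codon_starts = range(frame, n - 2, 3)
        seg_start = frame  # start of the current stop-free segment
        seg_first_atg: Optional[int] = None
        any_stop_before = False
        last = frame - 3
        for pos in codon_starts:
            last = pos
            codon = s[pos : pos + 3]
            if codon in STOP_CODONS:
                orfs.extend(
                    _emit(
                        s, strand, frame, seg_start, pos + 3, seg_first_atg,
                        stop=True, at_5edge=not any_stop_before,
                        seq_len=seq_len, min_aa=min_aa, tid=tid,
                    )
                )
                any_stop_before = True
                seg_start = pos + 3
                seg_first_atg = None
            elif codon == START_CODON and seg_first_atg is None:
                seg_first_atg = pos
        # trailing open segment (no stop before the 3' edge)
        seg_end = last + 3 if last >= frame else frame
        orfs.extend(
            _emit(
                s, strand, frame, seg_start, seg_end, seg_first_atg,
                stop=False, at_5edge=not any_stop_before,
                seq_len=seq_len, min_aa=min_aa, tid=tid,
            )
        )
    return orfs


def _emit(
    s: str,
    strand: str,
    frame: int,
    seg_start: int,
    seg_end: int,
    first_atg: Optional[int],
    stop: bool,
    at_5edge: bool,
    seq_len: int,
    min_aa: int,
    tid: str,
) -> list[ORF]:
    """Classify one stop-free segment and emit its ORF if reportable."""
    if seg_end <= seg_start:
        return []
    if first_atg is not None:
        begin = first_atg
        completeness = COMPLETE if stop else THREE_PRIME_PARTIAL
    elif at_5edge:
        begin = seg_start
        completeness = FIVE_PRIME_PARTIAL if stop else INTERNAL
    else:
        return []  # startless segment bounded upstream by a stop: not an ORF
    span = seg_end - begin
    aa = span // 3 - 1 if stop else span // 3
    if aa < min_aa:
        return []
    if strand == "+":
        start, end = begin, seg_end
    else:
        start, end = seq_len - seg_end, seq_len - begin
    return [ORF(tid, strand, frame, start, end, aa, completeness)]


def find_orfs(seq: str, min_aa: int = DEFAULT_MIN_AA, transcript_id: str = "") -> list[ORF]:
    """All ORFs of at least ``min_aa`` residues across six frames.

    Coordinates are on the forward strand of the transcript; for '-' strand
    ORFs the interval is the reverse-complemented footprint. Sorted by
    protein length descending (ties: strand, frame, start).
    """
    s = seq.upper()
    orfs = _scan_strand(s, "+", len(s), min_aa, transcript_id)
    orfs += _scan_strand(revcomp(s), "-", len(s), min_aa, transcript_id)
    orfs.sort(key=lambda o: (-o.aa_length, o.strand, o.frame, o.start))
    return orfs


# ---------------------------------------------------------------------------
# Fickett TESTCODE-style statistic
#
# Position bias: per base, the ratio of its most- to least-preferred codon
# position; composition: per-base fraction. Each parameter is converted to a
# coding probability through the classic lookup tables and combined with the
# published weights. Higher = more coding-like.
# ---------------------------------------------------------------------------

_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_EDGES = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_EDGES = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.17, 0.0]


def _lookup(value: float, edges: list[float], probs: list[float]) -> float:
    for idx, edge in enumerate(edges):
        if value >= edge:
            return probs[idx]
    return probs[-1]


def fickett_score(seq: str) -> float:
    """TESTCODE-style coding-potential score; deterministic, higher = more
    coding-like. Requires at least 200 bp of sequence."""
    s = seq.upper()
    if len(s) < 200:
        raise ValueError("fickett_score requires a sequence of at least 200 bp")
    score = 0.0
    for base in "ACGT":
        counts = [s[off::3].count(base) for off in range(3)]
        ratio = max(counts) / (min(counts) + 1.0)
        score += _lookup(ratio, _POSITION_EDGES, _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        fraction = s.count(base) / len(s)
        score += _lookup(fraction, _CONTENT_EDGES, _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


@dataclass
class CodingVerdict:
    transcript_id: str
    votes: dict[str, str]  # predicate -> "coding" | "noncoding"
    consensus_noncoding: bool


def classify_coding(
    seq: str,
    transcript_id: str = "",
    min_aa: int = DEFAULT_MIN_AA,
    orf_coverage: float = DEFAULT_ORF_COVERAGE,
    fickett_threshold: float = DEFAULT_FICKETT_THRESHOLD,
) -> CodingVerdict:
    """Consensus coding-potential call for one transcript.

    Predicates: longest ORF >= min_aa residues; longest ORF (any length)
    covering >= ``orf_coverage`` of the transcript; Fickett score >=
    ``fickett_threshold``. A transcript is consensus non-coding only when it
    exceeds 200 bp and every predicate votes non-coding.
    """
    all_orfs = find_orfs(seq, min_aa=1, transcript_id=transcript_id)
    longest_aa = all_orfs[0].aa_length if all_orfs else 0
    longest_bp = 3 * longest_aa
    votes = {
        "orf_length": "coding" if longest_aa >= min_aa else "noncoding",
        "orf_coverage": "coding"
        if seq and longest_bp / len(seq) >= orf_coverage
        else "noncoding",
        "fickett": "coding"
        if len(seq) >= 200 and fickett_score(seq) >= fickett_threshold
        else "noncoding",
    }
    consensus = (
        len(seq) > MIN_LNCRNA_LENGTH
        and all(v == "noncoding" for v in votes.values())
    )
    return CodingVerdict(transcript_id, votes, consensus)


def lncrna_set(transcripts: Mapping[str, str], **kwargs) -> set[str]:
    """Transcript ids judged non-coding by every predicate (and > 200 bp):
    the intersection of the per-predicate non-coding sets."""
    return {
        tid
        for tid, seq in transcripts.items()
        if classify_coding(seq, tid, **kwargs).consensus_noncoding
    }
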