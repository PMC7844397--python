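"""Reference-free alternative-splicing detection from pairwise alignment.

Without a genome, an AS event between two isoforms shows up as a pairwise
alignment that splits into exactly two collinear high-scoring segment pairs
(HSPs) around an internal unaligned gap. A transcript pair is called an AS
candidate when all of the following hold simultaneously: both transcripts
exceed 1,000 bp and the alignment has exactly two HSPs; the gap between the
HSPs (measured on the transcript carrying the extra sequence) exceeds
100 bp and lies at least 100 bp from both that transcript's ends; and the
HSP footprints overlap by at most 5 bp on either sequence.

HSPs come from iterated local alignment with masking: the best local
alignment is recorded, its footprint is masked on both sequences, and the
search repeats until the score drops below ``min_score``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

MATCH_SCORE = 1.0
MISMATCH_SCORE = -2.0
GAP_OPEN = -5.0
GAP_EXTEND = -2.0
DEFAULT_MIN_SCORE = 50.0

MIN_TRANSCRIPT_LEN = 1000  # strict: both transcripts must exceed this
MIN_GAP = 100  # strict: gap must exceed this
MIN_END_DISTANCE = 100  # inclusive: at least this far from both ends
MAX_OVERLAP = 5  # inclusive: HSPs may overlap by at most this

PREFILTER_K = 15
PREFILTER_MIN_SHARED = 30

#: an internal alignment gap longer than this (on either axis) splits the
#: alignment into separate HSPs; small indels from residual read error stay
#: within one HSP, while skipped-block gaps (> 100 bp) always split
SPLIT_GAP = 30

_MASK = "X"


def _make_aligner() -> Align.PairwiseAligner:
    alphabet = "ACGTNX"
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            matrix[x, y] = (
                MATCH_SCORE if x == y and x in "ACGT" else MISMATCH_SCORE
            )
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


@dataclass
class HSP:
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    score: float
    identity: float

    def __post_init__(self) -> None:
        if self.query_end <= self.query_start or self.subject_end <= self.subject_start:
            raise ValueError("HSP intervals must be non-empty")
        if self.score <= 0:
            raise ValueError("HSP score must be positive")


@dataclass
class ASEvent:
    transcript_a: str
    transcript_b: str
    hsp_pair: tuple[HSP, HSP]
    gap_length: int
    gap_interval: tuple[int, int]
    gap_on: str  # 'a' or 'b': the transcript carrying the extra sequence
    distance_to_5prime: int
    distance_to_3prime: int
    overlap: int  # negative when unaligned gaps exist on both axes


def _gap_cost(length: int) -> float:
    return GAP_OPEN + (length - 1) * GAP_EXTEND if length > 0 else 0.0


def _split_alignment(
    qa: str, qb: str, qblocks, sblocks, split_gap: int
) -> list[tuple[int, int, int, int, float, float]]:
    """Split an alignment's gap-free blocks at internal gaps > split_gap.

    Returns (qs, qe, ss, se, score, identity) per piece; the score of a
    piece sums its block match/mismatch scores and the affine penalties of
    the small gaps it retains.
    """
    pieces = []
    current: list[int] = []  # indices of blocks in the current piece
    for i in range(len(qblocks)):
        if current:
            prev = current[-1]
            gq = qblocks[i][0] - qblocks[prev][1]
            gs = sblocks[i][0] - sblocks[prev][1]
            if gq > split_gap or gs > split_gap:
                pieces.append(current)
                current = []
        current.append(i)
    if current:
        pieces.append(current)

    out = []
    for piece in pieces:
        score = 0.0
        matches = 0
        aligned_cols = 0
        for j, i in enumerate(piece):
            q0, q1 = int(qblocks[i][0]), int(qblocks[i][1])
            s0, s1 = int(sblocks[i][0]), int(sblocks[i][1])
            for x, y in zip(qa[q0:q1], qb[s0:s1]):
                if x == y and x in "ACGT":
                    score += MATCH_SCORE
                    matches += 1
                else:
                    score += MISMATCH_SCORE
            aligned_cols += q1 - q0
            if j > 0:
                prev = piece[j - 1]
                score += _gap_cost(int(qblocks[i][0] - qblocks[prev][1]))
                score += _gap_cost(int(sblocks[i][0] - sblocks[prev][1]))
        qs, qe = int(qblocks[piece[0]][0]), int(qblocks[piece[-1]][1])
        ss, se = int(sblocks[piece[0]][0]), int(sblocks[piece[-1]][1])
        aln_len = (qe - qs) + (se - ss) - aligned_cols
        out.append((qs, qe, ss, se, score, matches / aln_len if aln_len else 0.0))
    return out


def find_hsps(
    seq_a: str,
    seq_b: str,
    min_score: float = DEFAULT_MIN_SCORE,
    split_gap: int = SPLIT_GAP,
    max_rounds: int = 50,
) -> list[HSP]:
    """Maximal local alignments above min_score, by align-split-mask-repeat.

    Scoring: match +1, mismatch -2, gap open -5, gap extend -2. Each round
    takes the best remaining local alignment, splits it at internal gaps
    longer than ``split_gap`` on either axis (an affine-gap optimum happily
    bridges a skipped block, which must surface as two HSPs), keeps the
    pieces scoring >= min_score, and masks their footprints on both
    sequences. HSPs are returned sorted by query_start.
    """
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    aligner = _make_aligner()
    qa, qb = seq_a.upper(), seq_b.upper()
    hsps: list[HSP] = []
    for _ in range(max_rounds):
        alignments = aligner.align(qa, qb)
        if alignments.score < min_score:
            break
        aln = alignments[0]
        qblocks, sblocks = aln.aligned
        for qs, qe, ss, se, score, identity in _split_alignment(
            qa, qb, qblocks, sblocks, split_gap
        ):
            if score >= min_score:
                hsps.append(
                    HSP(
                        query_start=qs,
                        query_end=qe,
                        subject_start=ss,
                        subject_end=se,
                        score=score,
                        identity=identity,
                    )
                )
            # sub-threshold pieces are masked too: their footprint is spent
            qa = qa[:qs] + _MASK * (qe - qs) + qa[qe:]
            qb = qb[:ss] + _MASK * (se - ss) + qb[se:]
    hsps.sort(key=lambda h: (h.query_start, h.subject_start))
    return hsps


def evaluate_as_pair(
    seq_a: str,
    seq_b: str,
    hsps: Sequence[HSP],
    id_a: str = "a",
    id_b: str = "b",
    min_transcript_len: int = MIN_TRANSCRIPT_LEN,
    min_gap: int = MIN_GAP,
    min_end_distance: int = MIN_END_DISTANCE,
    max_overlap: int = MAX_OVERLAP,
) -> Optional[ASEvent]:
    """Apply the three AS criteria to an aligned transcript pair.

    Returns an ASEvent when both transcripts exceed min_transcript_len,
    there are exactly two collinear HSPs overlapping by at most max_overlap
    bp on either axis, and the inter-HSP gap (on the transcript where it is
    larger) exceeds min_gap while staying at least min_end_distance bp from
    that transcript's 5' and 3' ends. Otherwise None.
    """
    if len(seq_a) <= min_transcript_len or len(seq_b) <= min_transcript_len:
        return None
    if len(hsps) != 2:
        return None
    h1, h2 = sorted(hsps, key=lambda h: h.query_start)
    gap_q = h2.query_start - h1.query_end
    gap_s = h2.subject_start - h1.subject_end
    # collinearity with bounded footprint overlap on both axes
    if gap_q < -max_overlap or gap_s < -max_overlap:
        return None
    gap_length = max(gap_q, gap_s)
    if gap_length <= min_gap:
        return None
    if gap_q >= gap_s:
        gap_on, seq_len = "a", len(seq_a)
        interval = (h1.query_end, h2.query_start)
    else:
        gap_on, seq_len = "b", len(seq_b)
        interval = (h1.subject_end, h2.subject_start)
    d5 = interval[0]
    d3 = seq_len - interval[1]
    if d5 < min_end_distance or d3 < min_end_distance:
        return None
    return ASEvent(
        transcript_a=id_a,
        transcript_b=id_b,
        hsp_pair=(h1, h2),
        gap_length=gap_length,
        gap_interval=interval,
        gap_on=gap_on,
        distance_to_5prime=d5,
        distance_to_3prime=d3,
        overlap=-min(gap_q, gap_s),
    )


def _shared_kmer_pairs(
    transcripts: Mapping[str, str], k: int, min_shared: int
) -> set[tuple[str, str]]:
    from collections import Counter

    index: dict[str, list[str]] = {}
    for tid in sorted(transcripts):
        for kmer in set(
            transcripts[tid][i : i + k] for i in range(len(transcripts[tid]) - k + 1)
        ):
            index.setdefault(kmer, []).append(tid)
    shared: Counter = Counter()
    for kmer, holders in index.items():
        if 1 < len(holders) <= 50:  # drop low-complexity k-mers shared by many
            for a, b in itertools.combinations(holders, 2):
                shared[(a, b)] += 1
    return {pair for pair, n in shared.items() if n >= min_shared}


def scan_all_pairs(
    transcripts: Mapping[str, str],
    min_score: float = DEFAULT_MIN_SCORE,
    prefilter: bool = True,
    prefilter_k: int = PREFILTER_K,
    prefilter_min_shared: int = PREFILTER_MIN_SHARED,
    **criteria,
) -> list[ASEvent]:
    """AS events over all unordered transcript pairs.

    Candidate pairs are prefiltered by shared distinct k-mers (bypass with
    ``prefilter=False`` for small inputs). Pairs are always evaluated with
    the lexicographically smaller id as transcript_a, so the result is
    independent of input order.
    """
    ids = sorted(transcripts)
    if prefilter:
        pairs = sorted(_shared_kmer_pairs(transcripts, prefilter_k, prefilter_min_shared))
    else:
        pairs = list(itertools.combinations(ids, 2))
    min_len = criteria.get("min_transcript_len", MIN_TRANSCRIPT_LEN)
    events: list[ASEvent] = []
    for id_a, id_b in pairs:
        a, b = transcripts[id_a], transcripts[id_b]
        if len(a) <= min_len or len(b) <= min_len:
            continue
        hsps = find_hsps(a, b, min_score=min_score)
        event = evaluate_as_pair(a, b, hsps, id_a, id_b, **criteria)
        if event is not None:
            events.append(event)
    return events
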