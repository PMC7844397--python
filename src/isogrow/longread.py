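"""CCS read filtering and full-length non-chimeric (FLNC) classification.

Long-read cDNA sequencing yields circular consensus (CCS) reads that carry a
pass count and a predicted accuracy. Reads surviving the accuracy filter are
classified by the simultaneous presence of the 5' primer, the 3' primer and a
polyA tail: all three present and no internal primer copy -> full-length (FL);
an internal primer copy indicates a fusion of two cDNA molecules -> chimeric;
anything else -> non-full-length (nFL). FL reads are oriented 5'->3' (polyA at
the 3' end) and trimmed of primers and tail.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._util import DNA_ALPHABET, revcomp

logger = logging.getLogger("isogrow.longread")

#: search window (bp) from a read terminus within which a primer hit counts
#: as terminal rather than internal
END_WINDOW = 100

#: maximum gap (bp) allowed between the polyA tail and the 3' primer
MAX_POLYA_GAP = 10

DEFAULT_MAX_MISMATCH = 3
DEFAULT_POLYA_MIN_LEN = 20
DEFAULT_POLYA_MAX_NONA = 2


@dataclass
class CCSRead:
    """A circular-consensus read with its pass count and quality estimate."""

    id: str
    seq: str
    passes: int
    quality: float

    def is_valid(self) -> bool:
        return (
            bool(self.seq)
            and set(self.seq.upper()) <= DNA_ALPHABET
            and self.passes >= 0
            and 0.0 <= self.quality <= 1.0
        )


@dataclass
class PrimerHit:
    start: int
    end: int
    strand: str  # '+' primer as given, '-' reverse complement
    mismatches: int


@dataclass
class FLNCRecord:
    """Classification outcome for one CCS read.

    ``seq`` is the primer/polyA-trimmed sequence oriented 5'->3' for FL
    reads; evidence intervals are in the oriented read's coordinates.
    """

    id: str
    seq: str
    source_read: str
    read_class: str  # FL | nFL | chimeric
    primer5_hit: Optional[tuple[int, int]] = None
    primer3_hit: Optional[tuple[int, int]] = None
    polya_hit: Optional[tuple[int, int]] = None
    reverse_complemented: bool = False


@dataclass
class FilterResult:
    retained: list[CCSRead]
    n_retained: int
    n_rejected: int
    n_malformed: int = 0


def ccs_filter(
    reads: Sequence[CCSRead], min_passes: int = 3, min_quality: float = 0.9
) -> FilterResult:
    """Retain reads with ``passes >= min_passes`` and ``quality > min_quality``.

    The quality cut is strict (a read at exactly the threshold is rejected).
    Input order is preserved; malformed records are skipped and counted.
    """
    retained: list[CCSRead] = []
    n_rejected = 0
    n_malformed = 0
    for read in reads:
        if not isinstance(read, CCSRead) or not read.is_valid():
            n_malformed += 1
            rid = getattr(read, "id", "<unknown>")
            logger.warning("skipping malformed CCS record %s", rid)
            continue
        if read.passes >= min_passes and read.quality > min_quality:
            retained.append(read)
        else:
            n_rejected += 1
    return FilterResult(retained, len(retained), n_rejected, n_malformed)


def _hamming_scan(seq: str, pattern: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (position, mismatches) where pattern matches seq within max_mismatch."""
    n, m = len(seq), len(pattern)
    if n < m:
        return []
    s = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    p = np.frombuffer(pattern.upper().encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    mism = (windows != p).sum(axis=1)
    hits = np.nonzero(mism <= max_mismatch)[0]
    return [(int(i), int(mism[i])) for i in hits]


def detect_primer(
    seq: str, primer: str, max_mismatch: int = DEFAULT_MAX_MISMATCH
) -> list[PrimerHit]:
    """Approximate occurrences of ``primer`` on both strands of ``seq``.

    Substitution-only (Hamming) matching over a sliding window; hits are
    sorted by position. Primers shorter than 8 bp are rejected: they would
    match by chance too often to carry classification evidence.
    """
    if len(primer) < 8:
        raise ValueError("primer must be at least 8 bp")
    m = len(primer)
    hits = [
        PrimerHit(pos, pos + m, "+", mm)
        for pos, mm in _hamming_scan(seq, primer, max_mismatch)
    ]
    hits += [
        PrimerHit(pos, pos + m, "-", mm)
        for pos, mm in _hamming_scan(seq, revcomp(primer), max_mismatch)
    ]
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def detect_polya(
    seq: str,
    min_len: int = DEFAULT_POLYA_MIN_LEN,
    max_nonA: int = DEFAULT_POLYA_MAX_NONA,
) -> Optional[tuple[int, int]]:
    """The 3'-most A-rich run of length >= min_len with <= max_nonA non-A bases.

    Runs must start and end on an A. Returns the interval with the greatest
    end coordinate (ties broken toward the longer run), or None.
    """
    s = seq.upper()
    n = len(s)
    for j in range(n, min_len - 1, -1):
        if s[j - 1] != "A":
            continue
        # extend left as far as the non-A budget allows
        nonA = 0
        i = j - 1
        while i > 0:
            if s[i - 1] != "A":
                if nonA + 1 > max_nonA:
                    break
                nonA += 1
            i -= 1
        # trim to start on an A
        while i < j and s[i] != "A":
            i += 1
        if j - i >= min_len:
            return (i, j)
    return None


def _terminal_layout(
    s: str,
    primer5: str,
    primer3: str,
    max_mismatch: int,
    polya_min_len: int,
    polya_max_nonA: int,
):
    """Find (p5, p3, polya) evidence for the forward layout of ``s``.

    Forward layout: primer5 near the 5' terminus, primer3 near the 3'
    terminus, polyA immediately upstream of primer3. Returns the triple of
    found pieces (each possibly None).
    """
    n = len(s)
    hits5 = [h for h in detect_primer(s, primer5, max_mismatch) if h.strand == "+"]
    hits3 = [h for h in detect_primer(s, primer3, max_mismatch) if h.strand == "+"]
    p5 = next((h for h in hits5 if h.start <= END_WINDOW), None)
    p3 = next((h for h in reversed(hits3) if h.end >= n - END_WINDOW), None)
    polya = None
    if p3 is not None and (p5 is None or p3.start > p5.end):
        # mask the 3' primer before looking for the tail so trailing A's in
        # the primer itself are never counted
        tail = detect_polya(s[: p3.start], polya_min_len, polya_max_nonA)
        if tail is not None and p3.start - tail[1] <= MAX_POLYA_GAP:
            if p5 is None or tail[0] >= p5.end:
                polya = tail
    return p5, p3, polya


def classify_read(
    ccs: CCSRead,
    primer5: str,
    primer3: str,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    polya_min_len: int = DEFAULT_POLYA_MIN_LEN,
    polya_max_nonA: int = DEFAULT_POLYA_MAX_NONA,
) -> FLNCRecord:
    """Classify one CCS read as FL, nFL or chimeric and trim it.

    FL requires a 5' primer near one terminus, a 3' primer near the other,
    a polyA tail adjacent to the 3' primer, and no internal primer copy.
    Internal primer copies (either primer, either strand, clear of both
    terminal windows) mark the read chimeric regardless of other evidence.
    Reads are reverse-complemented as needed so the polyA sits at the 3' end.
    """
    seq = ccs.seq
    n = len(seq)

    all_hits = detect_primer(seq, primer5, max_mismatch) + detect_primer(
        seq, primer3, max_mismatch
    )
    internal = [
        h for h in all_hits if h.start > END_WINDOW and (n - h.end) > END_WINDOW
    ]
    if internal:
        return FLNCRecord(
            id=f"{ccs.id}/chimeric",
            seq=seq,
            source_read=ccs.id,
            read_class="chimeric",
        )

    best = None  # (n_evidence, oriented_seq, p5, p3, polya, was_rc)
    for was_rc, s in ((False, seq), (True, revcomp(seq))):
        p5, p3, polya = _terminal_layout(
            s, primer5, primer3, max_mismatch, polya_min_len, polya_max_nonA
        )
        n_ev = sum(x is not None for x in (p5, p3, polya))
        if best is None or n_ev > best[0]:
            best = (n_ev, s, p5, p3, polya, was_rc)
        if n_ev == 3:
            break

    n_ev, s, p5, p3, polya, was_rc = best
    if n_ev == 3:
        # trim at the contiguous pure-A run ending the tail: the tolerant
        # polyA interval may reach across interior non-A into the transcript
        trim_end = polya[1]
        while trim_end > p5.end and s[trim_end - 1].upper() == "A":
            trim_end -= 1
        trimmed = s[p5.end : trim_end]
        return FLNCRecord(
            id=f"{ccs.id}/flnc",
            seq=trimmed,
            source_read=ccs.id,
            read_class="FL",
            primer5_hit=(p5.start, p5.end),
            primer3_hit=(p3.start, p3.end),
            polya_hit=polya,
            reverse_complemented=was_rc,
        )

    # nFL: trim whatever terminal evidence was found
    start = p5.end if p5 is not None else 0
    end = len(s)
    if polya is not None:
        end = polya[0]
    elif p3 is not None:
        end = p3.start
    return FLNCRecord(
        id=f"{ccs.id}/nfl",
        seq=s[start:end],
        source_read=ccs.id,
        read_class="nFL",
        primer5_hit=(p5.start, p5.end) if p5 else None,
        primer3_hit=(p3.start, p3.end) if p3 else None,
        polya_hit=polya,
        reverse_complemented=was_rc,
    )


def classify_reads(
    reads: Sequence[CCSRead], primer5: str, primer3: str, **kwargs
) -> list[FLNCRecord]:
    """Classify a batch of filtered reads; every read receives a class."""
    return [classify_read(r, primer5, primer3, **kwargs) for r in reads]
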