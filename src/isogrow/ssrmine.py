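"""Microsatellite (SSR) detection in transcript sequences.

Perfect SSRs are maximal uninterrupted tandem runs of a primitive 1-6 bp
motif meeting per-motif-length minimum repeat counts (10 for mononucleotide,
6 for dinucleotide, 5 for tri- through hexanucleotide motifs). Detection is
restricted to transcripts longer than 500 bp. Adjacent loci separated by at
most ``max_interruption`` bp are merged into compound loci.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from ._util import revcomp

logger = logging.getLogger("isogrow.ssrmine")

#: minimum repeat count per motif length
DEFAULT_THRESHOLDS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

#: transcripts at or below this length are skipped
MIN_TRANSCRIPT_LENGTH = 500

#: maximum spacer (bp) between loci merged into one compound locus
DEFAULT_MAX_INTERRUPTION = 100

_CLASS_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass
class SSRLocus:
    transcript_id: str
    motif: str
    canonical_motif: str
    repeats: int
    start: int
    end: int
    kind: str = "perfect"  # perfect | compound


def canonical_rotation(motif: str, collapse_revcomp: bool = False) -> str:
    """Lexicographic minimum over cyclic rotations (optionally also the
    reverse-complement strand, for genomic rather than oriented input)."""
    rotations = [motif[i:] + motif[:i] for i in range(len(motif))]
    if collapse_revcomp:
        rc = revcomp(motif)
        rotations += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rotations)


def is_primitive(motif: str) -> bool:
    """True unless the motif is itself a repetition of a shorter motif."""
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def find_perfect_ssrs(
    seq: str,
    transcript_id: str = "",
    thresholds: Mapping[int, int] = DEFAULT_THRESHOLDS,
    min_transcript_length: int = MIN_TRANSCRIPT_LENGTH,
    collapse_revcomp: bool = False,
) -> list[SSRLocus]:
    """Maximal perfect tandem repeats in ``seq`` meeting the thresholds.

    The locus motif is the primitive repeat unit at the run start; runs whose
    unit is a repetition of a shorter motif are reported only at the shorter
    period (an ``AA`` x6 run surfaces as ``A`` x12). Runs containing N and
    mononucleotide N-runs are ignored. Transcripts not exceeding
    ``min_transcript_length`` yield no loci.
    """
    s = seq.upper()
    n = len(s)
    if n <= min_transcript_length:
        return []
    loci: list[SSRLocus] = []
    for m, min_rep in sorted(thresholds.items()):
        min_run = m * min_rep
        i = 0
        while i + min_run <= n:
            # left-maximality: inside a period-m run, s[i-1] == s[i+m-1]
            if i > 0 and s[i - 1] == s[i + m - 1]:
                i += 1
                continue
            j = i + m
            while j < n and s[j] == s[j - m]:
                j += 1
            repeats = (j - i) // m
            motif = s[i : i + m]
            if (
                repeats >= min_rep
                and "N" not in motif
                and is_primitive(motif)
            ):
                loci.append(
                    SSRLocus(
                        transcript_id=transcript_id,
                        motif=motif,
                        canonical_motif=canonical_rotation(motif, collapse_revcomp),
                        repeats=repeats,
                        start=i,
                        end=i + m * repeats,
                        kind="perfect",
                    )
                )
            i += 1
    loci.sort(key=lambda l: (l.start, l.end, len(l.motif)))
    return loci


def merge_compound(
    loci: Sequence[SSRLocus],
    max_interruption: int = DEFAULT_MAX_INTERRUPTION,
) -> list[SSRLocus]:
    """Merge loci of one transcript separated by <= max_interruption bp.

    Merged loci become one ``compound`` locus spanning the components, its
    motif the ``+``-joined component motifs and its repeat count their sum;
    isolated loci stay ``perfect``.
    """
    if not loci:
        return []
    ordered = sorted(loci, key=lambda l: (l.start, l.end))
    merged: list[SSRLocus] = []
    group = [ordered[0]]
    for loc in ordered[1:]:
        if loc.start - group[-1].end <= max_interruption:
            group.append(loc)
        else:
            merged.append(_collapse(group))
            group = [loc]
    merged.append(_collapse(group))
    return merged


def _collapse(group: list[SSRLocus]) -> SSRLocus:
    if len(group) == 1:
        return replace(group[0], kind="perfect")
    return SSRLocus(
        transcript_id=group[0].transcript_id,
        motif="+".join(l.motif for l in group),
        canonical_motif="+".join(l.canonical_motif for l in group),
        repeats=sum(l.repeats for l in group),
        start=group[0].start,
        end=max(l.end for l in group),
        kind="compound",
    )


def mine_transcripts(
    transcripts: Mapping[str, str],
    thresholds: Mapping[int, int] = DEFAULT_THRESHOLDS,
    min_transcript_length: int = MIN_TRANSCRIPT_LENGTH,
    max_interruption: int = DEFAULT_MAX_INTERRUPTION,
) -> tuple[list[SSRLocus], int]:
    """Run perfect-SSR detection plus compound merging over many transcripts.

    Returns (loci, number of transcripts actually scanned); skipped short
    transcripts are logged and excluded from the scanned count.
    """
    all_loci: list[SSRLocus] = []
    n_scanned = 0
    n_skipped = 0
    for tid in sorted(transcripts):
        seq = transcripts[tid]
        if len(seq) <= min_transcript_length:
            n_skipped += 1
            continue
        n_scanned += 1
        loci = find_perfect_ssrs(
            seq, tid, thresholds, min_transcript_length=min_transcript_length
        )
        all_loci.extend(merge_compound(loci, max_interruption))
    if n_skipped:
        logger.info("skipped %d transcripts at or below %d bp", n_skipped, min_transcript_length)
    return all_loci, n_scanned


def class_percentages(counts: Mapping[str, int], total: int) -> dict[str, float]:
    """Percent of ``total`` per class, rounded to 2 decimals (0 when empty)."""
    if total <= 0:
        return {k: 0.0 for k in counts}
    return {k: round(100.0 * v / total, 2) for k, v in counts.items()}


@dataclass
class SSRSummary:
    total: int
    by_motif_length: dict[str, int]
    percentages: dict[str, float]
    n_compound: int
    n_transcripts_multi_ssr: int
    empty: bool = False


def ssr_summary(loci: Iterable[SSRLocus], n_transcripts_scanned: int) -> SSRSummary:
    """Counts and percentages by motif-length class, plus compound and
    multi-SSR transcript tallies. Compound loci count once toward the total."""
    loci = list(loci)
    total = len(loci)
    by_class: Counter[str] = Counter()
    per_transcript: Counter[str] = Counter()
    n_compound = 0
    for loc in loci:
        per_transcript[loc.transcript_id] += 1
        if loc.kind == "compound":
            n_compound += 1
            by_class["compound"] += 1
        else:
            by_class[_CLASS_NAMES[len(loc.motif)]] += 1
    counts = {name: by_class.get(name, 0) for name in list(_CLASS_NAMES.values()) + ["compound"]}
    return SSRSummary(
        total=total,
        by_motif_length=counts,
        percentages=class_percentages(counts, total),
        n_compound=n_compound,
        n_transcripts_multi_ssr=sum(1 for v in per_transcript.values() if v > 1),
        empty=(total == 0),
    )
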