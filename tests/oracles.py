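"""Independent reference implementations used only to check the package.

Each oracle is written against the operation's contract, not its code:
a Gotoh dynamic-programming local aligner (numpy rows + explicit
traceback), a regex-based SSR enumerator, a positional six-frame ORF
scanner, and exhaustive window scans for primers and polyA tails.
"""

from __future__ import annotations

import re

import numpy as np

MATCH, MISMATCH, OPEN, EXT = 1.0, -2.0, -5.0, -2.0
NEG = -1e18


def _score(x: str, y: str) -> float:
    return MATCH if x == y and x in "ACGT" else MISMATCH


def sw_local(a: str, b: str):
    """Best local alignment of a vs b under affine gaps (Gotoh).

    Returns (score, blocks) with blocks a list of gap-free aligned segments
    [(qs, qe, ss, se), ...]; (0.0, []) when nothing scores positively.
    A gap of length g costs OPEN + (g - 1) * EXT.
    """
    n, m = len(a), len(b)
    enc_b = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    valid_b = np.isin(enc_b, np.frombuffer(b"ACGT", dtype=np.uint8))
    M = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    H = np.zeros((n + 1, m + 1))
    js = np.arange(1, m + 1)
    for i in range(1, n + 1):
        ai = a[i - 1].upper()
        s_row = np.where((enc_b == ord(ai)) & valid_b, MATCH, MISMATCH)
        F[i, 1:] = np.maximum(H[i - 1, 1:] + OPEN, F[i - 1, 1:] + EXT)
        M[i, 1:] = np.maximum(0.0, H[i - 1, :-1] + s_row)
        G = np.maximum(M[i], F[i])
        # E[i, j] = max_{k<j} G[k] + OPEN + (j-1-k) * EXT, via a prefix max
        A = G - np.arange(m + 1) * EXT
        runmax = np.maximum.accumulate(A)
        E[i, 1:] = runmax[:-1] + OPEN + (js - 1) * EXT
        H[i] = np.maximum.reduce([M[i], E[i], F[i], np.zeros(m + 1)])
    score = float(H.max())
    if score <= 0:
        return 0.0, []
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    pairs = []
    state = "H"
    while True:
        if state == "H":
            if H[i, j] <= 0:
                break
            if H[i, j] == M[i, j]:
                state = "M"
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "M":
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            state = "H"
        elif state == "E":
            if E[i, j] == E[i, j - 1] + EXT:
                j -= 1
            else:
                j -= 1
                state = "M" if M[i, j] >= F[i, j] else "F"
                continue
        elif state == "F":
            if F[i, j] == F[i - 1, j] + EXT:
                i -= 1
            else:
                i -= 1
                state = "M" if M[i, j] >= E[i, j] else "E"
                continue
    pairs.reverse()
    blocks = []
    for qi, sj in pairs:
        if blocks and qi == blocks[-1][1] and sj == blocks[-1][3]:
            blocks[-1][1] += 1
            blocks[-1][3] += 1
        else:
            blocks.append([qi, qi + 1, sj, sj + 1])
    return score, [tuple(bl) for bl in blocks]


def _gap_cost(g: int) -> float:
    return OPEN + (g - 1) * EXT if g > 0 else 0.0


def iterated_hsps(a: str, b: str, min_score: float = 50.0, split_gap: int = 30):
    """Reference align-split-mask-repeat HSP enumeration.

    Mirrors the contract: best local alignment, split at internal gaps
    > split_gap on either axis, keep pieces scoring >= min_score, mask every
    piece footprint, repeat. Returns (qs, qe, ss, se, score) tuples sorted
    by qs.
    """
    qa, qb = a.upper(), b.upper()
    hsps = []
    for _ in range(50):
        score, blocks = sw_local(qa, qb)
        if score < min_score:
            break
        pieces = [[blocks[0]]]
        for prev, cur in zip(blocks, blocks[1:]):
            if cur[0] - prev[1] > split_gap or cur[2] - prev[3] > split_gap:
                pieces.append([cur])
            else:
                pieces[-1].append(cur)
        for piece in pieces:
            s = 0.0
            for k, blk in enumerate(piece):
                s += sum(_score(x, y) for x, y in zip(qa[blk[0] : blk[1]], qb[blk[2] : blk[3]]))
                if k:
                    s += _gap_cost(blk[0] - piece[k - 1][1])
                    s += _gap_cost(blk[2] - piece[k - 1][3])
            qs, qe = piece[0][0], piece[-1][1]
            ss, se = piece[0][2], piece[-1][3]
            if s >= min_score:
                hsps.append((qs, qe, ss, se, s))
            qa = qa[:qs] + "X" * (qe - qs) + qa[qe:]
            qb = qb[:ss] + "X" * (se - ss) + qb[se:]
    return sorted(hsps)


# ---------------------------------------------------------------------------


def regex_ssrs(seq: str, thresholds: dict[int, int]) -> set[tuple]:
    """All maximal perfect SSR runs via overlapped regex search.

    Returns {(motif, repeats, start, end)} for primitive motifs at
    left-maximal run starts meeting the thresholds.
    """

    def primitive(m: str) -> bool:
        return all(
            not (len(m) % d == 0 and m == m[:d] * (len(m) // d))
            for d in range(1, len(m))
        )

    s = seq.upper()
    out = set()
    for m, k in thresholds.items():
        pat = re.compile(r"(?=(([ACGT]{%d})\2{%d,}))" % (m, k - 1))
        for match in pat.finditer(s):
            run, motif = match.group(1), match.group(2)
            start = match.start()
            repeats = len(run) // m
            end = start + m * repeats
            if "N" in motif or not primitive(motif):
                continue
            # left-maximal: the run cannot extend one base to the left
            if start > 0 and s[start - 1] == s[start + m - 1]:
                continue
            out.add((motif, repeats, start, end))
    return out


# ---------------------------------------------------------------------------


def six_frame_orfs(seq: str, min_aa: int) -> set[tuple]:
    """Positional six-frame ORF enumeration.

    Returns {(strand, start, end, aa, completeness)} in transcript (forward)
    coordinates, mirroring the reporting contract: complete / 5prime_partial
    / 3prime_partial / internal, min_aa on the protein length.
    """
    comp = str.maketrans("ACGTN", "TGCAN")
    out = set()
    n = len(seq)
    for strand in "+-":
        s = seq.upper() if strand == "+" else seq.upper().translate(comp)[::-1]
        for frame in range(3):
            codons = [s[p : p + 3] for p in range(frame, n - 2, 3)]
            positions = list(range(frame, n - 2, 3))
            # segment boundaries at stops
            seg = []
            segments = []
            for c, p in zip(codons, positions):
                seg.append((c, p))
                if c in ("TAA", "TAG", "TGA"):
                    segments.append((seg, True))
                    seg = []
            if seg:
                segments.append((seg, False))
            first = True
            for seg, has_stop in segments:
                atg = next((p for c, p in seg if c == "ATG"), None)
                if atg is not None:
                    begin = atg
                    cls = "complete" if has_stop else "3prime_partial"
                elif first:
                    begin = seg[0][1]
                    cls = "5prime_partial" if has_stop else "internal"
                else:
                    first = False
                    continue
                first = False
                end = seg[-1][1] + 3
                aa = (end - begin) // 3 - (1 if has_stop else 0)
                if aa < min_aa:
                    continue
                if strand == "+":
                    out.add((strand, begin, end, aa, cls))
                else:
                    out.add((strand, n - end, n - begin, aa, cls))
    return out


# ---------------------------------------------------------------------------


def brute_primer_hits(seq: str, primer: str, max_mm: int) -> set[tuple]:
    """Every (start, strand, mismatches) sliding-window occurrence."""
    comp = str.maketrans("ACGTN", "TGCAN")
    rc = primer.translate(comp)[::-1]
    out = set()
    for strand, pat in (("+", primer), ("-", rc)):
        for i in range(len(seq) - len(pat) + 1):
            mm = sum(1 for x, y in zip(seq[i : i + len(pat)], pat) if x != y)
            if mm <= max_mm:
                out.add((i, strand, mm))
    return out


def brute_polya(seq: str, min_len: int, max_nonA: int):
    """Exhaustive best polyA interval: max end, then max length."""
    s = seq.upper()
    best = None
    for j in range(len(s), min_len - 1, -1):
        for i in range(0, j - min_len + 1):
            window = s[i:j]
            if window[0] == "A" and window[-1] == "A" and window.count("A") >= len(window) - max_nonA:
                cand = (i, j)
                if best is None or j > best[1] or (j == best[1] and j - i > best[1] - best[0]):
                    best = cand
        if best is not None and best[1] == j:
            return best
    return best
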