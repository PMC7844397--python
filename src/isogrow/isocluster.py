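"""Isoform clustering, consensus polishing, dedup, and gene families.

FLNC sequences are greedily clustered at a global-identity threshold, each
cluster is polished to a per-column majority-vote consensus against its
representative, consensi are deduplicated at 0.99 identity (identity is
matches over the shorter sequence, the cited redundancy-removal tool's
semantics), and the surviving transcripts are partitioned into gene
families by cosine similarity of k-mer count profiles.

Determinism: every greedy pass processes sequences longest-first with
lexicographic id tie-breaks.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from math import sqrt
from typing import Mapping, Optional, Sequence

import edlib

DEFAULT_IDENTITY = 0.99
DEFAULT_KMER = 8
DEFAULT_FAMILY_SIMILARITY = 0.5
DEFAULT_MIN_SHARED_KMERS = 5


@dataclass
class Cluster:
    id: str
    members: list[str]
    representative: str
    consensus: str = ""
    identity_threshold: float = DEFAULT_IDENTITY


@dataclass
class GeneFamily:
    id: str
    members: list[str]
    centroid: dict[str, float] = field(default_factory=dict)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Identity of the shorter sequence against the longer.

    1 - edit_distance / len(shorter), with the shorter sequence aligned as
    an infix of the longer so full containment scores 1.0.
    """
    if not seq_a or not seq_b:
        return 0.0
    short, long_ = sorted((seq_a, seq_b), key=len)
    dist = edlib.align(short, long_, mode="HW")["editDistance"]
    return max(0.0, 1.0 - dist / len(short))


def _ordered_ids(seqs: Mapping[str, str]) -> list[str]:
    return sorted(seqs, key=lambda i: (-len(seqs[i]), i))


def greedy_cluster(
    flnc_seqs: Mapping[str, str], identity_threshold: float = DEFAULT_IDENTITY
) -> list[Cluster]:
    """Greedy longest-first clustering at a global identity threshold.

    Each sequence joins the first existing cluster whose representative it
    matches at identity >= threshold (identity over the shorter sequence),
    else founds a new cluster. Every input id lands in exactly one cluster.
    """
    clusters: list[Cluster] = []
    for sid in _ordered_ids(flnc_seqs):
        seq = flnc_seqs[sid]
        placed = False
        for cl in clusters:
            if pairwise_identity(seq, flnc_seqs[cl.representative]) >= identity_threshold:
                cl.members.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(
                    id=f"cluster{len(clusters)}",
                    members=[sid],
                    representative=sid,
                    identity_threshold=identity_threshold,
                )
            )
    return clusters


def majority_consensus(cluster: Cluster, seqs: Mapping[str, str]) -> str:
    """Per-column majority-vote consensus of cluster members.

    Members are globally aligned to the representative; each representative
    column collects one vote per member (a base, or a gap when the member
    lacks the column). Majority wins; ties fall back to the representative's
    base; a gap majority drops the column. Insertions relative to the
    representative are ignored. A singleton cluster returns its member
    unchanged.
    """
    if not cluster.members:
        raise ValueError("cluster has no members")
    rep = seqs[cluster.representative]
    if len(cluster.members) == 1:
        return rep
    votes: list[Counter] = [Counter() for _ in rep]
    for mid in cluster.members:
        member = seqs[mid]
        if mid == cluster.representative:
            for col, base in enumerate(rep):
                votes[col][base] += 1
            continue
        aln = edlib.align(member, rep, task="path", mode="NW")
        qpos = tpos = 0
        for length, op in _cigar_ops(aln["cigar"]):
            if op in "=X":
                for i in range(length):
                    votes[tpos + i][member[qpos + i]] += 1
                qpos += length
                tpos += length
            elif op == "I":  # extra member bases: no representative column
                qpos += length
            elif op == "D":  # member lacks these representative columns
                for i in range(length):
                    votes[tpos + i]["-"] += 1
                tpos += length
    out = []
    for col, counter in enumerate(votes):
        top = max(counter.values())
        winners = sorted(b for b, c in counter.items() if c == top)
        base = rep[col] if rep[col] in winners else winners[0]
        if base != "-":
            out.append(base)
    return "".join(out)


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def polish_clusters(clusters: Sequence[Cluster], seqs: Mapping[str, str]) -> None:
    """Fill each cluster's consensus in place."""
    for cl in clusters:
        cl.consensus = majority_consensus(cl, seqs)


def dedup_transcripts(
    consensi: Mapping[str, str], c: float = DEFAULT_IDENTITY
) -> tuple[list[str], dict[str, str]]:
    """Greedy longest-first redundancy removal at identity cutoff ``c``.

    A sequence matching an already-retained representative at identity >= c
    (matches over the shorter sequence) is dropped and mapped to it. Returns
    (retained ids, membership map id -> retained representative).
    """
    retained: list[str] = []
    membership: dict[str, str] = {}
    for sid in _ordered_ids(consensi):
        seq = consensi[sid]
        rep = next(
            (r for r in retained if pairwise_identity(seq, consensi[r]) >= c), None
        )
        if rep is None:
            retained.append(sid)
            membership[sid] = sid
        else:
            membership[sid] = rep
    return retained, membership


def kmer_profile(seq: str, k: int = DEFAULT_KMER) -> Counter:
    s = seq.upper()
    return Counter(s[i : i + k] for i in range(len(s) - k + 1))


def cosine_similarity(a: Counter, b: Counter) -> float:
    if not a or not b:
        return 0.0
    shared = set(a) & set(b)
    dot = sum(a[x] * b[x] for x in shared)
    norm = sqrt(sum(v * v for v in a.values())) * sqrt(sum(v * v for v in b.values()))
    return dot / norm if norm else 0.0


def family_partition(
    transcripts: Mapping[str, str],
    k: int = DEFAULT_KMER,
    similarity_threshold: float = DEFAULT_FAMILY_SIMILARITY,
    min_shared_kmers: int = DEFAULT_MIN_SHARED_KMERS,
) -> list[GeneFamily]:
    """Partition transcripts into gene families by k-mer profile similarity.

    Pairs sharing >= min_shared_kmers distinct k-mers are scored by cosine
    similarity of their k-mer count profiles; pairs at or above the
    threshold are connected and families are the connected components.
    """
    if not 4 <= k <= 16:
        raise ValueError("k must be in [4, 16]")
    ids = sorted(transcripts)
    profiles = {i: kmer_profile(transcripts[i], k) for i in ids}

    # inverted index prefilter: count distinct shared k-mers per pair
    index: dict[str, list[str]] = {}
    for i in ids:
        for kmer in profiles[i]:
            index.setdefault(kmer, []).append(i)
    shared: Counter = Counter()
    for kmer, holders in index.items():
        if len(holders) > 1:
            for a, b in itertools.combinations(holders, 2):
                shared[(a, b)] += 1

    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), n_shared in sorted(shared.items()):
        if n_shared < min_shared_kmers:
            continue
        if cosine_similarity(profiles[a], profiles[b]) >= similarity_threshold:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    families = []
    for idx, root in enumerate(sorted(groups)):
        members = sorted(groups[root])
        profile_sum: Counter = Counter()
        for m in members:
            profile_sum.update(profiles[m])
        centroid = {km: v / len(members) for km, v in profile_sum.items()}
        families.append(GeneFamily(id=f"family{idx}", members=members, centroid=centroid))
    return families
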