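"""HSP finding and the three-criteria AS evaluation."""

import numpy as np
import pytest

from conftest import random_dna
from oracles import iterated_hsps

from isogrow.splicescan import HSP, evaluate_as_pair, find_hsps, scan_all_pairs


def _impl_tuples(hsps):
    return sorted(
        (h.query_start, h.query_end, h.subject_start, h.subject_end, h.score)
        for h in hsps
    )


def test_identical_sequences_single_full_hsp(rng):
    a = random_dna(rng, 1500)
    hsps = find_hsps(a, a)
    assert len(hsps) == 1
    h = hsps[0]
    assert (h.query_start, h.query_end, h.subject_start, h.subject_end) == (0, 1500, 0, 1500)
    assert h.identity == 1.0


def test_internal_deletion_yields_two_flanking_hsps(rng):
    a = random_dna(rng, 1500)
    b = a[:700] + a[850:]  # 150 bp internal deletion
    hsps = find_hsps(a, b)
    assert len(hsps) == 2
    h1, h2 = hsps
    # gap placement can shift within repeated junction context, but the
    # flanks and the 150 bp gap are fixed
    assert abs(h1.query_end - 700) <= 10
    assert h2.query_start - h1.query_end == 150
    assert h2.subject_start - h1.subject_end <= 5


def test_unrelated_sequences_no_hsps(rng):
    assert find_hsps(random_dna(rng, 800), random_dna(rng, 800)) == []


@pytest.mark.parametrize("seed,dels", [(1, [(700, 150)]), (2, [(400, 200)]), (3, [])])
def test_find_hsps_agrees_with_dp_oracle(seed, dels):
    rng = np.random.default_rng(seed)
    a = random_dna(rng, 1400)
    b = a
    for pos, length in dels:
        b = b[:pos] + b[pos + length :]
    # sprinkle substitutions and a couple of small indels
    b = list(b)
    for pos in rng.choice(len(b) - 10, 8, replace=False):
        b[pos] = "ACGT"[rng.integers(0, 4)]
    b = "".join(b)
    assert _impl_tuples(find_hsps(a, b)) == [
        tuple(int(v) if i < 4 else float(v) for i, v in enumerate(t))
        for t in iterated_hsps(a, b)
    ]


def test_find_hsps_oracle_on_unrelated_pairs():
    rng = np.random.default_rng(9)
    a, b = random_dna(rng, 900), random_dna(rng, 900)
    assert _impl_tuples(find_hsps(a, b)) == list(iterated_hsps(a, b))


def _as_pair(rng, total=1500, pos=700, gap=150):
    a = random_dna(rng, total)
    b = a[:pos] + a[pos + gap :]
    return a, b


def test_planted_skip_produces_event_with_exact_gap(rng):
    a, b = _as_pair(rng)
    ev = evaluate_as_pair(a, b, find_hsps(a, b), "t1", "t2")
    assert ev is not None
    assert ev.gap_length == 150
    assert ev.gap_on == "a"
    # junction may shift a few bases within repeated context
    assert abs(ev.gap_interval[0] - 700) <= 10
    assert abs(ev.distance_to_5prime - 700) <= 10
    assert abs(ev.distance_to_3prime - 650) <= 10


def test_identical_pair_is_not_an_event(rng):
    a = random_dna(rng, 1500)
    assert evaluate_as_pair(a, a, find_hsps(a, a)) is None


def test_gap_at_most_100_rejected(rng):
    a, b = _as_pair(rng, gap=80)
    assert evaluate_as_pair(a, b, find_hsps(a, b)) is None


def test_short_transcripts_rejected(rng):
    a, b = _as_pair(rng, total=990, pos=400, gap=150)
    assert evaluate_as_pair(a, b, find_hsps(a, b)) is None


def test_gap_too_close_to_end_rejected(rng):
    a, b = _as_pair(rng, total=1500, pos=1290, gap=150)  # 60 bp from 3' end
    assert evaluate_as_pair(a, b, find_hsps(a, b)) is None


def test_event_symmetry(rng):
    a, b = _as_pair(rng)
    ev_ab = evaluate_as_pair(a, b, find_hsps(a, b))
    ev_ba = evaluate_as_pair(b, a, find_hsps(b, a))
    assert ev_ab is not None and ev_ba is not None
    assert ev_ab.gap_length == ev_ba.gap_length
    assert {ev_ab.gap_on, ev_ba.gap_on} == {"a", "b"}


def test_emitted_events_satisfy_invariants(sim_small):
    cfg, transcripts, truth = sim_small
    events = scan_all_pairs(transcripts.seqs)
    for ev in events:
        assert ev.gap_length > 100
        assert ev.distance_to_5prime >= 100
        assert ev.distance_to_3prime >= 100
        assert ev.overlap <= 5


def test_scan_recovers_planted_pairs_and_nothing_else(sim_small):
    cfg, transcripts, truth = sim_small
    found = {tuple(sorted((e.transcript_a, e.transcript_b))) for e in scan_all_pairs(transcripts.seqs)}
    eligible = {
        tuple(sorted(p))
        for p in truth.as_pairs
        if len(transcripts.seqs[p[0]]) > 1000 and len(transcripts.seqs[p[1]]) > 1000
    }
    assert found == eligible


def test_scan_is_permutation_invariant(sim_small):
    cfg, transcripts, truth = sim_small
    sub = dict(list(transcripts.seqs.items())[:12])
    shuffled = dict(reversed(list(sub.items())))
    key = lambda evs: {tuple(sorted((e.transcript_a, e.transcript_b))) for e in evs}
    assert key(scan_all_pairs(sub)) == key(scan_all_pairs(shuffled))


def test_null_families_give_zero_events():
    from isogrow import syndata

    cfg = syndata.SimConfig(n_genes=30, as_pair_fraction=0.0, seed=13)
    transcripts, truth = syndata.simulate_transcriptome(cfg)
    assert truth.as_pairs == set()
    assert scan_all_pairs(transcripts.seqs) == []


def test_three_hsps_rejected_as_ambiguous(rng):
    a = random_dna(rng, 2000)
    b = a[:500] + a[650:1200] + a[1350:]  # two skipped blocks
    hsps = find_hsps(a, b)
    assert len(hsps) == 3
    assert evaluate_as_pair(a, b, hsps) is None


def test_hsp_invariants_enforced():
    with pytest.raises(ValueError):
        HSP(10, 10, 0, 5, 50.0, 1.0)
    with pytest.raises(ValueError):
        HSP(0, 5, 0, 5, 0.0, 1.0)
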