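"""FPKM, the NB Wald screen, BH adjustment and DEG gating."""

import numpy as np
import pandas as pd
import pytest

from isogrow import syndata
from isogrow.dge import (
    CountMatrix,
    DEResult,
    bh_adjust,
    de_results,
    fpkm,
    nb_test,
    screen_degs,
    shared_degs,
    size_factors,
)


def _matrix(counts, lengths=None, samples=None):
    samples = samples or [f"{g}_F_{r}" for g in ("BG", "SG") for r in (1, 2, 3)]
    genes = [f"g{i}" for i in range(len(counts))]
    df = pd.DataFrame(counts, index=genes, columns=samples)
    return CountMatrix(
        counts=df,
        lengths=pd.Series(lengths if lengths is not None else 1000, index=genes),
        groups=pd.Series({s: s.split("_")[0] for s in samples}),
        tissues=pd.Series({s: s.split("_")[1] for s in samples}),
    )


def test_fpkm_unit_case():
    m = _matrix([[10] + [0] * 5, [999_990] + [10**6] * 5], lengths=[1000, 10_000])
    out = fpkm(m)
    assert out.iloc[0, 0] == pytest.approx(10.0)


def test_fpkm_scale_invariance():
    rng = np.random.default_rng(0)
    counts = rng.integers(1, 200, size=(30, 6))
    m1 = _matrix(counts)
    scaled = counts.copy()
    scaled[:, 0] *= 7
    m2 = _matrix(scaled)
    pd.testing.assert_series_equal(fpkm(m1).iloc[:, 0], fpkm(m2).iloc[:, 0])


def test_fpkm_matches_cellwise_formula():
    rng = np.random.default_rng(1)
    counts = rng.integers(0, 500, size=(20, 6))
    lengths = rng.integers(200, 5000, size=20)
    m = _matrix(counts, lengths=lengths)
    out = fpkm(m)
    N = counts.sum(axis=0)
    for i in range(20):
        for j in range(6):
            expected = counts[i, j] / ((lengths[i] / 1e3) * (N[j] / 1e6))
            assert out.iloc[i, j] == pytest.approx(expected)


def test_fpkm_zero_library_errors():
    m = _matrix([[0, 1, 1, 1, 1, 1]])
    with pytest.raises(ValueError, match="BG_F_1"):
        fpkm(m)


def test_bh_all_equal_pvalues():
    q = bh_adjust([0.2, 0.2, 0.2, 0.2])
    assert np.allclose(q, 0.2)


def test_bh_hand_computed_stepup():
    q = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
    q2 = bh_adjust([0.005, 0.04, 0.03, 0.9])
    # hand step-up: sorted (0.005, 0.03, 0.04, 0.9) -> (0.02, 0.053..., 0.053..., 0.9)
    assert np.allclose(q2, [0.02, 0.16 / 3, 0.16 / 3, 0.9])


def test_bh_monotone_in_rank_and_top_rank_identity():
    rng = np.random.default_rng(2)
    p = rng.uniform(size=200)
    q = bh_adjust(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    assert q[order][-1] == pytest.approx(p[order][-1])


def test_bh_permutation_invariant():
    rng = np.random.default_rng(3)
    p = rng.uniform(size=50)
    perm = rng.permutation(50)
    assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


def test_bh_rejects_bad_pvalues():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_size_factors_recover_depth_ratio():
    rng = np.random.default_rng(4)
    base = rng.integers(50, 500, size=100)
    counts = np.column_stack([base, base * 2, base, base, base, base])
    m = _matrix(counts)
    sf = size_factors(m.counts)
    assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0, rel=0.01)


def test_identical_groups_null_result():
    counts = np.tile(np.array([[100], [50], [200]]), (1, 6))
    m = _matrix(counts)
    tab = nb_test(m, "F")
    assert np.allclose(tab["log2fc"], 0.0)
    assert (tab["p"].dropna() > 0.99).all()


def test_nb_test_requires_replicates():
    m = _matrix(np.ones((5, 2), dtype=int) * 10, samples=["BG_F_1", "SG_F_1"])
    with pytest.raises(ValueError):
        nb_test(m, "F")


def test_null_type_one_error_in_band():
    """Empirical type-I error at alpha=0.05 over 2,000 null genes, n=3."""
    rng = np.random.default_rng(31)
    base = np.exp(rng.normal(4.5, 1.0, 2000))
    r_ = 1 / 0.1
    counts = np.column_stack([rng.negative_binomial(r_, r_ / (r_ + base)) for _ in range(6)])
    m = _matrix(counts)
    tab = nb_test(m, "F")
    p = tab.loc[tab["tested"], "p"].dropna()
    rate = (p < 0.05).mean()
    assert 0.03 <= rate <= 0.07


def test_sign_recovery_of_planted_effects():
    cfg = syndata.SimConfig(
        n_genes=500, de_fraction=0.1, log2fc_effect=2.0, nb_dispersion=0.1, seed=7
    )
    transcripts, _ = syndata.simulate_transcriptome(cfg)
    matrix, de_truth = syndata.simulate_count_matrix(transcripts, cfg)
    tab = nb_test(matrix, "F")
    ok = sum(np.sign(tab.loc[g, "log2fc"]) == np.sign(l) for g, l in de_truth.items())
    assert ok / len(de_truth) >= 0.95


@pytest.mark.parametrize(
    "log2fc,q,is_deg",
    [
        (0.5, 0.001, False),  # fails the fold-change gate
        (1.0, 0.009, True),  # both boundaries inclusive/strict as defined
        (-2.0, 0.02, False),  # fails the FDR gate
        (-1.0, 0.0099, True),
        (0.999, 0.001, False),
        (3.0, 0.01, False),  # FDR cut is strict
    ],
)
def test_deg_gate_grid(log2fc, q, is_deg):
    r = DEResult("g", "F", log2fc, 0.001, q, "up" if log2fc > 0 else "down", False)
    sets = screen_degs([r])
    flagged = r.gene in sets["F"]["up"] | sets["F"]["down"]
    assert flagged == is_deg


def test_screen_counts_direction():
    results = [
        DEResult("a", "F", 2.0, 1e-5, 1e-4, "up", True),
        DEResult("b", "F", -1.5, 1e-5, 1e-4, "down", True),
        DEResult("c", "V", 1.2, 1e-5, 1e-4, "up", True),
    ]
    sets = screen_degs(results)
    assert sets["F"]["up"] == {"a"} and sets["F"]["down"] == {"b"}
    assert sets["V"]["up"] == {"c"}


def test_shared_degs_set_semantics():
    assert shared_degs({"a", "b"}, {"c"})[0] == set()
    assert shared_degs({"a", "b"}, {"a", "b"})[0] == {"a", "b"}
    shared, discordant = shared_degs(
        {"up": {"a"}, "down": {"b"}}, {"up": {"b"}, "down": set()}
    )
    assert shared == {"b"} and discordant == {"b"}


def test_shared_planted_de_genes_recovered():
    cfg = syndata.SimConfig(
        n_genes=200, de_fraction=0.06, log2fc_effect=4.0, nb_dispersion=0.05, seed=19
    )
    transcripts, _ = syndata.simulate_transcriptome(cfg)
    matrix, de_truth = syndata.simulate_count_matrix(transcripts, cfg)
    degs = {}
    for tissue in ("F", "V"):
        res = de_results(matrix, tissue, max_fdr=0.05, min_abs_log2fc=1.0)
        s = screen_degs(res, max_fdr=0.05)
        degs[tissue] = s.get(tissue, {"up": set(), "down": set()})
    flat = lambda d: d["up"] | d["down"]
    shared, discordant = shared_degs(degs["F"], degs["V"])
    # exactly the genes the screen recovered in both tissues, no others
    assert shared == flat(degs["F"]) & flat(degs["V"])
    assert shared <= set(de_truth)  # no false positives among shared calls
    assert shared and discordant == set()
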