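"""Enrichment arithmetic, key-gene strategies, phenotype and qPCR math."""

import math

import numpy as np
import pandas as pd
import pytest

from isogrow.triage import (
    KEY_PATHWAYS,
    AnnotationMap,
    cross_tissue_strategy,
    ddct_fold_change,
    enrich_hypergeometric,
    go_recurrence_strategy,
    pathway_frequency_strategy,
    phenotype_ratios,
    select_key_genes,
)


def _annotation(pathways=None, go=None, universe=None):
    pathways = pathways or {}
    go = go or {}
    universe = universe or set(pathways) | set(go)
    return AnnotationMap(pathways=pathways, go_terms=go, universe=universe)


def _hypergeom_mass(N, K, n, k):
    return (math.comb(K, k) * math.comb(N - K, n - k)) / math.comb(N, n)


def test_hypergeometric_extreme_draw_closed_form():
    universe = {f"g{i}" for i in range(20)}
    hit = {f"g{i}" for i in range(5)}
    ann = _annotation(pathways={g: {"P"} for g in hit}, universe=universe)
    df = enrich_hypergeometric(hit, ann, "pathway").set_index("term")
    assert df.loc["P", "p"] == pytest.approx(1 / math.comb(20, 5))


def test_hypergeometric_matches_direct_summation():
    rng = np.random.default_rng(5)
    universe = {f"g{i}" for i in range(40)}
    members = set(rng.choice(sorted(universe), 12, replace=False))
    ann = _annotation(pathways={g: {"P"} for g in members}, universe=universe)
    gene_set = set(rng.choice(sorted(universe), 15, replace=False))
    df = enrich_hypergeometric(gene_set, ann, "pathway").set_index("term")
    k = len(gene_set & members)
    direct = sum(
        _hypergeom_mass(40, 12, 15, x) for x in range(k, min(12, 15) + 1)
    )
    assert df.loc["P", "p"] == pytest.approx(direct)


def test_hypergeometric_empty_universe_errors():
    ann = AnnotationMap(pathways={}, go_terms={}, universe=set())
    with pytest.raises(ValueError):
        enrich_hypergeometric(set(), ann)


def test_pathway_frequency_counts_and_ranking():
    ann = _annotation(
        pathways={
            "b2m": {
                "Cell adhesion molecules (CAMs)",
                "Intestinal immune network for IgA production",
                "Phagosome",
            },
            "solo": {"Phagosome"},
            "none": set(),
        }
    )
    hits = pathway_frequency_strategy(["b2m", "solo", "none"], ann, KEY_PATHWAYS, min_pathways=2)
    assert hits == [("b2m", 3)]


def test_pathway_frequency_empty_panel():
    ann = _annotation(pathways={"a": {"P"}})
    assert pathway_frequency_strategy(["a"], ann, key_pathways=[]) == []


def test_go_recurrence_strict_more_than_two():
    ann = _annotation(
        go={
            "two": {("GO:1", "metabolic process"), ("GO:2", "immune system process")},
            "three": {
                ("GO:1", "metabolic process"),
                ("GO:2", "metabolic process"),
                ("GO:3", "biological regulation"),
            },
            "offcat": {("GO:4", "other"), ("GO:5", "other"), ("GO:6", "other")},
        }
    )
    hits = go_recurrence_strategy(["two", "three", "offcat"], ann)
    assert hits == [("three", 3)]
    assert go_recurrence_strategy([], ann) == []


def test_cross_tissue_intersection():
    assert cross_tissue_strategy([{"a", "b"}, {"b", "c"}]) == {"b"}
    assert cross_tissue_strategy([{"a"}, {"b"}]) == set()
    with pytest.raises(ValueError):
        cross_tissue_strategy([{"a"}])


def test_select_key_genes_disjoint_sums():
    pw = [(f"p{i}", 2) for i in range(10)]
    go = [(f"g{i}", 3) for i in range(7)]
    ct = {f"c{i}" for i in range(3)}
    report = select_key_genes(pw, go, ct)
    assert len(report.genes) == 20
    assert all(report.strategies[g] for g in report.genes)


def test_select_key_genes_overlap_single_listing():
    report = select_key_genes([("x", 2)], [("x", 3)], {"x"})
    assert report.genes == ["x"]
    assert report.strategies["x"] == {"pathway_frequency", "go_recurrence", "cross_tissue"}
    strict = select_key_genes([("x", 2), ("y", 2)], [("x", 3)], {"x"}, mode="intersection")
    assert strict.genes == ["x"]


def test_select_key_genes_empty():
    assert select_key_genes([], [], set()).genes == []


def _table1():
    return pd.DataFrame(
        {
            "group": ["BG", "SG"],
            "BL": [21.30, 16.13],
            "HL": [6.90, 5.66],
            "HH": [6.10, 4.80],
            "HW": [4.23, 3.26],
            "BW": [185.90, 80.97],
        }
    )


def test_phenotype_ratio_big_group_reproduces_printed_value():
    out = phenotype_ratios(_table1())
    assert out["hl_bl_ratio"]["BG"] == 0.3239


def test_phenotype_ratio_small_group_from_means():
    # direct division of the group means; the published text value (0.3533)
    # differs slightly, consistent with per-fish averaging upstream
    out = phenotype_ratios(_table1())
    assert out["hl_bl_ratio"]["SG"] == 0.3509


def test_phenotype_ratio_identity_and_validation():
    df = pd.DataFrame({"group": ["X"], "BL": [5.0], "HL": [5.0]})
    assert phenotype_ratios(df)["hl_bl_ratio"]["X"] == 1.0
    bad = pd.DataFrame({"group": ["X"], "BL": [0.0], "HL": [5.0]})
    with pytest.raises(ValueError):
        phenotype_ratios(bad)


def test_phenotype_welch_tests_on_per_fish_values():
    rng = np.random.default_rng(6)
    rows = []
    for grp, mean in (("BG", 21.3), ("SG", 16.1)):
        for _ in range(3):
            rows.append({"group": grp, "BL": mean + rng.normal(0, 0.2), "HL": mean / 3})
    out = phenotype_ratios(pd.DataFrame(rows))
    assert out["welch_tests"]["BL"]["significant"]


def _ct_table():
    return pd.DataFrame(
        {
            "group": ["BG", "BG", "SG", "SG"],
            "actb": [15.0, 15.0, 15.0, 15.0],
            "sgk1": [20.0, 20.0, 22.0, 22.0],
        }
    )


def test_ddct_worked_example_fold_4():
    folds = ddct_fold_change(_ct_table(), reference_gene="actb", calibrator_group="SG")
    assert folds["sgk1"] == pytest.approx(4.0)


def test_ddct_zero_and_unit_shifts():
    ct = _ct_table()
    ct.loc[ct.group == "SG", "sgk1"] = 20.0
    assert ddct_fold_change(ct, "actb", "SG")["sgk1"] == pytest.approx(1.0)
    ct.loc[ct.group == "SG", "sgk1"] = 19.0  # ddCt = +1 for BG
    assert ddct_fold_change(ct, "actb", "SG")["sgk1"] == pytest.approx(0.5)


def test_ddct_group_swap_reciprocal():
    fwd = ddct_fold_change(_ct_table(), "actb", calibrator_group="SG")["sgk1"]
    rev = ddct_fold_change(_ct_table(), "actb", calibrator_group="BG")["sgk1"]
    assert fwd * rev == pytest.approx(1.0)


def test_ddct_missing_reference_errors():
    with pytest.raises(ValueError):
        ddct_fold_change(_ct_table().drop(columns="actb"), "actb", "SG")
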