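"""Enrichment, key-gene triage, phenotype ratios and qPCR fold changes.

Key growth-candidate genes are selected by three strategies: (i) recurrence
across a fixed panel of key pathways, (ii) recurrence (> 2 hits) within the
GO categories biological regulation, immune system process and metabolic
process, and (iii) differential expression shared across both bone tissues.
The report is the union of the strategies with per-gene provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dge import bh_adjust

#: the fixed panel of key growth-regulation pathways
KEY_PATHWAYS: tuple[str, ...] = (
    "Adrenergic signaling in cardiomyocytes",
    "Arginine and proline metabolism",
    "Biosynthesis of unsaturated fatty acids",
    "Carbon metabolism",
    "Cardiac muscle contraction",
    "Cell adhesion molecules (CAMs)",
    "Citrate cycle (TCA cycle)",
    "Fatty acid metabolism",
    "FoxO signaling pathway",
    "Intestinal immune network for IgA production",
    "mTOR signaling pathway",
    "Oxidative phosphorylation",
    "PPAR signaling pathway",
    "Regulation of actin cytoskeleton",
    "Phagosome",
)

GO_CATEGORIES = ("biological regulation", "immune system process", "metabolic process")

DEFAULT_MIN_PATHWAYS = 2
DEFAULT_MIN_GO_OCCURRENCES = 3  # "more than two times"


@dataclass
class AnnotationMap:
    """Gene -> pathways, gene -> (GO term, category) pairs, and the universe."""

    pathways: dict[str, set[str]]  # gene -> pathway ids
    go_terms: dict[str, set[tuple[str, str]]]  # gene -> {(term, category)}
    universe: set[str]

    def __post_init__(self) -> None:
        annotated = set(self.pathways) | set(self.go_terms)
        stray = annotated - self.universe
        if stray:
            raise ValueError(f"annotated genes outside the universe: {sorted(stray)[:5]}")

    def genes_in_pathway(self, pathway: str) -> set[str]:
        return {g for g, ps in self.pathways.items() if pathway in ps}


@dataclass
class KeyGeneReport:
    genes: list[str]
    strategies: dict[str, set[str]]  # gene -> strategy names
    evidence: dict[str, dict]


def enrich_hypergeometric(
    gene_set: set[str], annotation: AnnotationMap, term_type: str = "pathway"
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of ``gene_set`` per term.

    For each term with K annotated genes in a universe of N, and k of the
    n = |gene_set| genes hitting it, p = P(X >= k); q is BH-adjusted across
    the terms of this term_type. Terms with K = 0 are flagged and skipped.
    """
    if not annotation.universe:
        raise ValueError("annotation universe is empty")
    stray = gene_set - annotation.universe
    if stray:
        raise ValueError(f"gene_set not within universe: {sorted(stray)[:5]}")
    if term_type == "pathway":
        gene2terms = annotation.pathways
    elif term_type == "GO":
        gene2terms = {g: {t for t, _ in pairs} for g, pairs in annotation.go_terms.items()}
    else:
        raise ValueError(f"unknown term_type {term_type!r}")

    term2genes: dict[str, set[str]] = {}
    for g, terms in gene2terms.items():
        for t in terms:
            term2genes.setdefault(t, set()).add(g)

    N = len(annotation.universe)
    n = len(gene_set)
    rows = []
    for term in sorted(term2genes):
        K = len(term2genes[term])
        k = len(gene_set & term2genes[term])
        if K == 0:
            rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": np.nan, "skipped": True})
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0), "skipped": False})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = np.nan
        usable = ~df["skipped"]
        if usable.any():
            df.loc[usable, "q"] = bh_adjust(df.loc[usable, "p"].values)
    return df


def pathway_frequency_strategy(
    degs: Iterable[str],
    annotation: AnnotationMap,
    key_pathways: Sequence[str] = KEY_PATHWAYS,
    min_pathways: int = DEFAULT_MIN_PATHWAYS,
) -> list[tuple[str, int]]:
    """DEGs participating in >= min_pathways of the key pathways, ranked by
    participation count (ties: gene id)."""
    if not key_pathways:
        return []
    key = set(key_pathways)
    hits = []
    for gene in set(degs):
        count = len(annotation.pathways.get(gene, set()) & key)
        if count >= min_pathways:
            hits.append((gene, count))
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits


def go_recurrence_strategy(
    degs: Iterable[str],
    annotation: AnnotationMap,
    categories: Sequence[str] = GO_CATEGORIES,
    min_occurrences: int = DEFAULT_MIN_GO_OCCURRENCES,
) -> list[tuple[str, int]]:
    """DEGs with >= min_occurrences (GO term, category) hits within the named
    categories ("more than two times" reads as >= 3)."""
    unknown = set(categories) - set(GO_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown GO categories: {sorted(unknown)}")
    cats = set(categories)
    hits = []
    for gene in set(degs):
        count = sum(1 for _, cat in annotation.go_terms.get(gene, set()) if cat in cats)
        if count >= min_occurrences:
            hits.append((gene, count))
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits


def cross_tissue_strategy(deg_sets: Sequence[set[str]]) -> set[str]:
    """Genes differentially expressed in every provided tissue set."""
    if len(deg_sets) < 2:
        raise ValueError("need DEG sets from at least two tissues")
    shared = set(deg_sets[0])
    for s in deg_sets[1:]:
        shared &= set(s)
    return shared


def select_key_genes(
    pathway_hits: Sequence[tuple[str, int]],
    go_hits: Sequence[tuple[str, int]],
    cross_tissue: set[str],
    mode: str = "union",
) -> KeyGeneReport:
    """Combine the three strategies with per-gene provenance.

    ``union`` (default) reports every gene any strategy selected;
    ``intersection`` keeps only genes selected by all three. Ordering is
    stable: by number of supporting strategies, then gene id.
    """
    strategies: dict[str, set[str]] = {}
    evidence: dict[str, dict] = {}
    for gene, count in pathway_hits:
        strategies.setdefault(gene, set()).add("pathway_frequency")
        evidence.setdefault(gene, {})["pathway_count"] = count
    for gene, count in go_hits:
        strategies.setdefault(gene, set()).add("go_recurrence")
        evidence.setdefault(gene, {})["go_hits"] = count
    for gene in cross_tissue:
        strategies.setdefault(gene, set()).add("cross_tissue")
        evidence.setdefault(gene, {})["cross_tissue"] = True
    if mode == "intersection":
        strategies = {g: s for g, s in strategies.items() if len(s) == 3}
        evidence = {g: evidence[g] for g in strategies}
    elif mode != "union":
        raise ValueError(f"unknown mode {mode!r}")
    genes = sorted(strategies, key=lambda g: (-len(strategies[g]), g))
    return KeyGeneReport(genes=genes, strategies=strategies, evidence=evidence)


# ---------------------------------------------------------------------------
# phenotype ratios and qPCR arithmetic
# ---------------------------------------------------------------------------


def phenotype_ratios(
    table: pd.DataFrame,
    group_col: str = "group",
    hl_col: str = "HL",
    bl_col: str = "BL",
) -> dict:
    """Head-length / body-length ratio per group plus Welch trait tests.

    ``table`` holds either per-fish rows or one row of means per group; the
    ratio is computed from group means and rounded to 4 decimals. With > 1
    row per group, Welch (unequal-variance) two-sample t-tests are run per
    numeric trait between the first two groups, flagged at p < 0.05.
    """
    numeric = [c for c in table.columns if c != group_col]
    if (table[numeric] <= 0).any().any():
        raise ValueError("all phenotype measurements must be positive")
    means = table.groupby(group_col)[numeric].mean()
    if (means[bl_col] == 0).any():
        raise ValueError("zero body length")
    ratios = {
        grp: round(float(means.loc[grp, hl_col] / means.loc[grp, bl_col]), 4)
        for grp in means.index
    }
    out = {"hl_bl_ratio": ratios, "group_means": means}
    groups = list(means.index)
    counts = table.groupby(group_col).size()
    if len(groups) >= 2 and (counts > 1).all():
        a, b = groups[0], groups[1]
        tests = {}
        for trait in numeric:
            xa = table.loc[table[group_col] == a, trait]
            xb = table.loc[table[group_col] == b, trait]
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            tests[trait] = {"t": float(t), "p": float(p), "significant": bool(p < 0.05)}
        out["welch_tests"] = tests
    return out


def ddct_fold_change(
    ct: pd.DataFrame,
    reference_gene: str,
    calibrator_group: str,
    group_col: str = "group",
) -> dict[str, float]:
    """Relative expression by the 2^-ddCt method.

    Per sample, dCt = Ct_target - Ct_reference; per group, ddCt is the mean
    dCt minus the calibrator group's mean dCt; fold change = 2^-ddCt. Returns
    {gene: fold in the non-calibrator group} (one fold per target gene when
    there are exactly two groups; otherwise '{gene}@{group}' keys).
    """
    if reference_gene not in ct.columns:
        raise ValueError(f"reference gene {reference_gene!r} missing from Ct table")
    if ct[reference_gene].isna().any():
        raise ValueError("reference gene Ct missing for some samples")
    targets = [c for c in ct.columns if c not in (reference_gene, group_col)]
    groups = list(dict.fromkeys(ct[group_col]))
    if calibrator_group not in groups:
        raise ValueError(f"calibrator group {calibrator_group!r} absent")
    folds: dict[str, float] = {}
    for gene in targets:
        dct = ct[gene] - ct[reference_gene]
        mean_dct = dct.groupby(ct[group_col]).mean()
        for grp in groups:
            if grp == calibrator_group:
                continue
            ddct = mean_dct[grp] - mean_dct[calibrator_group]
            key = gene if len(groups) == 2 else f"{gene}@{grp}"
            folds[key] = float(2.0 ** (-ddct))
    return folds
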