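"""Standard-format I/O, pipeline configuration, and the end-to-end runner.

All tables are tab-separated with a ``#``-prefixed header line. FASTA/FASTQ
go through Biopython with transparent gzip. The pipeline expands one global
seed into named per-stage substreams, so each stage is reproducible on its
own, and writes a run manifest (config hash, seed, per-stage record counts)
atomically at the end.
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import dge, isocluster, longread, orfscan, splicescan, ssrmine, syndata, triage

logger = logging.getLogger("isogrow")


@dataclass
class FastaRecord:
    id: str
    comment: str
    seq: str


@dataclass
class FastqRecord:
    id: str
    comment: str
    seq: str
    qual: str  # Phred+33


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[FastaRecord]:
    """Parse FASTA (wrapped or single-line, optionally gzipped)."""
    records = []
    with _open(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fasta"):
                comment = rec.description[len(rec.id) :].strip()
                records.append(FastaRecord(rec.id, comment, str(rec.seq)))
        except ValueError as exc:
            raise ValueError(f"malformed FASTA in {path}: {exc}") from exc
    return records


def write_fasta(path, records: Iterable[FastaRecord], wrap: int = 60) -> None:
    with _open(path, "wt") as fh:
        for rec in records:
            header = f">{rec.id} {rec.comment}".rstrip()
            fh.write(header + "\n")
            seq = rec.seq
            if wrap:
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i : i + wrap] + "\n")
            else:
                fh.write(seq + "\n")


def read_fastq(path) -> list[FastqRecord]:
    """Parse FASTQ; a truncated trailing record raises with the record named."""
    records = []
    with _open(path) as fh:
        last_id = "<none>"
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                last_id = rec.id
                comment = rec.description[len(rec.id) :].strip()
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
                records.append(FastqRecord(rec.id, comment, str(rec.seq), qual))
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ in {path} after record {last_id!r}: {exc}"
            ) from exc
    return records


def write_fastq(path, records: Iterable[FastqRecord]) -> None:
    with _open(path, "wt") as fh:
        for rec in records:
            header = f"@{rec.id} {rec.comment}".rstrip()
            fh.write(f"{header}\n{rec.seq}\n+\n{rec.qual}\n")


def write_table(path, df: pd.DataFrame, index_label: str) -> None:
    """TSV with a commented header line (frozen column order)."""
    with _open(path, "wt") as fh:
        fh.write("#" + "\t".join([index_label] + list(df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False)


def read_table(path, index_col: str | int = 0) -> pd.DataFrame:
    with _open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected a '#'-prefixed header line")
        names = header[1:].rstrip("\n").split("\t")
        df = pd.read_csv(fh, sep="\t", header=None, names=names, index_col=index_col)
    return df


def write_annotation(path, annotation: triage.AnnotationMap) -> None:
    rows = []
    for gene in sorted(annotation.universe):
        for pw in sorted(annotation.pathways.get(gene, ())):
            rows.append((gene, "pathway", pw, ""))
        for term, cat in sorted(annotation.go_terms.get(gene, ())):
            rows.append((gene, "GO", term, cat))
        if gene not in annotation.pathways and gene not in annotation.go_terms:
            rows.append((gene, "none", "", ""))
    df = pd.DataFrame(rows, columns=["gene", "type", "term", "category"])
    with _open(path, "wt") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_annotation(path) -> triage.AnnotationMap:
    with _open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected a '#'-prefixed header line")
        names = header[1:].rstrip("\n").split("\t")
        df = pd.read_csv(fh, sep="\t", header=None, names=names, keep_default_na=False)
    pathways: dict[str, set[str]] = {}
    go_terms: dict[str, set[tuple[str, str]]] = {}
    universe = set(df["gene"])
    for _, row in df.iterrows():
        if row["type"] == "pathway":
            pathways.setdefault(row["gene"], set()).add(row["term"])
        elif row["type"] == "GO":
            go_terms.setdefault(row["gene"], set()).add((row["term"], row["category"]))
    return triage.AnnotationMap(pathways=pathways, go_terms=go_terms, universe=universe)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ClassifyParams:
    min_passes: int = 3
    min_quality: float = 0.9
    max_mismatch: int = longread.DEFAULT_MAX_MISMATCH


@dataclass
class ClusterParams:
    # raw FLNC reads carry residual error on both sides of a comparison, so
    # read clustering runs below the 0.99 dedup cutoff applied to consensi
    identity: float = 0.95
    dedup_identity: float = isocluster.DEFAULT_IDENTITY
    kmer: int = isocluster.DEFAULT_KMER
    family_similarity: float = isocluster.DEFAULT_FAMILY_SIMILARITY


@dataclass
class ASParams:
    min_score: float = splicescan.DEFAULT_MIN_SCORE
    min_transcript_len: int = splicescan.MIN_TRANSCRIPT_LEN
    min_gap: int = splicescan.MIN_GAP
    min_end_distance: int = splicescan.MIN_END_DISTANCE
    max_overlap: int = splicescan.MAX_OVERLAP
    prefilter: bool = True


@dataclass
class ORFParams:
    min_aa: int = orfscan.DEFAULT_MIN_AA
    orf_coverage: float = orfscan.DEFAULT_ORF_COVERAGE
    fickett_threshold: float = orfscan.DEFAULT_FICKETT_THRESHOLD


@dataclass
class SSRParams:
    min_transcript_length: int = ssrmine.MIN_TRANSCRIPT_LENGTH
    max_interruption: int = ssrmine.DEFAULT_MAX_INTERRUPTION


@dataclass
class DGEParams:
    max_fdr: float = dge.MAX_FDR
    min_abs_log2fc: float = dge.MIN_ABS_LOG2FC
    min_total_count: int = dge.MIN_TOTAL_COUNT


@dataclass
class TriageParams:
    min_pathways: int = triage.DEFAULT_MIN_PATHWAYS
    min_go_hits: int = triage.DEFAULT_MIN_GO_OCCURRENCES
    mode: str = "union"


@dataclass
class PipelineConfig:
    """Every stage threshold has exactly one home here."""

    outdir: str = "isogrow_out"
    seed: int = 0
    log_level: str = "INFO"
    simulate: syndata.SimConfig = field(default_factory=syndata.SimConfig)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    as_scan: ASParams = field(default_factory=ASParams)
    orf: ORFParams = field(default_factory=ORFParams)
    ssr: SSRParams = field(default_factory=SSRParams)
    dge: DGEParams = field(default_factory=DGEParams)
    triage: TriageParams = field(default_factory=TriageParams)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build(cls, data, path="")

    def to_yaml(self, path) -> None:
        with _open(path, "wt") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with _open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        where = path or "config"
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        target = {
            "simulate": syndata.SimConfig,
            "classify": ClassifyParams,
            "cluster": ClusterParams,
            "as_scan": ASParams,
            "orf": ORFParams,
            "ssr": SSRParams,
            "dge": DGEParams,
            "triage": TriageParams,
        }.get(name)
        if target is not None and isinstance(value, dict):
            kwargs[name] = _build(target, value, path=f"{path}.{name}".lstrip("."))
        else:
            kwargs[name] = value
    return cls(**kwargs)


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stage_counts: dict
    started: float
    finished: float

    def write(self, path) -> None:
        """Atomic write: the manifest appears only when complete."""
        tmp = str(path) + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, path)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in dependency order and write every artefact.

    Stage order: simulate -> filter/classify -> cluster/consensus/dedup/
    families -> AS scan, ORF/lncRNA, SSR -> FPKM/DGE -> triage. Identical
    config + seed give identical output files (the manifest carries wall
    times and is excluded from that guarantee).
    """
    from . import __version__

    started = time.time()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    sim = dataclasses.replace(config.simulate, seed=config.seed)
    transcripts, truth = syndata.simulate_transcriptome(sim)
    reads = syndata.simulate_long_reads(transcripts, sim)
    matrix, de_truth = syndata.simulate_count_matrix(transcripts, sim)
    annotation = syndata.simulate_annotation(transcripts, sim)
    counts["simulate"] = {
        "transcripts": len(transcripts.seqs),
        "reads": len(reads),
        "genes": len(matrix.counts),
    }

    write_fasta(
        outdir / "transcripts.fasta",
        [FastaRecord(t, f"gene={transcripts.gene_of[t]}", s) for t, s in sorted(transcripts.seqs.items())],
    )
    write_fastq(
        outdir / "reads.fastq",
        [
            FastqRecord(
                r.ccs.id,
                f"passes={r.ccs.passes} quality={r.ccs.quality:.4f} truth={r.truth_class}",
                r.ccs.seq,
                "I" * len(r.ccs.seq),
            )
            for r in reads
        ],
    )
    write_table(outdir / "counts.tsv", matrix.counts.assign(length=matrix.lengths), "gene")
    write_annotation(outdir / "annotation.tsv", annotation)

    # --- classify -----------------------------------------------------------
    filt = longread.ccs_filter(
        [r.ccs for r in reads], config.classify.min_passes, config.classify.min_quality
    )
    flnc = longread.classify_reads(
        filt.retained,
        sim.primer5,
        sim.primer3,
        max_mismatch=config.classify.max_mismatch,
    )
    by_class = {c: sum(1 for r in flnc if r.read_class == c) for c in ("FL", "nFL", "chimeric")}
    counts["classify"] = {
        "input": len(reads),
        "passed_filter": filt.n_retained,
        "rejected_filter": filt.n_rejected,
        **by_class,
    }
    write_fasta(
        outdir / "flnc.fasta",
        [
            FastaRecord(r.id, f"class={r.read_class} source={r.source_read}", r.seq)
            for r in flnc
            if r.read_class == "FL"
        ],
    )
    class_df = pd.DataFrame(
        [
            {
                "class": r.read_class,
                "primer5": _fmt_iv(r.primer5_hit),
                "primer3": _fmt_iv(r.primer3_hit),
                "polya": _fmt_iv(r.polya_hit),
            }
            for r in flnc
        ],
        index=[r.source_read for r in flnc],
    )
    write_table(outdir / "classification.tsv", class_df, "read")

    # --- cluster / consensus / dedup / families -----------------------------
    fl_seqs = {r.id: r.seq for r in flnc if r.read_class == "FL" and r.seq}
    clusters = isocluster.greedy_cluster(fl_seqs, config.cluster.identity)
    isocluster.polish_clusters(clusters, fl_seqs)
    consensi = {cl.id: cl.consensus for cl in clusters}
    retained, membership = isocluster.dedup_transcripts(
        consensi, config.cluster.dedup_identity
    )
    nr = {cid: consensi[cid] for cid in retained}
    families = isocluster.family_partition(
        nr, k=config.cluster.kmer, similarity_threshold=config.cluster.family_similarity
    )
    counts["cluster"] = {
        "flnc_in": len(fl_seqs),
        "clusters": len(clusters),
        "non_redundant": len(retained),
        "families": len(families),
    }
    write_fasta(
        outdir / "transcripts.nr.fasta",
        [FastaRecord(cid, "", nr[cid]) for cid in sorted(nr)],
    )
    member_rows = []
    for cl in clusters:
        for m in cl.members:
            member_rows.append(
                {"cluster": cl.id, "representative": cl.representative, "retained_as": membership[cl.id]}
            )
    write_table(
        outdir / "clusters.tsv",
        pd.DataFrame(member_rows, index=[m for cl in clusters for m in cl.members]),
        "member",
    )

    # --- AS / ORF / lncRNA / SSR -------------------------------------------
    asp = config.as_scan
    events = splicescan.scan_all_pairs(
        nr,
        min_score=asp.min_score,
        prefilter=asp.prefilter,
        min_transcript_len=asp.min_transcript_len,
        min_gap=asp.min_gap,
        min_end_distance=asp.min_end_distance,
        max_overlap=asp.max_overlap,
    )
    counts["as_scan"] = {"pairs": len(events)}
    write_table(outdir / "as_events.tsv", _events_frame(events), "pair")

    orf_rows = []
    for tid in sorted(nr):
        for orf in orfscan.find_orfs(nr[tid], min_aa=config.orf.min_aa, transcript_id=tid):
            orf_rows.append(dataclasses.asdict(orf))
    orf_df = pd.DataFrame(orf_rows)
    counts["orf"] = {
        "orfs": len(orf_df),
        "complete": int((orf_df["completeness"] == "complete").sum()) if len(orf_df) else 0,
    }
    if len(orf_df):
        orf_df = orf_df.set_index("transcript_id")
        write_table(outdir / "orfs.tsv", orf_df, "transcript_id")

    lnc = orfscan.lncrna_set(
        nr,
        min_aa=config.orf.min_aa,
        orf_coverage=config.orf.orf_coverage,
        fickett_threshold=config.orf.fickett_threshold,
    )
    counts["lncrna"] = {"candidates": len(lnc)}
    (outdir / "lncrna.ids.txt").write_text("".join(f"{t}\n" for t in sorted(lnc)))

    loci, n_scanned = ssrmine.mine_transcripts(
        nr,
        min_transcript_length=config.ssr.min_transcript_length,
        max_interruption=config.ssr.max_interruption,
    )
    summary = ssrmine.ssr_summary(loci, n_scanned)
    counts["ssr"] = {"loci": summary.total, "compound": summary.n_compound}
    loci_df = pd.DataFrame([dataclasses.asdict(l) for l in loci])
    if len(loci_df):
        loci_df = loci_df.set_index("transcript_id")
        write_table(outdir / "ssr_loci.tsv", loci_df, "transcript_id")

    # --- expression ---------------------------------------------------------
    fpkm_df = dge.fpkm(matrix)
    write_table(outdir / "fpkm.tsv", fpkm_df, "gene")
    deg_sets = {}
    all_results = []
    for tissue in dge.TISSUES:
        results = dge.de_results(
            matrix,
            tissue,
            max_fdr=config.dge.max_fdr,
            min_abs_log2fc=config.dge.min_abs_log2fc,
            min_total_count=config.dge.min_total_count,
        )
        all_results.extend(results)
        screened = dge.screen_degs(results, config.dge.max_fdr, config.dge.min_abs_log2fc)
        deg_sets[tissue] = screened.get(tissue, {"up": set(), "down": set()})
    de_df = pd.DataFrame([dataclasses.asdict(r) for r in all_results])
    if len(de_df):
        write_table(outdir / "dge.tsv", de_df.set_index("gene"), "gene")
    counts["dge"] = {
        t: {"up": len(deg_sets[t]["up"]), "down": len(deg_sets[t]["down"])}
        for t in dge.TISSUES
    }

    # --- triage -------------------------------------------------------------
    shared, discordant = dge.shared_degs(deg_sets["F"], deg_sets["V"])
    degs_union = sorted(
        set().union(*(deg_sets[t]["up"] | deg_sets[t]["down"] for t in dge.TISSUES))
    )
    pw_hits = triage.pathway_frequency_strategy(
        degs_union, annotation, min_pathways=config.triage.min_pathways
    )
    go_hits = triage.go_recurrence_strategy(
        degs_union, annotation, min_occurrences=config.triage.min_go_hits
    )
    report = triage.select_key_genes(pw_hits, go_hits, shared, mode=config.triage.mode)
    counts["triage"] = {"key_genes": len(report.genes), "shared_degs": len(shared)}
    key_df = pd.DataFrame(
        {
            "strategies": [",".join(sorted(report.strategies[g])) for g in report.genes],
            "evidence": [json.dumps(report.evidence[g], sort_keys=True) for g in report.genes],
        },
        index=report.genes,
    )
    write_table(outdir / "key_genes.tsv", key_df, "gene")

    manifest = RunManifest(
        version=__version__,
        config_hash=config.config_hash(),
        seed=config.seed,
        stage_counts=counts,
        started=started,
        finished=time.time(),
    )
    manifest.write(outdir / "manifest.json")
    return manifest


def _fmt_iv(iv) -> str:
    return f"{iv[0]}-{iv[1]}" if iv else "."


def _events_frame(events) -> pd.DataFrame:
    rows = []
    for ev in events:
        h1, h2 = ev.hsp_pair
        rows.append(
            {
                "transcript_a": ev.transcript_a,
                "transcript_b": ev.transcript_b,
                "gap_length": ev.gap_length,
                "gap_start": ev.gap_interval[0],
                "gap_end": ev.gap_interval[1],
                "gap_on": ev.gap_on,
                "dist5": ev.distance_to_5prime,
                "dist3": ev.distance_to_3prime,
                "overlap": ev.overlap,
                "hsp1": f"{h1.query_start}-{h1.query_end}/{h1.subject_start}-{h1.subject_end}",
                "hsp2": f"{h2.query_start}-{h2.query_end}/{h2.subject_start}-{h2.subject_end}",
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df.index = [f"{r['transcript_a']}|{r['transcript_b']}" for r in rows]
    return df
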