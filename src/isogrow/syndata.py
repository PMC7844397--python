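"""Synthetic transcriptomes, long reads, counts and annotations with truth.

The generator emulates the study design the pipeline targets: a two-group
(fast-growing BG vs slow-growing SG), two-tissue (frontal/parietal bone F,
vertebra V) comparison with three replicates, on top of a reference-free
full-length transcriptome. Gene families are concatenations of exon-like
blocks; a configurable fraction of coding families carries a skipped
internal block (> 100 bp, >= 100 bp from both transcript ends) so the AS
caller's criteria are satisfiable by construction. SSR loci and non-coding
transcripts are planted with exact truth coordinates; long reads carry
primers, polyA tails, per-base errors, chimeras and pass/quality labels;
counts are negative binomial with planted fold changes.

Every sampler is driven by a named substream of the config seed, so
identical configs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._util import revcomp, substream_rng
from .longread import CCSRead
from .orfscan import START_CODON, STOP_CODONS
from .ssrmine import DEFAULT_THRESHOLDS, SSRLocus, canonical_rotation, is_primitive
from .triage import GO_CATEGORIES, KEY_PATHWAYS

BASES = "ACGT"

#: codons drawn for planted coding sequences: a deliberately non-degenerate
#: usage (G/C-rich third positions) so composition statistics see real bias
_BIASED_CODONS = [
    "GCC", "GAG", "CTG", "AAG", "GAC", "TTC", "ATC", "GTG",
    "ACC", "TCC", "CAG", "AAC", "GGC", "TAC", "CGC", "CAC",
]


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_genes: int = 200
    # exon-block geometry
    n_blocks_min: int = 5
    n_blocks_max: int = 8
    block_len_min: int = 150
    block_len_max: int = 400
    # alternative splicing
    as_pair_fraction: float = 0.3
    as_block_min: int = 120
    as_block_max: int = 300
    # planted features
    ssr_plant_rate: float = 0.2  # loci per kb
    noncoding_fraction: float = 0.3
    # read synthesis
    primer5: str = "AAGCAGTGGTATCAACGCAGAGTAC"
    primer3: str = "TCTAGACGTGTAGCCATCGGAACTT"
    polya_len: int = 30
    read_error_rate: float = 0.01
    chimera_rate: float = 0.02
    nfl_dropout_rate: float = 0.15
    ccs_fail_rate: float = 0.10
    reads_per_transcript: int = 3
    # counts
    de_fraction: float = 0.1
    log2fc_effect: float = 2.0
    nb_dispersion: float = 0.1
    baseline_log_mean: float = 4.5
    baseline_log_sd: float = 1.0
    library_size_sigma: float = 0.1
    n_replicates: int = 3
    # annotation
    n_extra_pathways: int = 10
    n_go_terms: int = 30
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "as_pair_fraction",
            "noncoding_fraction",
            "read_error_rate",
            "chimera_rate",
            "nfl_dropout_rate",
            "ccs_fail_rate",
            "de_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per group for DE testing")
        if self.block_len_min <= 0 or self.block_len_max < self.block_len_min:
            raise ValueError("block length bounds must be positive and ordered")
        if self.n_blocks_max < self.n_blocks_min or self.n_blocks_min < 1:
            raise ValueError("block count bounds must be positive and ordered")
        if self.ssr_plant_rate < 0:
            raise ValueError("ssr_plant_rate must be non-negative")
        if self.as_pair_fraction > 0:
            if self.n_blocks_min < 3:
                raise ValueError(
                    "AS placement needs >= 3 blocks (the skipped block is internal)"
                )
            if self.as_block_min <= 100:
                raise ValueError("skipped blocks must exceed 100 bp")
            if self.block_len_min < 100:
                raise ValueError(
                    "flanking blocks must reach 100 bp for the end-distance criterion"
                )
        if len(self.primer5) < 8 or len(self.primer3) < 8:
            raise ValueError("primers must be at least 8 bp")


@dataclass
class TranscriptSet:
    seqs: dict[str, str]
    gene_of: dict[str, str]

    def __len__(self) -> int:
        return len(self.seqs)


@dataclass
class TruthTables:
    as_pairs: set[tuple[str, str]] = field(default_factory=set)
    ssr_loci: list[SSRLocus] = field(default_factory=list)
    noncoding_ids: set[str] = field(default_factory=set)
    de_genes: dict[str, float] = field(default_factory=dict)
    family_of: dict[str, str] = field(default_factory=dict)


@dataclass
class SimulatedRead:
    ccs: CCSRead
    truth_class: str  # FL | nFL | chimeric
    truth_transcript: str
    passes_filter: bool


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_BIASED_CODONS), n)
    return "".join(_BIASED_CODONS[i] for i in idx)


def _plant_cds(seq: str, rng: np.random.Generator, start: int, n_codons: int) -> str:
    cds = START_CODON + _random_codons(rng, n_codons) + "TAA"
    return seq[: start] + cds + seq[start + len(cds) :]


def _stop_free_stretches(seq: str) -> list[tuple[str, int, int]]:
    """(strand, start, end) of maximal stop-free codon stretches, 6 frames.

    Coordinates are on the forward strand; used only to bound ORF lengths in
    planted non-coding transcripts.
    """
    out = []
    n = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            seg_start = frame
            pos = frame
            while pos + 3 <= n:
                if s[pos : pos + 3] in STOP_CODONS:
                    out.append((strand, seg_start, pos))
                    seg_start = pos + 3
                pos += 3
            out.append((strand, seg_start, pos))
    return out


def _break_orfs(
    seq: str,
    rng: np.random.Generator,
    max_aa: int = 45,
    protected: Optional[list[tuple[int, int]]] = None,
) -> str:
    """Inject stop codons until no stop-free stretch reaches max_aa codons.

    ``protected`` intervals (forward coordinates, e.g. planted SSR runs) are
    never edited.
    """
    protected = protected or []
    s = seq
    n = len(s)

    def is_protected(fwd_start: int, fwd_end: int) -> bool:
        return any(fwd_start < pe and ps < fwd_end for ps, pe in protected)

    for _ in range(200):
        offenders = [
            (strand, a, b)
            for strand, a, b in _stop_free_stretches(s)
            if (b - a) // 3 >= max_aa
        ]
        if not offenders:
            return s
        strand, a, b = offenders[0]
        codon_starts = list(range(a, b - 2, 3))
        mid = len(codon_starts) // 2
        # prefer codons near the stretch middle, skipping protected spans
        order = sorted(codon_starts, key=lambda c: abs(codon_starts.index(c) - mid))
        for c in order:
            if strand == "+":
                fs, fe = c, c + 3
                stop = "TAA"
            else:
                fs, fe = n - c - 3, n - c
                stop = revcomp("TAA")
            if not is_protected(fs, fe):
                s = s[:fs] + stop + s[fe:]
                break
        else:
            return s  # whole stretch protected: leave as is
    return s


def _plant_ssrs(
    seq: str,
    rng: np.random.Generator,
    rate_per_kb: float,
    forbidden: list[tuple[int, int]],
    tid: str,
) -> tuple[str, list[SSRLocus]]:
    """Overwrite spaced repeat runs into ``seq`` and return exact truth loci.

    Runs never touch ``forbidden`` intervals or the 10 bp transcript ends,
    sit > 120 bp apart (so each stays a separate perfect locus under the
    default compound-merge window) and get flanking bases that break any
    periodic extension, making every planted run maximal.
    """
    n = len(seq)
    k = rng.poisson(rate_per_kb * n / 1000.0)
    if k == 0:
        return seq, []
    motif_lens = rng.choice([1, 2, 3, 4, 5, 6], size=k, p=[0.4, 0.3, 0.15, 0.08, 0.05, 0.02])
    s = list(seq)
    placed: list[SSRLocus] = []
    occupied = list(forbidden)
    for m in motif_lens:
        m = int(m)
        while True:
            motif = _random_seq(rng, m)
            if is_primitive(motif):
                break
        repeats = int(DEFAULT_THRESHOLDS[m] + rng.integers(0, 4))
        span = m * repeats
        for _ in range(30):  # rejection-sample a free slot
            start = int(rng.integers(10, max(11, n - span - 10)))
            end = start + span
            if all(start - 121 >= pe or ps >= end + 121 for ps, pe in occupied):
                break
        else:
            continue
        run = motif * repeats
        s[start:end] = run
        # break periodic extension on both flanks
        left_bad = motif[m - 1]
        s[start - 1] = next(b for b in BASES if b != left_bad)
        right_bad = motif[0]
        s[end] = next(b for b in BASES if b != right_bad)
        occupied.append((start, end))
        placed.append(
            SSRLocus(
                transcript_id=tid,
                motif=motif,
                canonical_motif=canonical_rotation(motif),
                repeats=repeats,
                start=start,
                end=end,
                kind="perfect",
            )
        )
    placed.sort(key=lambda l: l.start)
    return "".join(s), placed


def simulate_transcriptome(config: SimConfig) -> tuple[TranscriptSet, TruthTables]:
    """Generate gene families with planted AS pairs, SSRs and non-coding
    transcripts, plus the matching truth tables."""
    config.validate()
    rng = substream_rng(config.seed, "transcriptome")
    seqs: dict[str, str] = {}
    gene_of: dict[str, str] = {}
    truth = TruthTables()

    for g in range(config.n_genes):
        gene = f"G{g:04d}"
        noncoding = rng.random() < config.noncoding_fraction
        as_gene = (not noncoding) and rng.random() < config.as_pair_fraction

        n_blocks = int(rng.integers(config.n_blocks_min, config.n_blocks_max + 1))
        lens = rng.integers(config.block_len_min, config.block_len_max + 1, n_blocks)
        lens = [int(x) for x in lens]

        skip_idx = None
        if as_gene:
            skip_idx = int(rng.integers(1, n_blocks - 1))
            # in-frame skip keeps a downstream planted CDS intact by length
            skip_len = int(rng.integers(config.as_block_min, config.as_block_max + 1))
            lens[skip_idx] = skip_len - skip_len % 3
            # the retained isoform must clear 1,000 bp; the suffix after the
            # skipped block must hold a CDS of at least ~120 codons
            others = sum(lens) - lens[skip_idx]
            if others < 1100:
                lens[0] += 1100 - others
            suffix = sum(lens[skip_idx + 1 :])
            if suffix < 450:
                lens[-1] += 450 - suffix

        seq = "".join(_random_seq(rng, L) for L in lens)
        bounds = np.cumsum([0] + lens)
        skip_span = (
            (int(bounds[skip_idx]), int(bounds[skip_idx + 1]))
            if skip_idx is not None
            else None
        )

        cds_span = None
        if not noncoding:
            if skip_span is not None:
                start = skip_span[1] + 9
                n_codons = min(400, (len(seq) - start - 30) // 3)
            else:
                start = 30
                n_codons = min((len(seq) - 90) // 3, max(150, len(seq) // 6))
            seq = _plant_cds(seq, rng, start, n_codons)
            cds_span = (start, start + 3 * n_codons + 6)

        forbidden = [cds_span] if cds_span else []
        if skip_span is not None:
            # keep runs clear of the splice junction so truth coordinates
            # translate cleanly into the skipped isoform
            forbidden.append((skip_span[0] - 10, skip_span[1] + 10))
        seq, loci = _plant_ssrs(seq, rng, config.ssr_plant_rate, forbidden, f"{gene}_I1")

        # a transcript ending in A would be indistinguishable from its polyA
        # tail in reads; end on a non-A base so FLNC trimming is exact
        if seq.endswith("A"):
            seq = seq[:-1] + "G"

        if noncoding:
            seq = _break_orfs(seq, rng, protected=[(l.start - 1, l.end + 1) for l in loci])

        t1 = f"{gene}_I1"
        seqs[t1] = seq
        gene_of[t1] = gene
        truth.family_of[t1] = gene
        truth.ssr_loci.extend(loci)
        if noncoding:
            truth.noncoding_ids.add(t1)

        if skip_span is not None:
            t2 = f"{gene}_I2"
            a, b = skip_span
            seqs[t2] = seq[:a] + seq[b:]
            gene_of[t2] = gene
            truth.family_of[t2] = gene
            truth.as_pairs.add((t1, t2))
            shift = b - a
            for loc in loci:
                if loc.end <= a:
                    truth.ssr_loci.append(replace(loc, transcript_id=t2))
                elif loc.start >= b:
                    truth.ssr_loci.append(
                        replace(loc, transcript_id=t2, start=loc.start - shift, end=loc.end - shift)
                    )

    return TranscriptSet(seqs, gene_of), truth


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    """Per-base residual error: 60% substitution, 20% insertion, 20% deletion."""
    if error_rate <= 0:
        return seq
    out = []
    errs = rng.random(len(seq)) < error_rate
    kinds = rng.random(len(seq))
    for i, base in enumerate(seq):
        if not errs[i]:
            out.append(base)
        elif kinds[i] < 0.6:  # substitution
            out.append(BASES[(BASES.index(base) + int(rng.integers(1, 4))) % 4]
                       if base in BASES else base)
        elif kinds[i] < 0.8:  # insertion before the base
            out.append(BASES[int(rng.integers(0, 4))])
            out.append(base)
        # else deletion: emit nothing
    return "".join(out)


def _cassette(config: SimConfig, transcript: str) -> str:
    return config.primer5 + transcript + "A" * config.polya_len + config.primer3


def simulate_long_reads(
    transcripts: TranscriptSet, config: SimConfig
) -> list[SimulatedRead]:
    """CCS-like reads with truth labels.

    Each read is a primer/polyA-flanked cassette (random strand), possibly a
    two-transcript chimera or a cassette missing one evidence piece (nFL
    truth), with per-base errors and pass/quality values of which a
    ``ccs_fail_rate`` fraction fails the `passes >= 3 and quality > 0.9`
    filter.
    """
    if not transcripts.seqs:
        raise ValueError("transcript set is empty")
    config.validate()
    rng = substream_rng(config.seed, "reads")
    tids = sorted(transcripts.seqs)
    reads: list[SimulatedRead] = []
    idx = 0
    for tid in tids:
        for _ in range(config.reads_per_transcript):
            u = rng.random()
            if u < config.chimera_rate:
                partner = tids[int(rng.integers(0, len(tids)))]
                raw = _cassette(config, transcripts.seqs[tid]) + _cassette(
                    config, transcripts.seqs[partner]
                )
                label = "chimeric"
            elif u < config.chimera_rate + config.nfl_dropout_rate:
                mode = ("no_polya", "no_primer5", "no_primer3")[int(rng.integers(0, 3))]
                t = transcripts.seqs[tid]
                if mode == "no_polya":
                    raw = config.primer5 + t + config.primer3
                elif mode == "no_primer5":
                    raw = t + "A" * config.polya_len + config.primer3
                else:
                    raw = config.primer5 + t + "A" * config.polya_len
                label = "nFL"
            else:
                raw = _cassette(config, transcripts.seqs[tid])
                label = "FL"
            if rng.random() < 0.5:
                raw = revcomp(raw)
            raw = _mutate(raw, rng, config.read_error_rate)
            fails = rng.random() < config.ccs_fail_rate
            if fails:
                if rng.random() < 0.5:
                    passes = int(rng.integers(1, 3))
                    quality = float(rng.uniform(0.901, 0.999))
                else:
                    passes = int(rng.integers(3, 16))
                    quality = float(rng.uniform(0.5, 0.9))
            else:
                passes = int(rng.integers(3, 16))
                quality = float(rng.uniform(0.901, 0.999))
            reads.append(
                SimulatedRead(
                    ccs=CCSRead(id=f"read{idx:06d}", seq=raw, passes=passes, quality=quality),
                    truth_class=label,
                    truth_transcript=tid,
                    passes_filter=not fails,
                )
            )
            idx += 1
    return reads


def simulate_count_matrix(transcripts: TranscriptSet, config: SimConfig):
    """NB gene x sample counts for the BG/SG x F/V design, plus DE truth.

    DE genes get a BG/SG mean ratio of exactly 2**log2fc_effect (random
    sign), applied in both tissues; per-sample library-size factors are
    log-normal(0, library_size_sigma).
    """
    from .dge import CountMatrix  # local import to avoid a cycle at import time

    config.validate()
    rng = substream_rng(config.seed, "counts")
    genes = sorted(set(transcripts.gene_of.values()))
    lengths = {
        g: max(
            len(transcripts.seqs[t])
            for t, gg in transcripts.gene_of.items()
            if gg == g
        )
        for g in genes
    }
    base_mean = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, len(genes)))

    n_de = int(round(config.de_fraction * len(genes)))
    de_idx = rng.choice(len(genes), size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    de_truth = {genes[i]: float(s * config.log2fc_effect) for i, s in zip(de_idx, signs)}

    samples = [
        f"{grp}_{tis}_{rep + 1}"
        for grp in ("BG", "SG")
        for tis in ("F", "V")
        for rep in range(config.n_replicates)
    ]
    factors = np.exp(rng.normal(0.0, config.library_size_sigma, len(samples)))

    r = 1.0 / config.nb_dispersion
    counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
    lfc = np.zeros(len(genes))
    for i, s in zip(de_idx, signs):
        lfc[i] = s * config.log2fc_effect
    for j, sample in enumerate(samples):
        group = sample.split("_")[0]
        mu = base_mean * (2.0 ** lfc if group == "BG" else 1.0)
        mu = mu * factors[j]
        p = r / (r + mu)
        counts[:, j] = rng.negative_binomial(r, p)

    import pandas as pd

    df = pd.DataFrame(counts, index=genes, columns=samples)
    matrix = CountMatrix(
        counts=df,
        lengths=pd.Series({g: lengths[g] for g in genes}),
        groups=pd.Series({s: s.split("_")[0] for s in samples}),
        tissues=pd.Series({s: s.split("_")[1] for s in samples}),
    )
    return matrix, de_truth


def simulate_annotation(transcripts: TranscriptSet, config: SimConfig):
    """Random gene -> pathway / GO(category) maps over the key-pathway panel
    plus generic pathways and GO terms; deterministic given the seed."""
    from .triage import AnnotationMap

    config.validate()
    rng = substream_rng(config.seed, "annotation")
    genes = sorted(set(transcripts.gene_of.values()))
    pathways = list(KEY_PATHWAYS) + [f"pathway_{i:02d}" for i in range(config.n_extra_pathways)]
    go_terms = [f"GO:{7000000 + i}" for i in range(config.n_go_terms)]
    categories = list(GO_CATEGORIES) + ["other"]

    pmap: dict[str, set[str]] = {}
    gmap: dict[str, set[tuple[str, str]]] = {}
    for g in genes:
        n_pw = int(rng.poisson(1.0))
        if n_pw:
            chosen = rng.choice(len(pathways), size=min(n_pw, len(pathways)), replace=False)
            pmap[g] = {pathways[i] for i in chosen}
        n_go = int(rng.poisson(2.0))
        if n_go:
            chosen = rng.choice(len(go_terms), size=min(n_go, len(go_terms)), replace=False)
            gmap[g] = {
                (go_terms[i], categories[int(rng.integers(0, len(categories)))])
                for i in chosen
            }
    return AnnotationMap(pathways=pmap, go_terms=gmap, universe=set(genes))
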