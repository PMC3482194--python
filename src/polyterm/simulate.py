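"""Synthetic genome, read and expression-table generator.

The generator emulates the statistical structure the downstream analysis
assumes: two genotypes that differ in (i) the probability that
transcription reads through the terminal poly(A) site, (ii) the fraction of
transcripts cleaved at the distal rather than the proximal site, and (iii)
the transcription rate of LINE-1 elements. Reads are unstranded ~500 bp
cDNA fragments; a duplicated genomic segment creates multi-hit alignments;
intronless small genes and multi-exon genes are both represented.

Every read carries a ground-truth record (source, isoform, read-through
flag, true placement) so each downstream statistic can be checked against
a truth-derived oracle.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    ConditionParams,
    GeneModel,
    GenomeBundle,
    ModelError,
    RepeatFeature,
    SimulationTruth,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SizingError(ValueError):
    """A requested feature cannot fit on the requested chromosome."""


@dataclass(frozen=True)
class GenomeConfig:
    """Layout of the toy genome.

    Features are placed left to right with ``gene_gap`` of intergenic space
    between genes (comfortably larger than the 4 kb downstream extension
    window, so windows of adjacent genes do not collide with gene bodies).
    """

    chrom_name: str = "chrS"
    chrom_length: int = 400_000
    seed: int = 0
    # multi-exon genes with alternative polyadenylation
    n_multi_exon_genes: int = 4
    internal_exons: int = 4
    internal_exon_length: int = 1500
    terminal_exon_length: int = 3000
    multi_exon_span: int = 18_000
    autr_length: int = 600
    cutr_length: int = 1200
    # intronless small genes (ISGs) with alternative polyadenylation
    n_single_exon_genes: int = 3
    single_exon_span: int = 5000
    isg_autr_length: int = 300
    isg_cutr_length: int = 400
    # single-PAS genes (RUD background normalization)
    n_non_apa_genes: int = 3
    non_apa_span: int = 6000
    # intergenic repeats
    n_line1_full: int = 2
    n_line1_frag: int = 2
    n_sine: int = 3
    n_ltr: int = 3
    line1_full_length: int = 6500
    line1_frag_length: int = 2500
    sine_length: int = 200
    ltr_length: int = 500
    # repeat copies inserted into introns of multi-exon genes
    n_line1_intronic: int = 1
    n_sine_intronic: int = 1
    n_ltr_intronic: int = 1
    line1_intronic_length: int = 1500
    # duplicated segments (multi-hit alignments); each carries a LINE-1
    # fragment so non-uniquely mapped repeat reads exist, plus repeat-free
    # space so the non-unique category is not all repeat
    n_duplicated_segments: int = 1
    dup_segment_length: int = 6000
    dup_line1_length: int = 2000
    dup_line1_offset: int = 3500
    gene_gap: int = 10_000
    repeat_gap: int = 2000
    consensus_divergence: float = 0.2


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute a ``rate`` fraction of positions with a different base."""
    out = arr.copy()
    n_mut = rng.binomial(arr.size, rate)
    if n_mut == 0:
        return out
    pos = rng.choice(arr.size, size=n_mut, replace=False)
    idx = np.searchsorted(_BASES, out[pos])
    shift = rng.integers(1, 4, size=n_mut)
    out[pos] = _BASES[(idx + shift) % 4]
    return out


def build_toy_genome(config: GenomeConfig) -> GenomeBundle:
    """Build a seeded toy genome with genes, repeats and duplications."""
    rng = np.random.default_rng(config.seed)
    length = config.chrom_length
    if length < 50_000:
        raise SizingError("chromosome must be at least 50 kb")
    genome = _random_bases(rng, length)
    chrom = config.chrom_name

    consensus = {
        "LINE1": _random_bases(rng, config.line1_full_length),
        "SINE": _random_bases(rng, config.sine_length),
        "LTR": _random_bases(rng, config.ltr_length),
    }

    cursor = config.gene_gap
    genes: List[GeneModel] = []
    repeats: List[RepeatFeature] = []
    dups: List[tuple] = []

    def place(span: int, label: str, gap: int) -> int:
        nonlocal cursor
        if cursor + span + gap > length:
            raise SizingError(
                f"cannot place {label} ({span} bp) on {chrom} "
                f"of length {length}"
            )
        start = cursor
        cursor += span + gap
        return start

    strand_cycle = 0

    def next_strand() -> str:
        nonlocal strand_cycle
        strand_cycle += 1
        return "+" if strand_cycle % 2 else "-"

    # --- multi-exon APA genes -------------------------------------------
    span = config.multi_exon_span
    exonic = (config.internal_exons * config.internal_exon_length
              + config.terminal_exon_length)
    if exonic >= span:
        raise SizingError("multi-exon gene exons exceed the gene span")
    intron_each = (span - exonic) // config.internal_exons
    rel_exons = []
    off = 0
    for _ in range(config.internal_exons):
        rel_exons.append((off, off + config.internal_exon_length))
        off += config.internal_exon_length + intron_each
    rel_exons.append((span - config.terminal_exon_length, span))
    for i in range(config.n_multi_exon_genes):
        s = place(span, f"multi-exon gene {i}", config.gene_gap)
        strand = next_strand()
        genes.append(
            _make_gene(
                f"geneM{i:02d}", chrom, strand, s, span, rel_exons,
                autr=config.autr_length, cutr=config.cutr_length,
                cds_off5=200,
            )
        )

    # --- intronless small genes -----------------------------------------
    span = config.single_exon_span
    for i in range(config.n_single_exon_genes):
        s = place(span, f"single-exon gene {i}", config.gene_gap)
        strand = next_strand()
        genes.append(
            _make_gene(
                f"geneS{i:02d}", chrom, strand, s, span, [(0, span)],
                autr=config.isg_autr_length, cutr=config.isg_cutr_length,
                cds_off5=100,
            )
        )

    # --- single-PAS genes ------------------------------------------------
    span = config.non_apa_span
    half = span // 3
    for i in range(config.n_non_apa_genes):
        s = place(span, f"single-PAS gene {i}", config.gene_gap)
        strand = next_strand()
        rel = [(0, half), (span - half, span)]
        genes.append(
            _make_gene(
                f"geneN{i:02d}", chrom, strand, s, span, rel,
                autr=0, cutr=config.cutr_length, cds_off5=100,
            )
        )

    # --- repeats ----------------------------------------------------------
    def insert_repeat(seq_arr: np.ndarray, cls: str, name: str) -> None:
        s = place(seq_arr.size, name, config.repeat_gap)
        strand = next_strand()
        placed = seq_arr if strand == "+" else np.frombuffer(
            revcomp(seq_arr.tobytes().decode()).encode(), dtype=np.uint8
        )
        genome[s : s + seq_arr.size] = placed
        repeats.append(
            RepeatFeature(chrom, s, s + seq_arr.size, strand, cls, name)
        )

    div = config.consensus_divergence

    # repeats inside introns of multi-exon genes (intronic repeat reads)
    multi_genes = [g for g in genes if g.gene_id.startswith("geneM")]
    intron_slots = [
        (g, ivl) for g in multi_genes for ivl in g.introns
    ]
    slot = 0

    def insert_intronic(seq_arr: np.ndarray, cls: str, name: str) -> None:
        nonlocal slot
        while slot < len(intron_slots):
            _gene, (is_, ie) = intron_slots[slot]
            slot += 1
            if ie - is_ >= seq_arr.size + 200:
                pos = is_ + 100
                strand = next_strand()
                placed = seq_arr if strand == "+" else np.frombuffer(
                    revcomp(seq_arr.tobytes().decode()).encode(),
                    dtype=np.uint8,
                )
                genome[pos : pos + seq_arr.size] = placed
                repeats.append(
                    RepeatFeature(chrom, pos, pos + seq_arr.size, strand,
                                  cls, name)
                )
                return
        raise SizingError(f"no intron can hold {name} ({seq_arr.size} bp)")

    for i in range(config.n_line1_intronic):
        frag = consensus["LINE1"][-config.line1_intronic_length:]
        insert_intronic(_mutate(frag, div, rng), "LINE1",
                        f"LINE1_intronic_{i}")
    for i in range(config.n_sine_intronic):
        insert_intronic(_mutate(consensus["SINE"], div, rng), "SINE",
                        f"SINE_intronic_{i}")
    for i in range(config.n_ltr_intronic):
        insert_intronic(_mutate(consensus["LTR"], div, rng), "LTR",
                        f"LTR_intronic_{i}")

    for i in range(config.n_line1_full):
        if config.line1_full_length < 6000:
            raise SizingError("full-length LINE-1 must be >= 6000 bp")
        insert_repeat(_mutate(consensus["LINE1"], div, rng), "LINE1",
                      f"LINE1_full_{i}")
    for i in range(config.n_line1_frag):
        frag = consensus["LINE1"][-config.line1_frag_length:]
        insert_repeat(_mutate(frag, div, rng), "LINE1", f"LINE1_frag_{i}")
    for i in range(config.n_sine):
        insert_repeat(_mutate(consensus["SINE"], div, rng), "SINE",
                      f"SINE_{i}")
    for i in range(config.n_ltr):
        insert_repeat(_mutate(consensus["LTR"], div, rng), "LTR",
                      f"LTR_{i}")

    # --- duplicated segments ---------------------------------------------
    for i in range(config.n_duplicated_segments):
        seg = _random_bases(rng, config.dup_segment_length)
        frag = _mutate(
            consensus["LINE1"][-config.dup_line1_length:], div, rng
        )
        o = config.dup_line1_offset
        seg[o : o + frag.size] = frag
        src = place(seg.size, f"duplicated segment {i} (source)",
                    config.repeat_gap)
        cpy = place(seg.size, f"duplicated segment {i} (copy)",
                    config.repeat_gap)
        genome[src : src + seg.size] = seg
        genome[cpy : cpy + seg.size] = seg
        for base, tag in ((src, "src"), (cpy, "copy")):
            repeats.append(
                RepeatFeature(chrom, base + o, base + o + frag.size, "+",
                              "LINE1", f"LINE1_dup{i}_{tag}")
            )
        dups.append(
            ((chrom, src, src + seg.size), (chrom, cpy, cpy + seg.size))
        )

    bundle = GenomeBundle(
        sequences={chrom: genome.tobytes().decode()},
        genes=genes,
        repeats=repeats,
        duplicated_segments=dups,
        consensus={k: v.tobytes().decode() for k, v in consensus.items()},
    )
    bundle.validate()
    return bundle


def _make_gene(gene_id, chrom, strand, start, span, rel_exons,
               autr, cutr, cds_off5) -> GeneModel:
    """Instantiate a gene from +strand-relative exon blocks, mirroring for -."""
    if strand == "+":
        exons = tuple((start + a, start + b) for a, b in rel_exons)
        pas_distal = start + span if autr > 0 else None
        pas_proximal = start + span - autr if autr > 0 else start + span
        cds = (start + cds_off5,
               start + span - autr - cutr)
    else:
        exons = tuple(
            sorted((start + span - b, start + span - a) for a, b in rel_exons)
        )
        pas_distal = start if autr > 0 else None
        pas_proximal = start + autr if autr > 0 else start
        cds = (start + autr + cutr, start + span - cds_off5)
    return GeneModel(gene_id, chrom, strand, exons, pas_proximal,
                     pas_distal, cds)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _isoform_blocks(gene: GeneModel, pas: int, ext: int,
                    chrom_length: int, unspliced: bool) -> List[tuple]:
    """Transcript blocks in transcript (5'->3') order, genomically clipped.

    The poly(A) site lies inside an exon, so read-through extension is
    genomically contiguous with the clipped terminal exon.
    """
    if gene.strand == "+":
        end = min(pas + ext, chrom_length)
        if unspliced:
            return [(gene.tx_start, end)]
        blocks = [(s, min(e, pas)) for s, e in gene.exons if s < pas]
        blocks[-1] = (blocks[-1][0], max(blocks[-1][1], end))
        return blocks
    start = max(pas - ext, 0)
    if unspliced:
        return [(start, gene.tx_end)]
    blocks = [(max(s, pas), e) for s, e in gene.exons if e > pas]
    blocks[0] = (min(blocks[0][0], start), blocks[0][1])
    return list(reversed(blocks))  # transcript order for - strand


def _map_transcript_interval(blocks_tx, strand, t0, t1) -> Tuple[tuple, ...]:
    """Map a transcript-coordinate interval to sorted genomic blocks."""
    out = []
    off = 0
    for s, e in blocks_tx:
        blen = e - s
        lo, hi = max(t0, off), min(t1, off + blen)
        if lo < hi:
            if strand == "+":
                out.append((s + (lo - off), s + (hi - off)))
            else:
                out.append((e - (hi - off), e - (lo - off)))
        off += blen
    out.sort()
    return tuple(out)


def intergenic_intervals(bundle: GenomeBundle, utr3_ext: int = 4000,
                         utr5_ext: int = 1000) -> Dict[str, List[tuple]]:
    """Intervals outside gene bodies, extension windows and repeats.

    This is the sampling space for background intergenic reads: real
    intergenic reads mostly do not fall on uniquely mappable repeat copies,
    and keeping repeats out of the background makes repeat-expression
    recovery by the fold-change estimator interpretable.
    """
    blocked: Dict[str, List[tuple]] = {c: [] for c in bundle.sequences}
    for gene in bundle.genes:
        L = bundle.chrom_lengths[gene.chrom]
        blocked[gene.chrom].append((gene.tx_start, gene.tx_end))
        blocked[gene.chrom].append(gene.utr3_window(utr3_ext, L))
        blocked[gene.chrom].append(gene.utr5_window(utr5_ext, L))
    for rep in bundle.repeats:
        blocked[rep.chrom].append((rep.start, rep.end))
    out: Dict[str, List[tuple]] = {}
    for chrom, ivls in blocked.items():
        L = bundle.chrom_lengths[chrom]
        merged: List[list] = []
        for s, e in sorted(ivls):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        free = []
        prev = 0
        for s, e in merged:
            if s > prev:
                free.append((prev, s))
            prev = max(prev, e)
        if prev < L:
            free.append((prev, L))
        out[chrom] = free
    return out


def simulate_reads(
    bundle: GenomeBundle,
    params: ConditionParams,
    read_prefix: str = "read",
    utr3_ext: int = 4000,
    utr5_ext: int = 1000,
) -> Tuple[List[tuple], List[SimulationTruth]]:
    """Simulate unstranded cDNA fragments with per-read ground truth.

    Each read is drawn from one source: a LINE-1 element (genomic copy or,
    for a ``line1_consensus_frac`` share, the consensus itself, standing for
    diverged expressed copies absent from the assembly), a SINE or LTR copy,
    background intergenic space, random junk, or a gene. Gene reads choose
    the distal isoform with probability ``distal_frac``, extend past the
    chosen site with probability ``readthrough_prob`` by an exponential
    distance (capped), and are spliced except for an ``unspliced_frac``
    pre-mRNA share. Fragment lengths are normal(500, 100) truncated to
    [100, 1000] and truncated at transcript boundaries.
    """
    params.validate()
    bundle.validate()
    rng = np.random.default_rng(params.seed)
    chrom_lengths = bundle.chrom_lengths

    genes = list(bundle.genes)
    if not genes:
        raise ModelError("bundle has no genes")

    by_class: Dict[str, list] = {}
    for rep in bundle.repeats:
        by_class.setdefault(rep.repeat_class, []).append(rep)
    class_weights = {
        cls: np.array([r.element_length for r in reps], dtype=float)
        for cls, reps in by_class.items()
    }
    for cls in class_weights:
        class_weights[cls] /= class_weights[cls].sum()

    free = intergenic_intervals(bundle, utr3_ext, utr5_ext)
    ig_pool = [
        (chrom, s, e)
        for chrom, ivls in free.items()
        for s, e in ivls
        if e - s > params.read_length_max + 10
    ]
    ig_weights = np.array(
        [e - s - params.read_length_max for _, s, e in ig_pool], dtype=float
    )
    if ig_weights.size:
        ig_weights /= ig_weights.sum()

    thresholds = np.cumsum([
        params.line1_rate, params.sine_rate, params.ltr_rate,
        params.intergenic_rate, params.junk_rate,
    ])

    reads: List[tuple] = []
    truths: List[SimulationTruth] = []

    def sample_length() -> int:
        raw = rng.normal(params.read_length_mean, params.read_length_sd)
        return int(np.clip(raw, params.read_length_min,
                           params.read_length_max))

    def finish(read_id, seq, truth_kwargs):
        if params.error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            arr = _mutate(arr, params.error_rate, rng)
            seq = arr.tobytes().decode()
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        truths.append(SimulationTruth(read_id=read_id, strand=strand,
                                      **truth_kwargs))
        reads.append((read_id, seq))

    def repeat_read(read_id, cls):
        reps = by_class.get(cls)
        if not reps:
            raise ModelError(f"no {cls} elements in the bundle")
        rep = reps[rng.choice(len(reps), p=class_weights[cls])]
        n = sample_length()
        if n >= rep.element_length:
            s, e = rep.start, rep.end
        else:
            off = int(rng.integers(0, rep.element_length - n + 1))
            s, e = rep.start + off, rep.start + off + n
        seq = bundle.fetch(rep.chrom, s, e)
        finish(read_id, seq, dict(
            source_kind="repeat", source_id=rep.name, isoform="none",
            readthrough_flag=False, chrom=rep.chrom, start=s, end=e,
            blocks=((s, e),),
        ))

    def consensus_read(read_id):
        cons = bundle.consensus["LINE1"]
        n = min(sample_length(), len(cons))
        off = int(rng.integers(0, len(cons) - n + 1))
        finish(read_id, cons[off : off + n], dict(
            source_kind="repeat", source_id="LINE1_consensus",
            isoform="none", readthrough_flag=False, chrom=None,
            start=None, end=None, blocks=None,
        ))

    def intergenic_read(read_id):
        if not ig_pool:
            raise ModelError("no intergenic space available")
        chrom, s0, e0 = ig_pool[rng.choice(len(ig_pool), p=ig_weights)]
        n = sample_length()
        s = int(rng.integers(s0, e0 - n + 1))
        seq = bundle.fetch(chrom, s, s + n)
        finish(read_id, seq, dict(
            source_kind="intergenic", source_id="intergenic",
            isoform="none", readthrough_flag=False, chrom=chrom,
            start=s, end=s + n, blocks=((s, s + n),),
        ))

    def junk_read(read_id):
        n = sample_length()
        seq = _random_bases(rng, n).tobytes().decode()
        finish(read_id, seq, dict(
            source_kind="junk", source_id="junk", isoform="none",
            readthrough_flag=False, chrom=None, start=None, end=None,
            blocks=None,
        ))

    def gene_read(read_id):
        gene = genes[int(rng.integers(len(genes)))]
        if gene.is_apa and rng.random() < params.distal_frac:
            isoform, pas = "distal", gene.pas_distal
        elif gene.is_apa:
            isoform, pas = "proximal", gene.pas_proximal
        else:
            isoform, pas = "none", gene.pas_proximal
        ext = 0
        if rng.random() < params.readthrough_prob:
            ext = int(min(rng.exponential(params.extension_scale),
                          params.extension_cap))
        unspliced = rng.random() < params.unspliced_frac
        blocks_tx = _isoform_blocks(gene, pas, ext,
                                    chrom_lengths[gene.chrom], unspliced)
        lt = sum(e - s for s, e in blocks_tx)
        n = sample_length()
        t0 = int(rng.integers(0, lt))
        t1 = min(t0 + n, lt)
        gblocks = _map_transcript_interval(blocks_tx, gene.strand, t0, t1)
        flag = ext > 0 and t1 > lt - ext
        seq = "".join(bundle.fetch(gene.chrom, s, e) for s, e in gblocks)
        finish(read_id, seq, dict(
            source_kind="gene", source_id=gene.gene_id, isoform=isoform,
            readthrough_flag=flag, chrom=gene.chrom,
            start=gblocks[0][0], end=gblocks[-1][1], blocks=gblocks,
        ))

    for i in range(params.n_reads):
        read_id = f"{read_prefix}_{i:06d}"
        u = rng.random()
        if u < thresholds[0]:
            if rng.random() < params.line1_consensus_frac:
                consensus_read(read_id)
            else:
                repeat_read(read_id, "LINE1")
        elif u < thresholds[1]:
            repeat_read(read_id, "SINE")
        elif u < thresholds[2]:
            repeat_read(read_id, "LTR")
        elif u < thresholds[3]:
            intergenic_read(read_id)
        elif u < thresholds[4]:
            junk_read(read_id)
        else:
            gene_read(read_id)
    return reads, truths


# ---------------------------------------------------------------------------
# truth-derived PSL emission
# ---------------------------------------------------------------------------

def emit_truth_psl(
    reads: Sequence[tuple],
    truths: Sequence[SimulationTruth],
    bundle: GenomeBundle,
) -> List[str]:
    """Emit one PSL line per true placement, plus duplicated-copy lines.

    A placement falling entirely inside one side of a duplicated segment is
    also reported at the mirrored coordinates, reproducing the multi-hit
    alignments an aligner would find. Match/mismatch counts are computed
    against the genome sequence. Reads without a genomic placement yield no
    line (they are the unmapped fraction).
    """
    seq_by_id = dict(reads)
    if len(seq_by_id) != len(reads):
        raise ModelError("duplicate read ids")
    lines: List[str] = []
    chrom_lengths = bundle.chrom_lengths
    for truth in truths:
        if not truth.has_placement:
            continue
        seq = seq_by_id.get(truth.read_id)
        if seq is None:
            raise ModelError(f"truth for unknown read {truth.read_id}")
        blocks = truth.blocks or ((truth.start, truth.end),)
        placements = [(truth.chrom, blocks)]
        for (schrom, ss, se), (cchrom, cs, ce) in bundle.duplicated_segments:
            for (a_chrom, a_s, a_e), (b_chrom, b_s) in (
                ((schrom, ss, se), (cchrom, cs)),
                ((cchrom, cs, ce), (schrom, ss)),
            ):
                if truth.chrom == a_chrom and blocks[0][0] >= a_s \
                        and blocks[-1][1] <= a_e:
                    delta = b_s - a_s
                    placements.append(
                        (b_chrom,
                         tuple((s + delta, e + delta) for s, e in blocks))
                    )
        oriented = revcomp(seq) if truth.strand == "-" else seq
        for chrom, blks in placements:
            genome_seq = "".join(bundle.fetch(chrom, s, e) for s, e in blks)
            if len(genome_seq) != len(oriented):
                raise ModelError(
                    f"read {truth.read_id}: truth blocks disagree with length"
                )
            matches = sum(a == b for a, b in zip(oriented, genome_seq))
            lines.append(_psl_line(
                truth.read_id, len(seq), truth.strand, chrom,
                chrom_lengths[chrom], blks, matches,
                len(seq) - matches,
            ))
    return lines


def _psl_line(read_id, qsize, strand, chrom, tsize, blocks,
              matches, mismatches) -> str:
    sizes = [e - s for s, e in blocks]
    q_starts = list(np.cumsum([0] + sizes[:-1]))
    t_span = blocks[-1][1] - blocks[0][0]
    fields = [
        matches, mismatches, 0, 0, 0, 0,
        len(blocks) - 1, t_span - qsize,
        strand, read_id, qsize, 0, qsize,
        chrom, tsize, blocks[0][0], blocks[-1][1],
        len(blocks),
        ",".join(str(x) for x in sizes) + ",",
        ",".join(str(x) for x in q_starts) + ",",
        ",".join(str(s) for s, _ in blocks) + ",",
    ]
    return "\t".join(str(f) for f in fields)


# ---------------------------------------------------------------------------
# expression tables for the stratification stage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionSimConfig:
    """Synthetic per-gene expression for the length/exon stratification.

    Group sizes mirror, at roughly one fifth scale, an annotation in which
    ~20% of genes fall below the short-length cutoff and short single-exon
    genes form a distinct minority class. ``isg_down_factor`` multiplies the
    second condition's expression for short single-exon genes (1.0 = null).
    """

    n_long_multi: int = 2130
    n_short_multi: int = 300
    n_short_single: int = 250
    n_long_single: int = 70
    short_length_range: tuple = (500, 6500)
    long_length_range: tuple = (7000, 200_000)
    isg_down_factor: float = 0.5
    log2_noise_sd: float = 0.4
    mean_log2_expr: float = 6.0
    sd_log2_expr: float = 1.5
    seed: int = 0


def simulate_expression(config: ExpressionSimConfig):
    """Generate gene-info and two-condition expression tables.

    Returns ``(gene_info, expr_a, expr_b)`` DataFrames with columns
    (gene_id, length, n_exons) and (gene_id, value).
    """
    rng = np.random.default_rng(config.seed)
    groups = [
        ("long_multi", config.n_long_multi, config.long_length_range, False),
        ("short_multi", config.n_short_multi, config.short_length_range, False),
        ("short_single", config.n_short_single, config.short_length_range, True),
        ("long_single", config.n_long_single, config.long_length_range, True),
    ]
    rows = []
    for label, n, (lo, hi), single in groups:
        if n == 0:
            continue
        if lo >= 7000:  # long genes: log-uniform lengths
            lengths = np.exp(
                rng.uniform(np.log(lo), np.log(hi), size=n)
            ).astype(int)
        else:
            lengths = rng.integers(lo, hi, size=n)
        n_exons = (np.ones(n, dtype=int) if single
                   else rng.integers(2, 26, size=n))
        for j in range(n):
            rows.append((label, int(lengths[j]), int(n_exons[j])))
    gene_ids = [f"g{i:05d}" for i in range(len(rows))]
    labels = [r[0] for r in rows]
    gene_info = pd.DataFrame({
        "gene_id": gene_ids,
        "length": [r[1] for r in rows],
        "n_exons": [r[2] for r in rows],
    })
    base = 2.0 ** rng.normal(config.mean_log2_expr, config.sd_log2_expr,
                             size=len(rows))
    factor = np.array([
        config.isg_down_factor if lab == "short_single" else 1.0
        for lab in labels
    ])
    noise = 2.0 ** rng.normal(0.0, config.log2_noise_sd, size=len(rows))
    expr_a = pd.DataFrame({"gene_id": gene_ids, "value": base})
    expr_b = pd.DataFrame({"gene_id": gene_ids,
                           "value": base * factor * noise})
    return gene_info, expr_a, expr_b
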