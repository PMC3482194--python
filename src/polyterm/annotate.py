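"""Six-way genomic region classification of uniquely mapped reads.

A read is classified against the flattened gene models by precedence:
fully exonic in a single gene > exon & intron of one gene > fully intronic
> within the 4 kb window downstream of an annotated 3' end > within the
1 kb window upstream of a 5' end > intergenic. Gene-body categories
dominate extension windows; overlap is strand-agnostic (the library is
unstranded). Ties between genes go to the gene with the most overlapped
bases, then lexicographic gene id.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from intervaltree import IntervalTree

from .model import REGION_CATEGORIES, GeneModel
from .stats import fisher_exact_2x2

DEFAULT_UTR3_EXT = 4000
DEFAULT_UTR5_EXT = 1000


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class RegionCall:
    read_id: str
    category: str
    gene_id: Optional[str] = None


@dataclass
class RegionTable:
    """Per-condition category counts and proportions."""

    condition: str
    counts: Dict[str, int]
    total: int
    proportions: Optional[Dict[str, float]] = None

    @classmethod
    def from_counts(cls, condition: str, counts: Dict[str, int]) -> "RegionTable":
        full = {c: int(counts.get(c, 0)) for c in REGION_CATEGORIES}
        total = sum(full.values())
        props = ({c: v / total for c, v in full.items()}
                 if total > 0 else None)
        return cls(condition, full, total, props)


@dataclass(frozen=True)
class CategoryComparison:
    category: str
    count_a: int
    count_b: int
    prop_a: float
    prop_b: float
    ratio: float  # prop_b / prop_a
    fisher_p: float
    degenerate: bool = False


@dataclass
class _GeneFeatures:
    gene: GeneModel
    exons: tuple
    introns: tuple
    utr3_ext: tuple
    utr5_ext: tuple


class GeneIndex:
    """Interval index over exons, introns and extension windows."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        chrom_lengths: Dict[str, int],
        utr3_ext: int = DEFAULT_UTR3_EXT,
        utr5_ext: int = DEFAULT_UTR5_EXT,
    ):
        self.chrom_lengths = dict(chrom_lengths)
        self.features: Dict[str, _GeneFeatures] = {}
        self._trees: Dict[str, IntervalTree] = {}
        for gene in genes:
            if gene.gene_id in self.features:
                raise AnnotationError(f"duplicate gene id {gene.gene_id!r}")
            L = chrom_lengths[gene.chrom]
            feats = _GeneFeatures(
                gene=gene,
                exons=gene.exons,
                introns=gene.introns,
                utr3_ext=gene.utr3_window(utr3_ext, L),
                utr5_ext=gene.utr5_window(utr5_ext, L),
            )
            self.features[gene.gene_id] = feats
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            for kind, ivls in (
                ("exon", feats.exons),
                ("intron", feats.introns),
                ("utr3_ext", (feats.utr3_ext,)),
                ("utr5_ext", (feats.utr5_ext,)),
            ):
                for s, e in ivls:
                    if e > s:
                        tree.addi(s, e, (gene.gene_id, kind))

    def query(self, chrom: str, start: int, end: int) -> List[tuple]:
        """All (gene_id, kind, start, end) features overlapping an interval."""
        if chrom not in self.chrom_lengths:
            raise AnnotationError(f"unknown chromosome {chrom!r}")
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [
            (iv.data[0], iv.data[1], iv.begin, iv.end)
            for iv in tree.overlap(start, end)
        ]


def _overlap(blocks, intervals) -> int:
    total = 0
    for bs, be in blocks:
        for s, e in intervals:
            lo, hi = max(bs, s), min(be, e)
            if lo < hi:
                total += hi - lo
    return total


def _merged_coverage(blocks, intervals) -> int:
    """Bases of ``blocks`` covered by the union of ``intervals``."""
    merged: List[list] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return _overlap(blocks, merged)


def classify_read(blocks: Sequence[tuple], index: GeneIndex,
                  chrom: str, read_id: str = "") -> RegionCall:
    """Assign one six-way region category to an aligned read."""
    blocks = sorted(blocks)
    total = sum(e - s for s, e in blocks)
    if total == 0:
        raise AnnotationError(f"read {read_id}: empty block list")
    feats = index.query(chrom, blocks[0][0], blocks[-1][1])
    gene_ids = sorted({gid for gid, _, _, _ in feats})

    exon_cov: Dict[str, int] = {}
    intron_cov: Dict[str, int] = {}
    for gid in gene_ids:
        gf = index.features[gid]
        exon_cov[gid] = _overlap(blocks, gf.exons)
        intron_cov[gid] = _overlap(blocks, gf.introns)

    def best(candidates, cov):
        return min(candidates, key=lambda g: (-cov[g], g))

    fully_exonic = [g for g in gene_ids if exon_cov[g] == total]
    if fully_exonic:
        return RegionCall(read_id, "exon", best(fully_exonic, exon_cov))

    mixed = [g for g in gene_ids if exon_cov[g] > 0 and intron_cov[g] > 0]
    if mixed:
        cov = {g: exon_cov[g] + intron_cov[g] for g in mixed}
        return RegionCall(read_id, "exon_intron", best(mixed, cov))

    all_introns = [ivl for g in gene_ids for ivl in index.features[g].introns]
    if all_introns and _merged_coverage(blocks, all_introns) == total:
        return RegionCall(read_id, "intron", best(gene_ids, intron_cov))

    for kind in ("utr3_ext", "utr5_ext"):
        cov = {
            g: _overlap(blocks, (getattr(index.features[g], kind),))
            for g in gene_ids
        }
        hit = [g for g in gene_ids if cov[g] > 0]
        if hit:
            return RegionCall(read_id, kind, best(hit, cov))

    return RegionCall(read_id, "intergenic", None)


def tabulate_regions(calls: Sequence[RegionCall], condition: str) -> RegionTable:
    counts: Dict[str, int] = {}
    for call in calls:
        counts[call.category] = counts.get(call.category, 0) + 1
    return RegionTable.from_counts(condition, counts)


def compare_region_tables(a: RegionTable, b: RegionTable) -> List[CategoryComparison]:
    """Fisher exact tests of each non-exon category against the exon control.

    For category c the 2x2 table is [[count_a(c), count_a(exon)],
    [count_b(c), count_b(exon)]]; the reported ratio is the proportion in b
    over the proportion in a.
    """
    if a.total == 0 or b.total == 0:
        raise AnnotationError("cannot compare empty region tables")
    if a.counts["exon"] == 0 or b.counts["exon"] == 0:
        raise AnnotationError("exon control category has zero count")
    out = []
    for cat in REGION_CATEGORIES:
        if cat == "exon":
            continue
        ca, cb = a.counts[cat], b.counts[cat]
        pa, pb = ca / a.total, cb / b.total
        degenerate = ca == 0 and cb == 0
        pval = 1.0 if degenerate else fisher_exact_2x2(
            [[ca, a.counts["exon"]], [cb, b.counts["exon"]]]
        )
        ratio = (pb / pa) if pa > 0 else float("inf") if pb > 0 else 1.0
        out.append(CategoryComparison(cat, ca, cb, pa, pb, ratio, pval,
                                      degenerate))
    return out
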