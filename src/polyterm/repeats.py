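"""Transposable-element read attribution and LINE-1 3'-end profiling.

Reads are attributed to LINE-1 / SINE / LTR classes within four read
categories: uniquely mapped intergenic reads, uniquely mapped intronic
reads, non-uniquely mapped reads (using all reported placements), and
unmapped reads (matched against a consensus library). A read overlapping a
repeat by >= 1 bp is attributed; a read overlapping two classes counts once
in each and is flagged. Full-length LINE-1 expression is supported by reads
overlapping genomic LINE-1 copies of >= 6 kb, whose 3'-end positions are
binned into five equal element-relative fifths.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from .alignment import AlignmentHit, MappingStatus, STATUS_NON_UNIQUE, STATUS_UNIQUE
from .annotate import RegionCall
from .model import REPEAT_CLASSES, RepeatFeature
from .stats import chi_squared, fisher_exact_2x2, proportion_sd

READ_CATEGORIES = ("intergenic_unique", "intronic_unique", "non_unique",
                   "unmapped")
DEFAULT_LINE1_MIN_LENGTH = 6000
DEFAULT_N_BINS = 5


class RepeatError(ValueError):
    pass


@dataclass
class RepeatCountTable:
    condition: str
    read_category: str
    counts: Dict[str, int]  # repeat class -> distinct reads
    total: int  # all reads in the category
    multi_class_reads: int = 0  # reads attributed to more than one class


@dataclass(frozen=True)
class FoldChange:
    repeat_class: str
    read_category: str
    count_a: int
    count_b: int
    total_a: int
    total_b: int
    fold: float  # (count_b/total_b) / (count_a/total_a)
    fisher_p: float
    sd_a: float
    sd_b: float
    infinite: bool = False


@dataclass
class Line1EndProfile:
    condition: str
    bin_counts: List[int]
    n_reads: int


class RepeatIndex:
    def __init__(self, repeats: Sequence[RepeatFeature]):
        self._trees: Dict[str, IntervalTree] = {}
        for rep in repeats:
            tree = self._trees.setdefault(rep.chrom, IntervalTree())
            tree.addi(rep.start, rep.end, rep)

    def overlapping(self, chrom: str, blocks: Sequence[tuple]) -> List[RepeatFeature]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        found = {}
        for s, e in blocks:
            for iv in tree.overlap(s, e):
                found[id(iv.data)] = iv.data
        return list(found.values())


def attribute_repeats(
    statuses: Dict[str, MappingStatus],
    calls: Dict[str, RegionCall],
    repeats: Sequence[RepeatFeature],
    condition: str,
    all_hits: Optional[Dict[str, List[AlignmentHit]]] = None,
) -> Dict[str, RepeatCountTable]:
    """Count repeat-class reads in the mapped read categories.

    Unique reads are split by their region call (intergenic vs intron);
    non-unique reads are attributed via the union of all their placements
    (``all_hits``; falls back to the best hit when not supplied).
    """
    index = RepeatIndex(repeats)
    tables = {
        cat: RepeatCountTable(condition, cat,
                              {c: 0 for c in REPEAT_CLASSES}, 0)
        for cat in ("intergenic_unique", "intronic_unique", "non_unique")
    }
    for read_id, status in statuses.items():
        if status.status == STATUS_UNIQUE:
            call = calls.get(read_id)
            if call is None:
                raise RepeatError(
                    f"unique read {read_id} has no region call"
                )
            if call.category == "intergenic":
                cat = "intergenic_unique"
            elif call.category == "intron":
                cat = "intronic_unique"
            else:
                continue  # exonic and extension-window reads are excluded
            placements = [status.best_hit]
        elif status.status == STATUS_NON_UNIQUE:
            cat = "non_unique"
            if all_hits is not None and read_id in all_hits:
                placements = all_hits[read_id]
            else:
                placements = [status.best_hit]
        else:
            continue
        table = tables[cat]
        table.total += 1
        classes = set()
        for hit in placements:
            for rep in index.overlapping(hit.chrom, hit.blocks):
                classes.add(rep.repeat_class)
        for cls in classes:
            table.counts[cls] += 1
        if len(classes) > 1:
            table.multi_class_reads += 1
    return tables


def match_consensus(
    seq: str,
    library: Dict[str, str],
    min_aligned_frac: float = 0.5,
    min_identity: float = 0.8,
) -> Optional[str]:
    """Attribute a read to a repeat class by ungapped consensus alignment.

    Slides the read (both strands) along each consensus; the best-scoring
    class is assigned when at least ``min_aligned_frac`` of the read aligns
    at ``min_identity`` or better, else ``None``.
    """
    if not library:
        raise RepeatError("empty consensus library")
    if not seq:
        raise RepeatError("empty read sequence")
    from .model import revcomp

    n = len(seq)
    min_overlap = int(np.ceil(min_aligned_frac * n))
    best_cls, best_score = None, -1
    for cls, cons in library.items():
        m = len(cons)
        if m < min_overlap:
            continue
        cons_arr = np.frombuffer(cons.encode(), dtype=np.uint8)
        pad = n - min_overlap
        padded = np.zeros(m + 2 * pad, dtype=np.uint8)  # 0 never matches ACGT
        padded[pad : pad + m] = cons_arr
        n_off = padded.size - n + 1
        for oriented in (seq, revcomp(seq)):
            q = np.frombuffer(oriented.encode(), dtype=np.uint8)
            matches = np.zeros(n_off, dtype=np.int32)
            for i in range(n):
                matches += padded[i : i + n_off] == q[i]
            offsets = np.arange(n_off)
            overlap = (np.minimum(offsets + n, pad + m)
                       - np.maximum(offsets, pad))
            ok = (overlap >= min_overlap) & (
                matches >= np.ceil(min_identity * overlap)
            )
            if ok.any():
                score = int(matches[ok].max())
                if score > best_score:
                    best_score, best_cls = score, cls
    return best_cls


def attribute_unmapped(
    reads: Sequence[tuple],
    library: Dict[str, str],
    condition: str,
    min_aligned_frac: float = 0.5,
    min_identity: float = 0.8,
) -> RepeatCountTable:
    """Repeat-class counts among unmapped reads via consensus matching."""
    counts = {c: 0 for c in REPEAT_CLASSES}
    for _read_id, seq in reads:
        cls = match_consensus(seq, library, min_aligned_frac, min_identity)
        if cls is not None:
            counts[cls] += 1
    return RepeatCountTable(condition, "unmapped", counts, len(reads))


def repeat_fold_change(
    a: RepeatCountTable, b: RepeatCountTable, repeat_class: str
) -> FoldChange:
    """Proportion fold change of one repeat class between two conditions."""
    if a.read_category != b.read_category:
        raise RepeatError("fold change requires matching read categories")
    if a.total == 0 or b.total == 0:
        raise RepeatError("fold change requires nonzero category totals")
    ca, cb = a.counts[repeat_class], b.counts[repeat_class]
    pa, pb = ca / a.total, cb / b.total
    infinite = ca == 0
    fold = float("inf") if infinite else pb / pa
    fisher_p = fisher_exact_2x2(
        [[ca, a.total - ca], [cb, b.total - cb]]
    )
    return FoldChange(
        repeat_class, a.read_category, ca, cb, a.total, b.total, fold,
        fisher_p, proportion_sd(pa, a.total), proportion_sd(pb, b.total),
        infinite,
    )


def line1_full_length_filter(
    unique_hits: Iterable[AlignmentHit],
    repeats: Sequence[RepeatFeature],
    min_length: int = DEFAULT_LINE1_MIN_LENGTH,
) -> List[Tuple[AlignmentHit, RepeatFeature]]:
    """Pairs of (hit, element) where a unique read overlaps a full-length
    LINE-1 copy (element length >= 6 kb); partial overlap qualifies."""
    full = [r for r in repeats
            if r.repeat_class == "LINE1" and r.element_length >= min_length]
    index = RepeatIndex(full)
    pairs = []
    for hit in unique_hits:
        elements = index.overlapping(hit.chrom, hit.blocks)
        if not elements:
            continue

        def olap(rep):
            return sum(
                max(0, min(e, rep.end) - max(s, rep.start))
                for s, e in hit.blocks
            )

        best = min(elements, key=lambda r: (-olap(r), r.start))
        pairs.append((hit, best))
    return pairs


def line1_end_profile(
    pairs: Sequence[Tuple[AlignmentHit, RepeatFeature]],
    condition: str,
    n_bins: int = DEFAULT_N_BINS,
) -> Line1EndProfile:
    """Bin read 3'-end positions along full-length LINE-1 elements.

    The read's 3'-most aligned base (alignment-strand aware) is converted to
    the element-relative coordinate in element 5'->3' orientation and
    assigned to bin floor(n_bins * pos / element_length), clamped to the
    last bin.
    """
    counts = [0] * n_bins
    for hit, rep in pairs:
        if hit.chrom != rep.chrom or hit.end <= rep.start or hit.start >= rep.end:
            raise RepeatError(
                f"read {hit.read_id} does not overlap its paired element"
            )
        gpos = hit.end - 1 if hit.strand == "+" else hit.start
        if rep.strand == "+":
            rel = gpos - rep.start
        else:
            rel = rep.end - 1 - gpos
        rel = min(max(rel, 0), rep.element_length - 1)
        b = int(n_bins * rel / rep.element_length)
        counts[min(b, n_bins - 1)] += 1
    return Line1EndProfile(condition, counts, len(pairs))


def compare_end_profiles(a: Line1EndProfile, b: Line1EndProfile):
    """Chi-squared comparison of two 3'-end bin distributions."""
    if a.n_reads == 0 or b.n_reads == 0:
        raise RepeatError("end profiles must contain reads")
    return chi_squared([a.bin_counts, b.bin_counts])
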