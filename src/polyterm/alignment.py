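"""PSL ingestion and mapping-uniqueness resolution.

Each candidate placement of a read is scored as matches minus mismatches;
a read is uniquely mapped when the best hit outscores the second best by at
least the gap threshold (default 10, inclusive). Reads with no hits are
unmapped; tied or closely scored hits are non-unique.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .model import GenomeBundle, revcomp

PSL_COLUMNS = 21
DEFAULT_GAP_THRESHOLD = 10

STATUS_UNIQUE = "unique"
STATUS_NON_UNIQUE = "non_unique"
STATUS_UNMAPPED = "unmapped"


class PslFormatError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentHit:
    """One candidate placement of a read on the genome."""

    read_id: str
    chrom: str
    strand: str
    blocks: tuple  # sorted, non-overlapping (target_start, target_end)
    matches: int
    mismatches: int

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def score(self) -> int:
        return self.matches - self.mismatches


@dataclass(frozen=True)
class MappingStatus:
    read_id: str
    status: str
    best_hit: Optional[AlignmentHit] = None
    score_gap: Optional[int] = None


def score_hit(hit: AlignmentHit) -> int:
    """Alignment score: matched minus mismatched nucleotides."""
    return hit.matches - hit.mismatches


def read_psl(path) -> List[AlignmentHit]:
    """Parse a 21-column PSL file into alignment hits.

    Accepts headerless files and files carrying the standard 5-line
    ``psLayout`` header. Only single-character ``+``/``-`` strands are
    accepted (no translocation dialects).
    """
    with open(path) as fh:
        return parse_psl_lines(fh.readlines())


def parse_psl_lines(lines: Sequence[str]) -> List[AlignmentHit]:
    """Parse PSL records given as lines (see :func:`read_psl`)."""
    hits: List[AlignmentHit] = []
    start = 0
    if lines and lines[0].startswith("psLayout"):
        start = 5
    for lineno, line in enumerate(lines[start:], start=start + 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != PSL_COLUMNS:
            raise PslFormatError(
                f"line {lineno}: expected {PSL_COLUMNS} columns, got {len(fields)}"
            )
        try:
            matches = int(fields[0])
            mismatches = int(fields[1])
            strand = fields[8]
            read_id = fields[9]
            chrom = fields[13]
            block_count = int(fields[17])
            block_sizes = _parse_int_list(fields[18])
            t_starts = _parse_int_list(fields[20])
        except ValueError as exc:
            raise PslFormatError(f"line {lineno}: {exc}") from None
        if strand not in ("+", "-"):
            raise PslFormatError(
                f"line {lineno}: unsupported strand field {strand!r}"
            )
        if len(block_sizes) != block_count or len(t_starts) != block_count:
            raise PslFormatError(
                f"line {lineno}: block list lengths disagree with blockCount"
            )
        blocks = tuple(
            (ts, ts + bs) for ts, bs in zip(t_starts, block_sizes)
        )
        hits.append(
            AlignmentHit(read_id, chrom, strand, blocks, matches, mismatches)
        )
    return hits


def _parse_int_list(field: str) -> List[int]:
    return [int(tok) for tok in field.rstrip(",").split(",") if tok]


def resolve_uniqueness(
    hits: Sequence[AlignmentHit],
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
) -> MappingStatus:
    """Classify one read's hit set as unique / non-unique / unmapped.

    With two or more hits the read is unique iff the best score exceeds the
    second best by at least ``gap_threshold`` (inclusive). The best hit is
    reported in either case, with ties broken by (chrom, start) for
    determinism.
    """
    if gap_threshold < 0:
        raise AlignmentError("gap_threshold must be >= 0")
    hits = list(hits)
    if not hits:
        raise AlignmentError("resolve_uniqueness needs the read_id for empty hit sets")
    read_id = hits[0].read_id
    for h in hits:
        if h.read_id != read_id:
            raise AlignmentError(
                f"hits mix read ids {read_id!r} and {h.read_id!r}"
            )
    ordered = sorted(hits, key=lambda h: (-h.score, h.chrom, h.start))
    best = ordered[0]
    if len(ordered) == 1:
        return MappingStatus(read_id, STATUS_UNIQUE, best, None)
    gap = best.score - ordered[1].score
    status = STATUS_UNIQUE if gap >= gap_threshold else STATUS_NON_UNIQUE
    return MappingStatus(read_id, status, best, gap)


def resolve_all(
    hits: Iterable[AlignmentHit],
    read_ids: Optional[Iterable[str]] = None,
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
) -> Dict[str, MappingStatus]:
    """Resolve every read; reads listed but absent from the hits are unmapped."""
    by_read: Dict[str, List[AlignmentHit]] = {}
    for hit in hits:
        by_read.setdefault(hit.read_id, []).append(hit)
    statuses: Dict[str, MappingStatus] = {}
    for read_id, read_hits in by_read.items():
        statuses[read_id] = resolve_uniqueness(read_hits, gap_threshold)
    if read_ids is not None:
        for read_id in read_ids:
            if read_id not in statuses:
                statuses[read_id] = MappingStatus(read_id, STATUS_UNMAPPED)
    return statuses


_MAX_TOY_GENOME = 1_000_000


def toy_align(
    reads: Sequence[tuple],
    bundle: GenomeBundle,
    min_identity: float = 0.9,
) -> List[AlignmentHit]:
    """Brute-force ungapped aligner for small fixtures.

    Reports every position (both strands) where the read aligns end-to-end
    with at least ``min_identity`` matching bases. Quadratic in genome and
    read length; guarded to toy genomes of <= 1 Mb.
    """
    total = sum(len(s) for s in bundle.sequences.values())
    if total > _MAX_TOY_GENOME:
        raise AlignmentError(
            f"toy_align is limited to genomes <= {_MAX_TOY_GENOME} bp (got {total})"
        )
    encoded = {
        chrom: np.frombuffer(seq.encode(), dtype=np.uint8)
        for chrom, seq in bundle.sequences.items()
    }
    hits: List[AlignmentHit] = []
    for read_id, seq in reads:
        n = len(seq)
        if n == 0:
            continue
        threshold = int(np.ceil(min_identity * n))
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            q = np.frombuffer(oriented.encode(), dtype=np.uint8)
            for chrom, g in encoded.items():
                if g.size < n:
                    continue
                counts = np.zeros(g.size - n + 1, dtype=np.int32)
                for i in range(n):
                    counts += g[i : g.size - n + 1 + i] == q[i]
                for pos in np.nonzero(counts >= threshold)[0]:
                    matches = int(counts[pos])
                    hits.append(
                        AlignmentHit(
                            read_id,
                            chrom,
                            strand,
                            ((int(pos), int(pos) + n),),
                            matches,
                            n - matches,
                        )
                    )
    return hits
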