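"""Core genomic domain objects shared across the pipeline.

All coordinates are 0-based half-open genomic intervals. Gene models carry
an annotated proximal and (for genes with alternative polyadenylation) a
distal poly(A) site; the region between them is the alternative 3' UTR
(aUTR), present only in transcripts cleaved at the distal site, while the
constitutive 3' UTR (cUTR) between the stop codon and the proximal site is
present in all isoforms.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

REPEAT_CLASSES = ("LINE1", "SINE", "LTR")

REGION_CATEGORIES = (
    "exon",
    "exon_intron",
    "intron",
    "utr3_ext",
    "utr5_ext",
    "intergenic",
)

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ModelError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class RepeatFeature:
    """One genomic copy of a transposable element.

    ``element_length`` is the length of the genomic copy, the quantity that
    decides whether a LINE-1 element counts as full length (>= 6 kb).
    """

    chrom: str
    start: int
    end: int
    strand: str
    repeat_class: str
    name: str = ""

    @property
    def element_length(self) -> int:
        return self.end - self.start

    def validate(self) -> None:
        if self.end <= self.start:
            raise ModelError(f"repeat {self.name}: end <= start")
        if self.strand not in "+-":
            raise ModelError(f"repeat {self.name}: bad strand {self.strand!r}")
        if self.repeat_class not in REPEAT_CLASSES:
            raise ModelError(
                f"repeat {self.name}: unknown class {self.repeat_class!r}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A transcript model with exon blocks, optional CDS and poly(A) sites.

    ``pas_distal`` is ``None`` for genes without alternative polyadenylation
    (single poly(A) site); such genes provide the background normalization
    for RUD. Strand conventions: on ``+`` the proximal site lies genomically
    left of the distal site; on ``-`` the order reverses.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple  # tuple of (start, end), sorted, disjoint
    pas_proximal: int
    pas_distal: Optional[int] = None
    cds: Optional[tuple] = None  # (start, end)

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_apa(self) -> bool:
        return self.pas_distal is not None

    @property
    def introns(self) -> tuple:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def terminal_pas(self) -> int:
        """The most 3' annotated poly(A) site (distal if present)."""
        return self.pas_distal if self.pas_distal is not None else self.pas_proximal

    def transcript_interval(self, pas: int) -> tuple:
        """Genomic span of a transcript cleaved at ``pas``."""
        if self.strand == "+":
            return (self.tx_start, pas)
        return (pas, self.tx_end)

    def utr3_window(self, size: int, chrom_length: int) -> tuple:
        """Extension window downstream of the annotated 3' end."""
        if self.strand == "+":
            return (self.tx_end, min(self.tx_end + size, chrom_length))
        return (max(self.tx_start - size, 0), self.tx_start)

    def utr5_window(self, size: int, chrom_length: int) -> tuple:
        """Extension window upstream of the annotated 5' end."""
        if self.strand == "+":
            return (max(self.tx_start - size, 0), self.tx_start)
        return (self.tx_end, min(self.tx_end + size, chrom_length))

    def cutr_interval(self) -> tuple:
        """Constitutive 3' UTR: stop codon to proximal poly(A) site."""
        if self.cds is None:
            raise ModelError(f"gene {self.gene_id}: no CDS annotated")
        if self.strand == "+":
            return (self.cds[1], self.pas_proximal)
        return (self.pas_proximal, self.cds[0])

    def autr_interval(self) -> tuple:
        """Alternative 3' UTR: proximal to distal poly(A) site."""
        if not self.is_apa:
            raise ModelError(f"gene {self.gene_id}: single poly(A) site gene")
        if self.strand == "+":
            return (self.pas_proximal, self.pas_distal)
        return (self.pas_distal, self.pas_proximal)

    def validate(self, chrom_length: Optional[int] = None) -> None:
        if self.strand not in "+-":
            raise ModelError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ModelError(f"gene {self.gene_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ModelError(f"gene {self.gene_id}: empty exon block")
            if prev_end is not None and s < prev_end:
                raise ModelError(
                    f"gene {self.gene_id}: exon blocks unsorted or overlapping"
                )
            prev_end = e
        lo, hi = self.tx_start, self.tx_end
        if not (lo <= self.pas_proximal <= hi):
            raise ModelError(f"gene {self.gene_id}: proximal PAS outside span")
        if self.pas_distal is not None:
            if not (lo <= self.pas_distal <= hi):
                raise ModelError(f"gene {self.gene_id}: distal PAS outside span")
            if self.strand == "+" and not self.pas_proximal < self.pas_distal:
                raise ModelError(
                    f"gene {self.gene_id}: + strand requires proximal < distal"
                )
            if self.strand == "-" and not self.pas_proximal > self.pas_distal:
                raise ModelError(
                    f"gene {self.gene_id}: - strand requires proximal > distal"
                )
        if chrom_length is not None and (lo < 0 or hi > chrom_length):
            raise ModelError(f"gene {self.gene_id}: outside chromosome bounds")


@dataclass
class GenomeBundle:
    """A toy genome with gene models, repeat annotation and duplications.

    ``duplicated_segments`` holds ``((chrom, start, end), (chrom, start,
    end))`` pairs whose sequences are identical, the source of multi-hit
    alignments. ``consensus`` maps a repeat class to its consensus sequence
    (the library used to attribute unmapped reads).
    """

    sequences: dict
    genes: list
    repeats: list
    duplicated_segments: list = field(default_factory=list)
    consensus: dict = field(default_factory=dict)

    @property
    def chrom_lengths(self) -> dict:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq) or end < start:
            raise ModelError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds"
            )
        return seq[start:end]

    def validate(self) -> None:
        lengths = self.chrom_lengths
        for gene in self.genes:
            if gene.chrom not in lengths:
                raise ModelError(f"gene {gene.gene_id}: unknown chromosome")
            gene.validate(lengths[gene.chrom])
        for rep in self.repeats:
            rep.validate()
            if rep.chrom not in lengths:
                raise ModelError(f"repeat {rep.name}: unknown chromosome")
            if rep.start < 0 or rep.end > lengths[rep.chrom]:
                raise ModelError(f"repeat {rep.name}: outside chromosome bounds")
        for src, cpy in self.duplicated_segments:
            if self.fetch(*src) != self.fetch(*cpy):
                raise ModelError(
                    f"duplicated segment {src} -> {cpy}: sequences differ"
                )


@dataclass(frozen=True)
class ConditionParams:
    """Per-condition generator settings.

    The three condition-defining dials are the read-through probability
    past the chosen poly(A) site (``readthrough_prob``), the probability of
    cleaving at the distal rather than proximal site (``distal_frac``) and
    the expected fraction of reads drawn from LINE-1 elements
    (``line1_rate``). The remaining rates model background shared between
    conditions.
    """

    n_reads: int
    seed: int
    readthrough_prob: float = 0.1
    extension_scale: float = 2000.0
    distal_frac: float = 0.3
    line1_rate: float = 0.02
    sine_rate: float = 0.05
    ltr_rate: float = 0.05
    intergenic_rate: float = 0.20
    junk_rate: float = 0.01
    line1_consensus_frac: float = 0.2
    unspliced_frac: float = 0.15
    error_rate: float = 0.0
    read_length_mean: float = 500.0
    read_length_sd: float = 100.0
    read_length_min: int = 100
    read_length_max: int = 1000
    extension_cap: int = 10000

    def validate(self) -> None:
        for name in ("readthrough_prob", "distal_frac", "line1_rate",
                     "sine_rate", "ltr_rate", "intergenic_rate", "junk_rate",
                     "line1_consensus_frac", "unspliced_frac", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ModelError(f"{name}={v} outside [0, 1]")
        if self.extension_scale <= 0:
            raise ModelError("extension_scale must be > 0")
        if self.n_reads < 1:
            raise ModelError("n_reads must be >= 1")
        total = (self.line1_rate + self.sine_rate + self.ltr_rate
                 + self.intergenic_rate + self.junk_rate)
        if total > 1.0:
            raise ModelError("source rates sum to more than 1")
        if not 0 < self.read_length_min <= self.read_length_max:
            raise ModelError("bad read length bounds")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth label for one simulated read.

    ``chrom`` is ``None`` for reads with no genomic origin (LINE-1
    consensus-derived mRNA fragments and random junk); ``blocks`` are the
    sorted genomic blocks the read covers (several for spliced reads).
    ``strand`` is the emission strand relative to the genome ``+`` strand
    (the library is unstranded, so it is randomized).
    """

    read_id: str
    source_kind: str  # gene | repeat | intergenic | junk
    source_id: str
    isoform: str  # proximal | distal | none
    readthrough_flag: bool
    chrom: Optional[str]
    start: Optional[int]
    end: Optional[int]
    strand: str
    blocks: Optional[tuple] = None

    @property
    def has_placement(self) -> bool:
        return self.chrom is not None


def truth_sequence(bundle: GenomeBundle, truth: SimulationTruth) -> str:
    """Reconstruct a read's sequence from its truth placement."""
    if not truth.has_placement:
        raise ModelError(f"read {truth.read_id}: no genomic placement")
    blocks = truth.blocks or ((truth.start, truth.end),)
    seq = "".join(bundle.fetch(truth.chrom, s, e) for s, e in blocks)
    return revcomp(seq) if truth.strand == "-" else seq
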