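"""RUD (relative usage of distal poly(A) sites) and read-through indices.

RUD is computed as a read-coverage analog: for a gene with a proximal and a
distal poly(A) site, the constitutive 3' UTR (cUTR, stop codon to proximal
site) is covered by all transcript isoforms while the alternative 3' UTR
(aUTR, proximal to distal site) is covered only by distal-site transcripts,
so after subtracting a background estimated from single-site genes,

    RUD = clip01( (cov_aUTR - background) / (cov_cUTR - background) )

approximates the fraction of transcripts using the distal site. The
read-through index mirrors a qRT-PCR design: mean coverage in a window
downstream of the terminal poly(A) site over mean coverage in a gene-body
window, normalized per gene to a reference condition.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .model import GeneModel
from .stats import welch_t_test


class ApaError(ValueError):
    pass


class CoverageTrack:
    """Per-base read coverage over the toy genome, strand-agnostic."""

    def __init__(self, chrom_lengths: Dict[str, int]):
        self._lengths = dict(chrom_lengths)
        self._delta = {c: np.zeros(n + 1) for c, n in chrom_lengths.items()}
        self._cov: Optional[Dict[str, np.ndarray]] = None

    def add_blocks(self, chrom: str, blocks: Sequence[tuple]) -> None:
        delta = self._delta.get(chrom)
        if delta is None:
            raise ApaError(f"unknown chromosome {chrom!r}")
        n = self._lengths[chrom]
        for s, e in blocks:
            if s < 0 or e > n or e < s:
                raise ApaError(
                    f"interval {chrom}:{s}-{e} outside chromosome bounds"
                )
            delta[s] += 1
            delta[e] -= 1
        self._cov = None

    @classmethod
    def from_hits(cls, hits: Iterable, chrom_lengths: Dict[str, int]):
        track = cls(chrom_lengths)
        for hit in hits:
            track.add_blocks(hit.chrom, hit.blocks)
        return track

    def _coverage(self, chrom: str) -> np.ndarray:
        if self._cov is None:
            self._cov = {
                c: np.cumsum(d[:-1]) for c, d in self._delta.items()
            }
        return self._cov[chrom]

    def mean(self, chrom: str, start: int, end: int) -> float:
        if chrom not in self._lengths:
            raise ApaError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self._lengths[chrom] or end <= start:
            raise ApaError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds"
            )
        return float(self._coverage(chrom)[start:end].mean())


@dataclass(frozen=True)
class RudRecord:
    gene_id: str
    cov_cutr: float
    cov_autr: float
    rud: Optional[float]  # None when undefined (cUTR signal <= background)

    @property
    def defined(self) -> bool:
        return self.rud is not None


@dataclass(frozen=True)
class SampleRud:
    label: str
    mean_rud: float
    sd: float
    n_genes: int
    n_undefined: int
    background: float
    single_gene: bool = False  # sd degenerate


@dataclass(frozen=True)
class ReadThroughResult:
    gene_id: str
    upstream_signal: float
    downstream_signal: float
    ratio: Optional[float]  # None when upstream signal is zero

    @property
    def defined(self) -> bool:
        return self.ratio is not None


@dataclass(frozen=True)
class NormalizedReadThrough:
    gene_id: str
    ratio: Optional[float]
    reference_ratio: Optional[float]
    normalized_fold: Optional[float]


def sample_background(
    non_apa_genes: Sequence[GeneModel],
    coverage: CoverageTrack,
    window: int = 4000,
) -> float:
    """Noise floor: mean coverage downstream of single-site genes' PAS."""
    genes = [g for g in non_apa_genes if not g.is_apa]
    if not genes:
        raise ApaError("background estimation needs >= 1 single-PAS gene")
    means = []
    for gene in genes:
        L = coverage._lengths[gene.chrom]
        if gene.strand == "+":
            s, e = gene.pas_proximal, min(gene.pas_proximal + window, L)
        else:
            s, e = max(gene.pas_proximal - window, 0), gene.pas_proximal
        if e > s:
            means.append(coverage.mean(gene.chrom, s, e))
    if not means:
        raise ApaError("no valid downstream windows for background")
    return float(np.mean(means))


def gene_rud(gene: GeneModel, coverage: CoverageTrack,
             background: float = 0.0) -> RudRecord:
    """Coverage-based RUD for one gene with two poly(A) sites."""
    if not gene.is_apa:
        raise ApaError(f"gene {gene.gene_id} has a single poly(A) site")
    cs, ce = gene.cutr_interval()
    as_, ae = gene.autr_interval()
    if ce <= cs or ae <= as_:
        raise ApaError(f"gene {gene.gene_id}: empty cUTR or aUTR")
    cov_c = coverage.mean(gene.chrom, cs, ce)
    cov_a = coverage.mean(gene.chrom, as_, ae)
    den = cov_c - background
    if den <= 0:
        return RudRecord(gene.gene_id, cov_c, cov_a, None)
    rud = min(max((cov_a - background) / den, 0.0), 1.0)
    return RudRecord(gene.gene_id, cov_c, cov_a, rud)


def sample_rud(records: Sequence[RudRecord], label: str,
               background: float = 0.0) -> SampleRud:
    """Mean and SD of defined per-gene RUD scores."""
    defined = [r.rud for r in records if r.defined]
    n_undef = len(records) - len(defined)
    if not defined:
        raise ApaError("no gene has a defined RUD score")
    arr = np.asarray(defined)
    single = arr.size == 1
    sd = 0.0 if single else float(arr.std(ddof=1))
    return SampleRud(label, float(arr.mean()), sd, arr.size, n_undef,
                     background, single)


def compare_rud(groups: Dict[str, Sequence[SampleRud]]) -> Dict[str, object]:
    """Welch t tests on replicate mean RUDs for each pair of groups."""
    labels = sorted(groups)
    results = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            a = [s.mean_rud for s in groups[la]]
            b = [s.mean_rud for s in groups[lb]]
            if len(a) < 2 or len(b) < 2:
                raise ApaError(
                    f"contrast {la} vs {lb} needs >= 2 replicates per group"
                )
            results[f"{la}_vs_{lb}"] = welch_t_test(a, b)
    return results


def readthrough_index(
    gene: GeneModel,
    coverage: CoverageTrack,
    up_window: int = 500,
    down_window: int = 500,
    down_offset: int = 500,
) -> ReadThroughResult:
    """Downstream-over-upstream coverage ratio around the terminal PAS.

    The upstream window sits in the gene body ending at the proximal
    poly(A) site (covered by all isoforms); the downstream window starts
    ``down_offset`` past the terminal (distal) site.
    """
    term = gene.terminal_pas
    L = coverage._lengths[gene.chrom]
    if gene.strand == "+":
        up = (gene.pas_proximal - up_window, gene.pas_proximal)
        down = (term + down_offset, term + down_offset + down_window)
    else:
        up = (gene.pas_proximal, gene.pas_proximal + up_window)
        down = (term - down_offset - down_window, term - down_offset)
    if up[0] < 0 or down[0] < 0 or up[1] > L or down[1] > L:
        raise ApaError(f"gene {gene.gene_id}: windows outside chromosome")
    if up[0] < gene.tx_start or up[1] > gene.tx_end:
        raise ApaError(f"gene {gene.gene_id}: upstream window outside gene body")
    cov_up = coverage.mean(gene.chrom, *up)
    cov_down = coverage.mean(gene.chrom, *down)
    ratio = None if cov_up == 0 else cov_down / cov_up
    return ReadThroughResult(gene.gene_id, cov_up, cov_down, ratio)


def normalize_readthrough(
    results: Sequence[ReadThroughResult],
    reference: Sequence[ReadThroughResult],
) -> List[NormalizedReadThrough]:
    """Per-gene read-through fold relative to the reference condition
    (reference normalizes to 1.0)."""
    ref_by_gene = {r.gene_id: r for r in reference}
    out = []
    for res in results:
        ref = ref_by_gene.get(res.gene_id)
        fold = None
        ref_ratio = None if ref is None else ref.ratio
        if res.ratio is not None and ref_ratio:
            fold = res.ratio / ref_ratio
        out.append(NormalizedReadThrough(res.gene_id, res.ratio, ref_ratio,
                                         fold))
    return out
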