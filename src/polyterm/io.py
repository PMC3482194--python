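"""Readers and writers for the plain-text formats the pipeline exchanges.

Gene models travel as BED12 plus a poly(A)-site side table; repeats, truth
labels, mapping statuses and region calls as tab-delimited tables; reads
and the consensus library as FASTA; alignments as headerless 21-column PSL.
"""
from __future__ import annotations

import csv
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import AlignmentHit, MappingStatus
from .annotate import RegionCall
from .model import GeneModel, GenomeBundle, RepeatFeature, SimulationTruth


# --- FASTA -----------------------------------------------------------------

def write_fasta(records: Iterable[tuple], path) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> List[tuple]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


# --- gene models: BED12 + PAS side table -----------------------------------

def write_gene_models(genes: Sequence[GeneModel], bed_path, pas_path) -> None:
    with open(bed_path, "w") as bed:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            starts = ",".join(str(s - g.tx_start) for s, _ in g.exons) + ","
            thick = g.cds if g.cds else (g.tx_start, g.tx_start)
            bed.write("\t".join(str(x) for x in (
                g.chrom, g.tx_start, g.tx_end, g.gene_id, 0, g.strand,
                thick[0], thick[1], 0, len(g.exons), sizes, starts,
            )) + "\n")
    with open(pas_path, "w") as pas:
        pas.write("gene_id\tproximal_pas\tdistal_pas\tstrand\n")
        for g in genes:
            distal = "." if g.pas_distal is None else g.pas_distal
            pas.write(f"{g.gene_id}\t{g.pas_proximal}\t{distal}\t{g.strand}\n")


def read_gene_models(bed_path, pas_path) -> List[GeneModel]:
    pas: Dict[str, tuple] = {}
    with open(pas_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            distal = (None if row["distal_pas"] == "."
                      else int(row["distal_pas"]))
            pas[row["gene_id"]] = (int(row["proximal_pas"]), distal)
    genes = []
    with open(bed_path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            chrom, start = f[0], int(f[1])
            gene_id, strand = f[3], f[5]
            thick = (int(f[6]), int(f[7]))
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s)
                          for o, s in zip(starts, sizes))
            prox, distal = pas[gene_id]
            cds = None if thick[0] == thick[1] else thick
            genes.append(GeneModel(gene_id, chrom, strand, exons, prox,
                                   distal, cds))
    return genes


# --- repeats ---------------------------------------------------------------

def write_repeats(repeats: Sequence[RepeatFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\trepeat_class\telement_length\tname\n")
        for r in repeats:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}"
                     f"\t{r.repeat_class}\t{r.element_length}\t{r.name}\n")


def read_repeats(path) -> List[RepeatFeature]:
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(RepeatFeature(
                row["chrom"], int(row["start"]), int(row["end"]),
                row["strand"], row["repeat_class"], row.get("name", ""),
            ))
    return out


# --- truth -----------------------------------------------------------------

def write_truth(truths: Sequence[SimulationTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsource_kind\tsource_id\tisoform\treadthrough"
                 "\tchrom\tstart\tend\tstrand\tblocks\n")
        for t in truths:
            blocks = ("." if t.blocks is None else
                      ";".join(f"{s}-{e}" for s, e in t.blocks))
            fh.write("\t".join(str(x) for x in (
                t.read_id, t.source_kind, t.source_id, t.isoform,
                int(t.readthrough_flag),
                t.chrom or ".", "." if t.start is None else t.start,
                "." if t.end is None else t.end, t.strand, blocks,
            )) + "\n")


def read_truth(path) -> List[SimulationTruth]:
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            blocks = None
            if row["blocks"] != ".":
                blocks = tuple(
                    tuple(int(x) for x in part.split("-"))
                    for part in row["blocks"].split(";")
                )
            out.append(SimulationTruth(
                read_id=row["read_id"], source_kind=row["source_kind"],
                source_id=row["source_id"], isoform=row["isoform"],
                readthrough_flag=bool(int(row["readthrough"])),
                chrom=None if row["chrom"] == "." else row["chrom"],
                start=None if row["start"] == "." else int(row["start"]),
                end=None if row["end"] == "." else int(row["end"]),
                strand=row["strand"], blocks=blocks,
            ))
    return out


# --- PSL -------------------------------------------------------------------

def write_psl_lines(lines: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")


# --- mapping status / region calls -----------------------------------------

def write_mapping_status(statuses: Dict[str, MappingStatus], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstatus\tchrom\tstart\tend\tstrand\tscore\tgap\n")
        for read_id in sorted(statuses):
            st = statuses[read_id]
            if st.best_hit is None:
                fh.write(f"{read_id}\t{st.status}\t.\t.\t.\t.\t.\t.\n")
            else:
                h = st.best_hit
                gap = "." if st.score_gap is None else st.score_gap
                fh.write(f"{read_id}\t{st.status}\t{h.chrom}\t{h.start}"
                         f"\t{h.end}\t{h.strand}\t{h.score}\t{gap}\n")


def write_region_calls(calls: Dict[str, RegionCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcategory\tgene_id\n")
        for read_id in sorted(calls):
            c = calls[read_id]
            fh.write(f"{read_id}\t{c.category}\t{c.gene_id or '.'}\n")


# --- expression tables -----------------------------------------------------

def write_expression(df, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
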