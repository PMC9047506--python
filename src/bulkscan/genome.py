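"""Gene-model containers and FASTA/GFF3 round-trip helpers.

Coordinates on disk (GFF3, VCF) are 1-based inclusive; every conversion to
0-based string indexing happens inside this module so that downstream code
never does its own ``+/- 1`` arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = ("TAA", "TAG", "TGA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC ACGTN only)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GeneModelError(ValueError):
    """A gene model violates a structural constraint (e.g. CDS length % 3)."""


@dataclass
class GeneModel:
    """One protein-coding gene with a single transcript.

    ``exons`` and ``cds`` are lists of 1-based inclusive ``(start, end)``
    intervals in ascending genomic order regardless of strand; ``strand``
    determines reading direction.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.start > self.end:
            raise GeneModelError(f"{self.gene_id}: start > end")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            prev_end = 0
            for s, e in ivs:
                if s > e:
                    raise GeneModelError(f"{self.gene_id}: inverted {name} interval")
                if s <= prev_end:
                    raise GeneModelError(f"{self.gene_id}: {name} overlap or disorder")
                prev_end = e

    # -- interval queries ---------------------------------------------------

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def locate(self, pos: int) -> str | None:
        """Classify a position within this gene: 'cds', 'utr' or 'intron'.

        Returns ``None`` when the position lies outside the gene span.
        """
        if not self.contains(pos):
            return None
        if any(s <= pos <= e for s, e in self.cds):
            return "cds"
        if any(s <= pos <= e for s, e in self.exons):
            return "utr"
        return "intron"

    # -- CDS geometry -------------------------------------------------------

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def exon_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def spliced_cds(self, chrom_seq: str) -> str:
        """Spliced CDS in reading (strand) orientation, from the chromosome string."""
        asc = "".join(chrom_seq[s - 1 : e] for s, e in self.cds)
        return asc if self.strand == "+" else revcomp(asc)

    def cds_offset(self, pos: int) -> int:
        """0-based offset of a genomic position within the reading-oriented CDS."""
        off = 0
        asc_off = None
        for s, e in self.cds:
            if s <= pos <= e:
                asc_off = off + (pos - s)
                break
            off += e - s + 1
        if asc_off is None:
            raise GeneModelError(f"{self.gene_id}: position {pos} not in CDS")
        if self.strand == "+":
            return asc_off
        return self.cds_length - 1 - asc_off

    def protein(self, chrom_seq: str) -> str:
        """Translation of the spliced CDS with the standard genetic code."""
        cds = self.spliced_cds(chrom_seq)
        if len(cds) % 3:
            raise GeneModelError(f"{self.gene_id}: CDS length {len(cds)} not divisible by 3")
        return str(Seq(cds).translate())


# -- FASTA ------------------------------------------------------------------


def write_fasta(seqs: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# -- GFF3 -------------------------------------------------------------------


def write_gff3(genes: list[GeneModel], path: str) -> None:
    """Write gene/mRNA/exon/CDS features, 1-based inclusive, phase tracked."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tbulkscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tbulkscan\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tbulkscan\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            # phase: number of bases to skip to reach the next codon start
            cds_iv = g.cds if g.strand == "+" else list(reversed(g.cds))
            consumed = 0
            phases = {}
            for s, e in cds_iv:
                phases[(s, e)] = (3 - consumed % 3) % 3
                consumed += e - s + 1
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.chrom}\tbulkscan\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phases[(s, e)]}\t"
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


def read_gff3(path: str) -> list[GeneModel]:
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = sorted(
            (f.start, f.end) for f in db.children(g, featuretype="exon")
        )
        cds = sorted((f.start, f.end) for f in db.children(g, featuretype="CDS"))
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand,
                exons=exons,
                cds=cds,
            )
        )
    return genes
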