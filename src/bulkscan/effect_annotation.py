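"""Variant-effect classification against gene models.

A minimal point-substitution annotator: each biallelic SNP is located in
the gene structure and, when it hits a CDS, the alternate base is
substituted into the spliced, strand-oriented coding sequence and the
affected codon is retranslated with the standard genetic code. Categories:
intergenic, intronic, utr, synonymous, nonsynonymous, stopgain, stoploss.
Splice-site effects are not modelled — a site in an intron's first or last
2 bp is still 'intronic'.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .genome import GeneModel, revcomp
from .qtl_scan import CandidateRegion
from .variant_filtering import SnpSite

logger = logging.getLogger(__name__)

CONSEQUENTIAL = frozenset({"nonsynonymous", "stopgain", "stoploss"})
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class ReferenceMismatchError(ValueError):
    """The variant's REF allele disagrees with the reference sequence."""


@dataclass(frozen=True)
class VariantEffect:
    """Classification of one SNP against one (or no) gene model."""

    site: SnpSite
    gene_id: str | None
    category: str
    ref_aa: str | None = None
    alt_aa: str | None = None


class GeneIndex:
    """Sorted per-chromosome interval lookup over non-overlapping genes."""

    def __init__(self, genes: list[GeneModel]) -> None:
        self._by_chrom: dict[str, tuple[list[int], list[GeneModel]]] = {}
        for gene in sorted(genes, key=lambda g: (g.chrom, g.start)):
            starts, models = self._by_chrom.setdefault(gene.chrom, ([], []))
            if models and gene.start <= models[-1].end:
                raise ValueError(
                    f"overlapping genes {models[-1].gene_id} and {gene.gene_id}"
                )
            starts.append(gene.start)
            models.append(gene)

    def gene_at(self, chrom: str, pos: int) -> GeneModel | None:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, models = entry
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and models[i].contains(pos):
            return models[i]
        return None


def classify_variant_effect(
    site: SnpSite,
    genes: GeneIndex | list[GeneModel],
    references: dict[str, str],
) -> VariantEffect:
    """Classify one SNP; raises on REF mismatch or malformed CDS."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    seq = references.get(site.chrom)
    if seq is None:
        raise KeyError(f"no reference sequence for {site.chrom}")
    ref_base = seq[site.pos - 1]
    if ref_base != site.ref_allele:
        raise ReferenceMismatchError(
            f"{site.chrom}:{site.pos}: VCF REF {site.ref_allele} != reference {ref_base}"
        )
    gene = index.gene_at(site.chrom, site.pos)
    if gene is None:
        return VariantEffect(site, None, "intergenic")
    where = gene.locate(site.pos)
    if where in ("utr", "intron"):
        return VariantEffect(site, gene.gene_id, "utr" if where == "utr" else "intronic")
    return _classify_coding(site, gene, seq)


def _classify_coding(site: SnpSite, gene: GeneModel, seq: str) -> VariantEffect:
    cds = gene.spliced_cds(seq)
    if len(cds) % 3:
        raise ValueError(
            f"gene {gene.gene_id}: CDS length {len(cds)} not divisible by 3"
        )
    off = gene.cds_offset(site.pos)
    alt = site.alt_allele if gene.strand == "+" else _COMP[site.alt_allele]
    codon_i, within = divmod(off, 3)
    ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        category = "synonymous"
    elif alt_aa == "*":
        category = "stopgain"
    elif ref_aa == "*":
        category = "stoploss"
    else:
        category = "nonsynonymous"
    return VariantEffect(site, gene.gene_id, category, ref_aa, alt_aa)


def classify_variants(
    sites: list[SnpSite],
    genes: list[GeneModel] | GeneIndex,
    references: dict[str, str],
) -> list[VariantEffect]:
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [classify_variant_effect(s, index, references) for s in sites]


@dataclass
class AnnotatedGene:
    """A gene carrying consequential variants inside a candidate region."""

    gene_id: str
    chrom: str
    start: int
    end: int
    effects: list[VariantEffect] = field(default_factory=list)

    @property
    def worst_effect(self) -> str:
        order = ("stopgain", "stoploss", "nonsynonymous")
        for cat in order:
            if any(e.category == cat for e in self.effects):
                return cat
        return self.effects[0].category if self.effects else "none"


def genes_in_regions(
    effects: list[VariantEffect],
    regions: list[CandidateRegion],
    genes: list[GeneModel],
    keep: frozenset[str] = CONSEQUENTIAL,
) -> tuple[list[AnnotatedGene], int]:
    """Candidate genes: consequential in-region sites grouped by gene.

    Returns the genes (sorted by chromosome then position) and the number
    of surviving sites; synonymous and non-coding sites are dropped, as
    are sites outside every region.
    """
    by_id = {g.gene_id: g for g in genes}
    grouped: dict[str, AnnotatedGene] = {}
    n_surviving = 0
    for eff in effects:
        if eff.category not in keep or eff.gene_id is None:
            continue
        site = eff.site
        if not any(
            r.chrom == site.chrom and r.contains(site.pos) for r in regions
        ):
            continue
        n_surviving += 1
        if eff.gene_id not in grouped:
            model = by_id[eff.gene_id]
            grouped[eff.gene_id] = AnnotatedGene(
                eff.gene_id, model.chrom, model.start, model.end
            )
        grouped[eff.gene_id].effects.append(eff)
    ordered = sorted(grouped.values(), key=lambda g: (g.chrom, g.start))
    return ordered, n_surviving


def effects_to_frame(effects: list[VariantEffect]):
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [e.site.chrom for e in effects],
            "pos": [e.site.pos for e in effects],
            "ref": [e.site.ref_allele for e in effects],
            "alt": [e.site.alt_allele for e in effects],
            "gene_id": [e.gene_id or "." for e in effects],
            "category": [e.category for e in effects],
            "ref_aa": [e.ref_aa or "." for e in effects],
            "alt_aa": [e.alt_aa or "." for e in effects],
        }
    )
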