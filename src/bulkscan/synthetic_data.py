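"""Truth-known simulator of an F2 bulked-segregant experiment.

The generator emulates the study design every downstream stage assumes: two
fully homozygous parental lines (XAP1, AYP1) differing at Poisson-placed
SNPs; an F2 population of 200 plants segregating 3:1 for a single fully
penetrant recessive sterility locus; phenotype-selected bulks of 30 sterile
(BY) and 30 fertile (KY) plants sequenced to ~30x against ~10x parents; and
a negative-binomial count matrix for the four groups x 3 replicates with
differential expression concentrated near the causal locus.

Gametes are produced under the Haldane model: the crossover count per
chromosome is Poisson(map length in Morgans) with positions uniform, i.e.
no interference. All randomness flows from one integer seed, split
deterministically per stage, so each stage is independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .genome import GeneModel, revcomp

logger = logging.getLogger(__name__)

#: Sample order used in every on-disk artifact.
SAMPLES = ("XAP1", "AYP1", "BY", "KY")
#: Expression groups (4 groups x replicates).
GROUPS = ("XAP1", "AYP1", "KY", "BY")
#: Parent labels; chromosome-origin codes are indices into this tuple.
PARENTS = ("XAP1", "AYP1")

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# non-stop codons used to fill CDSs (start/stop handled separately)
_STOP = {"TAA", "TAG", "TGA"}
_CODING_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP
]

# engineered causal codons: for a SNP at codon offset k, the reference codon
# and the alternate base that converts it into a premature stop
_STOPGAIN_DESIGN = {
    0: ("CAA", "T"),  # Gln -> TAA
    1: ("TCA", "G"),  # Ser -> TGA
    2: ("TAC", "A"),  # Tyr -> TAA
}


class SizingError(ValueError):
    """A chromosome is too short to host the requested genes or SNPs."""


class BulkSizeError(ValueError):
    """The population lacks enough plants of a phenotype to fill a bulk."""


@dataclass
class SimConfig:
    """Study-design parameters of one simulated F2 bulking experiment.

    Defaults reproduce the experiment at desk scale: one 5 Mb chromosome
    carrying ~2,000 informative SNPs, an F2 of 200 plants, 30+30 extreme
    bulks, parents at ~10x and bulks at ~30x mean depth.
    """

    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000}
    )
    snp_density: float = 4e-4  # SNPs per bp between the two parents
    # desk-scale chromosomes keep a realistic whole-chromosome map length
    # (5 Mb x 20 cM/Mb = 100 cM) rather than a realistic per-Mb rate
    recomb_rate: float = 20.0  # cM per Mb
    causal_chrom: str | None = "chr1"
    causal_pos: int | None = 2_500_000
    causal_origin: str = "AYP1"  # parent donating the recessive sterile allele
    stopgain_at_causal: bool = True
    n_f2: int = 200
    n_bulk: int = 30
    parent_depth: float = 10.0
    bulk_depth: float = 30.0
    seq_error: float = 0.001  # per-read allele miscall probability
    phenotype_error: float = 0.0  # bulk-contamination (misclassification) rate
    genes_per_chrom: int = 40
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosome_lengths:
            raise ValueError("at least one chromosome is required")
        for name, length in self.chromosome_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name}: length must be positive")
        for attr in ("n_f2", "n_bulk", "genes_per_chrom"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be strictly positive")
        for attr in ("parent_depth", "bulk_depth", "recomb_rate"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")
        if self.snp_density < 0:
            raise ValueError("snp_density must be non-negative")
        if not 0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must lie in [0, 0.5)")
        if not 0 <= self.phenotype_error < 0.5:
            raise ValueError("phenotype_error must lie in [0, 0.5)")
        if self.causal_origin not in PARENTS:
            raise ValueError(f"causal_origin must be one of {PARENTS}")
        if (self.causal_pos is None) != (self.causal_chrom is None):
            raise ValueError("causal_chrom and causal_pos must be set together")
        if self.causal_pos is not None:
            if self.causal_chrom not in self.chromosome_lengths:
                raise ValueError(f"unknown causal chromosome {self.causal_chrom}")
            if not 1 <= self.causal_pos <= self.chromosome_lengths[self.causal_chrom]:
                raise ValueError("causal_pos outside its chromosome")

    def stage_rng(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage generator split from the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.rng_seed, spawn_key=(stage,))
        )


# ---------------------------------------------------------------------------
# genome, gene models, parental SNPs
# ---------------------------------------------------------------------------


def _fill_coding_sequence(ref: np.ndarray, gene: GeneModel, rng: np.random.Generator) -> None:
    """Overwrite the reference so the gene's spliced CDS is ATG..stop, no internal stop."""
    n_codons = gene.cds_length // 3
    body = rng.choice(len(_CODING_CODONS), size=max(n_codons - 2, 0))
    coding = "ATG" + "".join(_CODING_CODONS[i] for i in body) + _STOP_LIST[rng.integers(3)]
    asc = coding if gene.strand == "+" else revcomp(coding)
    i = 0
    for s, e in gene.cds:
        seg = asc[i : i + (e - s + 1)]
        ref[s - 1 : e] = np.frombuffer(seg.encode(), dtype="S1")
        i += e - s + 1


_STOP_LIST = ("TAA", "TAG", "TGA")


def _build_gene(
    gene_id: str,
    chrom: str,
    lo: int,
    hi: int,
    rng: np.random.Generator,
    strand: str | None = None,
    anchor_pos: int | None = None,
) -> GeneModel:
    """Lay out one gene inside [lo, hi] (1-based inclusive bounds).

    When ``anchor_pos`` is given the gene is positioned so that the anchor
    falls inside the first CDS segment, at least one full codon away from
    the start and stop codons.
    """
    span = hi - lo + 1
    if span < 400:
        raise SizingError(f"{chrom}: slot of {span} bp too short for a gene")
    utr5 = int(rng.integers(20, 80))
    utr3 = int(rng.integers(20, 80))
    has_intron = bool(rng.integers(2))
    intron_len = int(rng.integers(60, 240)) if has_intron else 0
    budget = span - utr5 - utr3 - intron_len - 20
    n_codons = int(min(rng.integers(60, 220), budget // 3))
    if n_codons < 12:
        raise SizingError(f"{chrom}: slot of {span} bp too short for a CDS")
    cds_len = 3 * n_codons
    if strand is None:
        strand = "+" if rng.integers(2) else "-"

    # split CDS around the intron (ascending genomic order)
    if has_intron:
        cut = int(rng.integers(9, cds_len - 9))
        cut -= cut % 3  # keep the anchor arithmetic simple: cut on codon boundary
        cut = max(cut, 3)
    else:
        cut = cds_len

    total = utr5 + cds_len + intron_len + utr3
    if anchor_pos is None:
        gstart = lo + int(rng.integers(0, max(span - total, 1)))
    else:
        # place anchor inside the first CDS segment, away from start/stop codons
        off = 3 + int(rng.integers(0, max(cut - 6, 1)))
        gstart = anchor_pos - (utr5 + off)
        if gstart < lo or gstart + total - 1 > hi:
            raise SizingError(
                f"{chrom}: anchor {anchor_pos} too close to a chromosome end"
            )
    gend = gstart + total - 1

    # ascending layout: [utr_left][cds1][intron][cds2][utr_right]
    left = utr5 if strand == "+" else utr3
    cds1_s = gstart + left
    cds1_e = cds1_s + cut - 1
    if has_intron:
        cds2_s = cds1_e + intron_len + 1
        cds2_e = cds2_s + (cds_len - cut) - 1
        cds = [(cds1_s, cds1_e), (cds2_s, cds2_e)]
        exons = [(gstart, cds1_e), (cds2_s, gend)]
    else:
        cds = [(cds1_s, cds1_e)]
        exons = [(gstart, gend)]
    # the reading-strand first codon must sit at the reading 5' end; for '-'
    # genes the ascending layout above puts the 3' UTR first, which is what
    # revcomp-based filling expects, so nothing else to do here.
    return GeneModel(gene_id, chrom, gstart, gend, strand, exons, cds)


def simulate_genome_and_genes(
    config: SimConfig,
) -> tuple[dict[str, str], list[GeneModel], pd.DataFrame]:
    """Simulate reference sequences, gene models and parental SNPs.

    Returns ``(references, genes, snps)`` where ``snps`` is a DataFrame with
    columns ``chrom, pos, ref, alt, alt_parent`` — parents are homozygous
    for opposite alleles at every SNP, ``alt_parent`` naming the parent that
    carries the non-reference allele. When a causal locus is configured a
    SNP is forced at ``causal_pos`` (by default engineered as a stop-gain in
    the gene hosting it), with ``alt_parent = causal_origin``.
    """
    rng = config.stage_rng(0)
    refs_arr: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    snp_rows: list[tuple[str, int, str, str, str]] = []
    causal_gene: GeneModel | None = None

    for chrom, length in config.chromosome_lengths.items():
        ref = rng.choice(_BASES, size=length)
        slot = length // config.genes_per_chrom
        if slot < 400:
            raise SizingError(
                f"{chrom}: {length} bp cannot host {config.genes_per_chrom} genes"
            )
        causal_here = (
            config.causal_pos is not None and chrom == config.causal_chrom
        )
        # the causal-locus gene is placed first, anchored on causal_pos, so the
        # regular gene grid can simply skip any slot it overlaps
        if causal_here:
            lo = max(1, config.causal_pos - 2500)
            hi = min(length, config.causal_pos + 2500)
            causal_gene = _build_gene(
                f"{chrom}.gC", chrom, lo, hi, rng, strand="+",
                anchor_pos=config.causal_pos,
            )
            genes.append(causal_gene)
            _fill_coding_sequence(ref, causal_gene, rng)
        for i in range(config.genes_per_chrom):
            lo, hi = i * slot + 1, min((i + 1) * slot, length)
            if causal_here and not (hi < causal_gene.start or lo > causal_gene.end):
                continue
            gene = _build_gene(f"{chrom}.g{i + 1:04d}", chrom, lo, hi, rng)
            genes.append(gene)
            _fill_coding_sequence(ref, gene, rng)

        # engineered stop-gain at the causal position
        excluded: set[int] = set()
        if causal_here:
            pos = config.causal_pos
            if config.stopgain_at_causal and causal_gene is not None:
                off = causal_gene.cds_offset(pos)
                within = off % 3
                codon_start = pos - within  # causal gene is '+' by construction
                codon, alt = _STOPGAIN_DESIGN[within]
                ref[codon_start - 1 : codon_start + 2] = np.frombuffer(
                    codon.encode(), dtype="S1"
                )
                ref_base = codon[within]
                excluded = {codon_start, codon_start + 1, codon_start + 2}
            else:
                ref_base = ref[pos - 1].decode()
                alt = _other_base(ref_base, rng)
                excluded = {pos}
            snp_rows.append((chrom, pos, ref_base, alt, config.causal_origin))

        n_snps = rng.poisson(length * config.snp_density)
        if n_snps > length // 2:
            raise SizingError(f"{chrom}: snp_density too high for {length} bp")
        positions = rng.choice(length, size=n_snps, replace=False) + 1
        positions = np.sort(positions)
        for pos in positions:
            if int(pos) in excluded:
                continue
            ref_base = ref[pos - 1].decode()
            alt = _other_base(ref_base, rng)
            snp_rows.append((chrom, int(pos), ref_base, alt, PARENTS[rng.integers(2)]))
        refs_arr[chrom] = ref

    refs = {c: a.tobytes().decode() for c, a in refs_arr.items()}
    snps = pd.DataFrame(
        snp_rows, columns=["chrom", "pos", "ref", "alt", "alt_parent"]
    ).sort_values(["chrom", "pos"], ignore_index=True)
    logger.info("simulated %d genes and %d parental SNPs", len(genes), len(snps))
    return refs, genes, snps


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(3)]


# ---------------------------------------------------------------------------
# F2 population
# ---------------------------------------------------------------------------


@dataclass
class ChromosomeCopy:
    """One recombinant chromosome: breakpoints plus parental-origin labels.

    ``origins`` has one more element than ``breakpoints``; segment ``i``
    spans ``(breakpoints[i-1], breakpoints[i]]`` and carries origin code
    ``origins[i]`` (an index into :data:`PARENTS`).
    """

    breakpoints: np.ndarray
    origins: np.ndarray

    def origin_at(self, pos: int) -> int:
        return int(self.origins[np.searchsorted(self.breakpoints, pos)])

    def origins_at(self, positions: np.ndarray) -> np.ndarray:
        return self.origins[np.searchsorted(self.breakpoints, positions)]


@dataclass
class F2Individual:
    """An F2 plant: two recombinant copies per chromosome plus its phenotype."""

    copies: dict[str, tuple[ChromosomeCopy, ChromosomeCopy]]
    phenotype: str  # 'fertile' | 'sterile'

    def dosage(self, chrom: str, pos: int, origin_code: int) -> int:
        a, b = self.copies[chrom]
        return int(a.origin_at(pos) == origin_code) + int(b.origin_at(pos) == origin_code)


def _gamete(length: int, recomb_rate: float, rng: np.random.Generator) -> ChromosomeCopy:
    morgans = length / 1e6 * recomb_rate / 100.0
    k = rng.poisson(morgans)
    bps = np.unique(rng.uniform(0, length, size=k)) if k else np.empty(0)
    start = int(rng.integers(2))
    origins = (start + np.arange(len(bps) + 1)) % 2
    return ChromosomeCopy(bps, origins)


def simulate_f2_population(
    config: SimConfig, snps: pd.DataFrame
) -> list[F2Individual]:
    """Simulate ``n_f2`` plants from two independent recombinant gametes each.

    Phenotype is fully penetrant recessive: sterile iff both copies carry
    the ``causal_origin`` allele at the causal position (optionally flipped
    at rate ``phenotype_error``). Without a causal locus, phenotypes are
    drawn independently with P(sterile) = 1/4, which makes the bulks random
    subsets of the population — the no-QTL null.
    """
    if config.causal_pos is not None:
        at_causal = snps[
            (snps["chrom"] == config.causal_chrom) & (snps["pos"] == config.causal_pos)
        ]
        if at_causal.empty:
            raise ValueError("no SNP at the configured causal position")
    rng = config.stage_rng(1)
    causal_code = PARENTS.index(config.causal_origin)
    population: list[F2Individual] = []
    for _ in range(config.n_f2):
        copies = {
            chrom: (
                _gamete(length, config.recomb_rate, rng),
                _gamete(length, config.recomb_rate, rng),
            )
            for chrom, length in config.chromosome_lengths.items()
        }
        if config.causal_pos is None:
            sterile = rng.random() < 0.25
        else:
            a, b = copies[config.causal_chrom]
            sterile = (
                a.origin_at(config.causal_pos) == causal_code
                and b.origin_at(config.causal_pos) == causal_code
            )
        if config.phenotype_error and rng.random() < config.phenotype_error:
            sterile = not sterile
        population.append(
            F2Individual(copies, "sterile" if sterile else "fertile")
        )
    return population


# ---------------------------------------------------------------------------
# bulk selection and sequencing
# ---------------------------------------------------------------------------


def select_and_sequence_bulks(
    population: list[F2Individual], config: SimConfig, snps: pd.DataFrame
) -> pd.DataFrame:
    """Select 30+30 extreme plants and draw allelic depths for all samples.

    At each SNP every sample's total depth is Poisson (``bulk_depth`` for
    BY/KY, ``parent_depth`` for the parents) and its alt-allele read count
    is Binomial(depth, f') where f is the sample's true alt-allele frequency
    (chromosome-level for bulks, 0 or 1 for the homozygous parents) and
    f' = f(1-e) + (1-f)e applies the per-read miscall rate e.

    Returns a DataFrame with columns ``chrom, pos, ref, alt`` and
    ``{sample}_ref / {sample}_alt`` depth pairs for XAP1, AYP1, BY, KY.
    """
    rng = config.stage_rng(2)
    sterile = [ind for ind in population if ind.phenotype == "sterile"]
    fertile = [ind for ind in population if ind.phenotype == "fertile"]
    for name, group in (("sterile", sterile), ("fertile", fertile)):
        if len(group) < config.n_bulk:
            raise BulkSizeError(
                f"only {len(group)} {name} plants for a bulk of {config.n_bulk}; "
                f"resample the F2 population or lower n_bulk"
            )
    by = [sterile[i] for i in rng.choice(len(sterile), config.n_bulk, replace=False)]
    ky = [fertile[i] for i in rng.choice(len(fertile), config.n_bulk, replace=False)]

    e = config.seq_error
    n_chromcopies = 2 * config.n_bulk
    out = snps[["chrom", "pos", "ref", "alt"]].copy()
    alt_codes = snps["alt_parent"].map(PARENTS.index).to_numpy()

    # true bulk alt-allele frequencies, chromosome level
    freq = {"BY": np.zeros(len(snps)), "KY": np.zeros(len(snps))}
    for bulk_name, plants in (("BY", by), ("KY", ky)):
        counts = np.zeros(len(snps))
        for chrom, idx in snps.groupby("chrom", sort=False).indices.items():
            positions = snps["pos"].to_numpy()[idx]
            codes = alt_codes[idx]
            acc = np.zeros(len(idx))
            for plant in plants:
                for copy in plant.copies[chrom]:
                    acc += copy.origins_at(positions) == codes
            counts[idx] = acc
        freq[bulk_name] = counts / n_chromcopies

    for sample in SAMPLES:
        if sample in PARENTS:
            f = (alt_codes == PARENTS.index(sample)).astype(float)
            depth = rng.poisson(config.parent_depth, size=len(snps))
        else:
            f = freq[sample]
            depth = rng.poisson(config.bulk_depth, size=len(snps))
        p = f * (1 - e) + (1 - f) * e
        alt_reads = rng.binomial(depth, p)
        out[f"{sample}_ref"] = depth - alt_reads
        out[f"{sample}_alt"] = alt_reads
    return out


def write_vcf(
    table: pd.DataFrame, path: str, chromosome_lengths: dict[str, int]
) -> None:
    """Serialize an allelic-depth table as VCF v4.2 with per-sample GT and AD."""
    header = pysam.VariantHeader()
    for chrom, length in chromosome_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref,alt)")
    for sample in SAMPLES:
        header.add_sample(sample)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for row in table.itertuples(index=False):
            rec = vcf.new_record(
                contig=row.chrom, start=row.pos - 1, alleles=(row.ref, row.alt)
            )
            for sample in SAMPLES:
                r = int(getattr(row, f"{sample}_ref"))
                a = int(getattr(row, f"{sample}_alt"))
                rec.samples[sample]["AD"] = (r, a)
                rec.samples[sample]["GT"] = _genotype_call(r, a)
            vcf.write(rec)


def _genotype_call(ref_reads: int, alt_reads: int) -> tuple[int | None, int | None]:
    depth = ref_reads + alt_reads
    if depth == 0:
        return (None, None)
    frac = alt_reads / depth
    if frac < 0.25:
        return (0, 0)
    if frac > 0.75:
        return (1, 1)
    return (0, 1)


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSpec:
    """Negative-binomial design of the 4-group x 3-replicate count matrix.

    ``de_lfc`` maps gene id -> signed log2 fold change applied to the BY
    group only; all other groups share the baseline mean. Counts for gene g
    in library j are NB with mean ``baseline * 2**lfc * size_factor_j`` and
    gene-level dispersion alpha (variance mu + alpha mu^2).
    """

    gene_ids: list[str]
    baseline_means: np.ndarray
    dispersions: np.ndarray
    de_lfc: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 3
    library_size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        self.baseline_means = np.asarray(self.baseline_means, dtype=float)
        self.dispersions = np.asarray(self.dispersions, dtype=float)
        if len(self.baseline_means) != n or len(self.dispersions) != n:
            raise ValueError("baseline_means/dispersions must match gene_ids")
        if np.any(self.dispersions < 0) or np.any(self.baseline_means < 0):
            raise ValueError("means and dispersions must be non-negative")
        unknown = set(self.de_lfc) - set(self.gene_ids)
        if unknown:
            raise ValueError(f"DE genes not in gene set: {sorted(unknown)[:5]}")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per group")

    @property
    def library_names(self) -> list[str]:
        return [f"{g}_{r + 1}" for g in GROUPS for r in range(self.n_replicates)]

    @classmethod
    def random(
        cls,
        gene_ids: list[str],
        rng: np.random.Generator,
        de_lfc: dict[str, float] | None = None,
        mean_log: float = 4.5,
        mean_sd: float = 1.2,
        dispersion: float = 0.1,
    ) -> "ExpressionSpec":
        """Lognormal baseline means with a common dispersion."""
        means = rng.lognormal(mean_log, mean_sd, size=len(gene_ids))
        disps = np.full(len(gene_ids), dispersion)
        return cls(list(gene_ids), means, disps, de_lfc or {})


def expression_spec_for_truth(
    genes: list[GeneModel],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    causal_lfc: float = -2.5,
    n_linked_de: int = 6,
    n_background_de: int = 20,
    linked_window: int = 1_000_000,
) -> ExpressionSpec:
    """Expression design with DE concentrated near the causal locus.

    The gene hosting the causal SNP is strongly down-regulated in the
    sterile bulk (``causal_lfc``); a handful of genes within
    ``linked_window`` of the locus and random background genes receive
    moderate signed fold changes.
    """
    if rng is None:
        rng = config.stage_rng(3)
    gene_ids = [g.gene_id for g in genes]
    de: dict[str, float] = {}
    if config.causal_pos is not None:
        causal = [
            g
            for g in genes
            if g.chrom == config.causal_chrom and g.contains(config.causal_pos)
        ]
        if causal:
            de[causal[0].gene_id] = causal_lfc
        linked = [
            g.gene_id
            for g in genes
            if g.chrom == config.causal_chrom
            and abs((g.start + g.end) // 2 - config.causal_pos) <= linked_window
            and g.gene_id not in de
        ]
        for gid in rng.permutation(linked)[:n_linked_de]:
            de[gid] = float(rng.choice([-1, 1])) * float(rng.uniform(1.5, 3.0))
    pool = [g for g in gene_ids if g not in de]
    for gid in rng.permutation(pool)[:n_background_de]:
        de[gid] = float(rng.choice([-1, 1])) * float(rng.uniform(1.5, 3.0))
    return ExpressionSpec.random(gene_ids, rng, de_lfc=de)


def simulate_expression_counts(
    spec: ExpressionSpec, rng: np.random.Generator | int
) -> pd.DataFrame:
    """Draw the genes x 12-library NB count matrix defined by ``spec``."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_genes = len(spec.gene_ids)
    libs = spec.library_names
    sf = (
        spec.library_size_factors
        if spec.library_size_factors is not None
        else np.ones(len(libs))
    )
    if len(sf) != len(libs):
        raise ValueError("library_size_factors must have one entry per library")
    lfc = np.zeros(n_genes)
    for i, gid in enumerate(spec.gene_ids):
        if gid in spec.de_lfc:
            lfc[i] = spec.de_lfc[gid]
    counts = np.zeros((n_genes, len(libs)), dtype=np.int64)
    for j, lib in enumerate(libs):
        group = lib.rsplit("_", 1)[0]
        mu = spec.baseline_means * sf[j]
        if group == "BY":
            mu = mu * np.exp2(lfc)
        counts[:, j] = _nb_draw(mu, spec.dispersions, rng)
    return pd.DataFrame(counts, index=pd.Index(spec.gene_ids, name="gene_id"), columns=libs)


def _nb_draw(
    mu: np.ndarray, alpha: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """NB(mu, variance mu + alpha mu^2) draws; alpha == 0 degrades to Poisson."""
    out = np.empty(len(mu), dtype=np.int64)
    poisson = alpha <= 0
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        size = 1.0 / alpha[nb]
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def simulate_term_map(
    gene_ids: list[str],
    rng: np.random.Generator,
    n_terms: int = 20,
    min_size: int = 5,
    max_size: int = 40,
) -> dict[str, set[str]]:
    """Random flat term -> gene-set annotation over the simulated genes."""
    terms: dict[str, set[str]] = {}
    for t in range(n_terms):
        size = int(rng.integers(min_size, max_size + 1))
        members = rng.choice(len(gene_ids), size=min(size, len(gene_ids)), replace=False)
        terms[f"TERM:{t + 1:04d}"] = {gene_ids[i] for i in members}
    return terms


# ---------------------------------------------------------------------------
# truth serialization
# ---------------------------------------------------------------------------


def write_truth(
    path: str, config: SimConfig, spec: ExpressionSpec | None = None
) -> None:
    """Write the simulation truth (causal locus, DE genes) as a flat TSV."""
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"causal_chrom\t{config.causal_chrom}\n")
        fh.write(f"causal_pos\t{config.causal_pos}\n")
        fh.write(f"causal_origin\t{config.causal_origin}\n")
        if spec is not None:
            for gid in sorted(spec.de_lfc):
                fh.write(f"de_gene\t{gid}:{spec.de_lfc[gid]:+.3f}\n")


def write_counts_tsv(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t")


def read_counts_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
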