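"""End-to-end orchestration: simulate -> filter -> scan -> annotate -> DE ->
enrich -> integrate, with every intermediate written to an output directory.

Each stage is also runnable standalone on files (see the CLI); the pipeline
is deterministic for a fixed seed — running it twice into two directories
produces byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (
    de_analysis,
    effect_annotation,
    enrichment,
    genome,
    integration,
    qtl_scan,
    synthetic_data,
    variant_filtering,
)
from .synthetic_data import GROUPS, SimConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the pipeline computed, for programmatic inspection."""

    config: SimConfig
    outdir: Path
    segregation: integration.SegregationTest
    filter_result: variant_filtering.FilterResult
    scan_results: list[qtl_scan.ScanResult]
    regions: list[qtl_scan.CandidateRegion]
    annotated_genes: list[effect_annotation.AnnotatedGene]
    de: de_analysis.DEIntersection
    enrichment_table: pd.DataFrame
    candidates: list[integration.CandidateGene]
    truth: dict = field(default_factory=dict)


def load_config(path: str) -> SimConfig:
    """Read a SimConfig from a flat YAML mapping of field names to values."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimConfig(**data)


def run_pipeline(
    config: SimConfig,
    outdir: str | Path,
    high_parent: str = "XAP1",
    min_depth: int = 7,
    low_index: float = 0.3,
    n_reps: int = 1000,
    level: float = 0.95,
    merge_gap: int = 1_000_000,
    min_sites: int = 3,
    alpha: float = 0.05,
    lfc: float = 1.0,
    make_plot: bool = False,
) -> PipelineResult:
    """Run the whole conjunctive analysis on one simulated experiment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # -- stage 1: synthetic experiment -------------------------------------
    refs, genes, snps = synthetic_data.simulate_genome_and_genes(config)
    genome.write_fasta(refs, str(outdir / "reference.fasta"))
    genome.write_gff3(genes, str(outdir / "genes.gff3"))
    population = synthetic_data.simulate_f2_population(config, snps)
    n_sterile = sum(ind.phenotype == "sterile" for ind in population)
    n_fertile = len(population) - n_sterile
    table = synthetic_data.select_and_sequence_bulks(population, config, snps)
    vcf_path = outdir / "variants.vcf"
    synthetic_data.write_vcf(table, str(vcf_path), config.chromosome_lengths)

    expr_rng = config.stage_rng(3)
    spec = synthetic_data.expression_spec_for_truth(genes, config, rng=expr_rng)
    counts = synthetic_data.simulate_expression_counts(spec, expr_rng)
    synthetic_data.write_counts_tsv(counts, str(outdir / "counts.tsv"))
    synthetic_data.write_truth(str(outdir / "truth.tsv"), config, spec)
    logger.info(
        "stage simulate: %d SNPs, %d genes, %d/%d fertile/sterile",
        len(snps), len(genes), n_fertile, n_sterile,
    )

    # -- stage 2: segregation test ------------------------------------------
    segregation = integration.chi_square_segregation(n_fertile, n_sterile)

    # -- stage 3: SNP index + filters ---------------------------------------
    parsed = variant_filtering.read_allelic_depths(str(vcf_path))
    records = [
        variant_filtering.compute_snp_index(site, high_parent)
        for site in parsed.sites
    ]
    filt = variant_filtering.apply_filters(
        records, min_depth=min_depth, low_index=low_index
    )
    variant_filtering.write_filter_outputs(
        filt, str(outdir / "filtered_sites.tsv"), str(outdir / "filter_tally.tsv")
    )
    logger.info(
        "stage filter: %d in, %d retained", len(records), len(filt.retained)
    )

    # -- stage 4: delta scan + regions --------------------------------------
    scan = qtl_scan.scan_records(
        filt.retained,
        n_bulk=config.n_bulk,
        n_reps=n_reps,
        level=level,
        seed=config.rng_seed,
    )
    regions = qtl_scan.call_candidates_and_merge(
        scan, merge_gap=merge_gap, min_sites=min_sites
    )
    qtl_scan.write_scan_outputs(
        scan, regions, str(outdir / "scan.tsv"), str(outdir / "regions.bed")
    )
    if make_plot:
        qtl_scan.plot_scan(scan, regions, str(outdir / "scan.png"))
    logger.info(
        "stage scan: %d candidate sites, %d regions",
        sum(r.is_candidate for r in scan), len(regions),
    )

    # -- stage 5: effect annotation -----------------------------------------
    candidate_sites = [r.record.site for r in scan if r.is_candidate]
    effects = effect_annotation.classify_variants(candidate_sites, genes, refs)
    effect_annotation.effects_to_frame(effects).to_csv(
        outdir / "effects.tsv", sep="\t", index=False
    )
    annotated, n_kept_sites = effect_annotation.genes_in_regions(
        effects, regions, genes
    )
    logger.info(
        "stage annotate: %d consequential in-region sites in %d genes",
        n_kept_sites, len(annotated),
    )

    # -- stage 6: differential expression -----------------------------------
    factors = de_analysis.size_factors(counts)
    contrasts = de_analysis.run_all_contrasts(counts, factors)
    de = de_analysis.call_and_intersect_degs(contrasts, alpha=alpha, lfc=lfc)
    for name, tab in de.per_contrast.items():
        tab.to_csv(outdir / f"de_{name}.tsv", sep="\t")
    lengths = pd.Series({g.gene_id: g.exon_length for g in genes}, name="length")
    fpkm = de_analysis.compute_fpkm(counts, lengths)
    expr_summary = de_analysis.group_means(fpkm)
    with open(outdir / "shared_degs.tsv", "w") as fh:
        fh.write("gene_id\tdirection\n")
        for gid in sorted(de.shared_up):
            fh.write(f"{gid}\tup\n")
        for gid in sorted(de.shared_down):
            fh.write(f"{gid}\tdown\n")
    logger.info(
        "stage de: %d shared up, %d shared down",
        len(de.shared_up), len(de.shared_down),
    )

    # -- stage 7: enrichment -------------------------------------------------
    term_rng = config.stage_rng(4)
    gene_ids = [g.gene_id for g in genes]
    terms = synthetic_data.simulate_term_map(gene_ids, term_rng)
    term_map = enrichment.TermMap(terms, set(gene_ids))
    shared = de.shared_up | de.shared_down
    if shared:
        enr = enrichment.hypergeometric_enrichment(shared, term_map, alpha=alpha)
    else:
        enr = pd.DataFrame(
            columns=["term", "description", "k", "K", "n", "N", "p", "padj", "significant"]
        )
    enrichment.write_enrichment_tsv(enr, str(outdir / "enrichment.tsv"))

    # -- stage 8: integration + report ---------------------------------------
    candidates = integration.integrate_bsa_bsr(
        annotated, de.shared_up, de.shared_down, expr_summary
    )
    report = integration.candidates_to_frame(candidates)
    report.to_csv(outdir / "candidate_genes.tsv", sep="\t", index=False)
    _write_text_report(
        outdir / "report.txt",
        config, segregation, filt, scan, regions, annotated, de, candidates,
    )
    truth = {
        "causal_chrom": config.causal_chrom,
        "causal_pos": config.causal_pos,
        "causal_origin": config.causal_origin,
        "de_lfc": dict(spec.de_lfc),
    }
    return PipelineResult(
        config=config,
        outdir=outdir,
        segregation=segregation,
        filter_result=filt,
        scan_results=scan,
        regions=regions,
        annotated_genes=annotated,
        de=de,
        enrichment_table=enr,
        candidates=candidates,
        truth=truth,
    )


def run_null_calibration(
    seed: int,
    n_runs: int = 10,
    n_chroms: int = 9,
    chrom_length: int = 5_000_000,
    n_sites: int = 2000,
    n_reps: int = 1000,
    level: float = 0.95,
) -> pd.DataFrame:
    """Empirical coverage of the null band on no-QTL genomes.

    Each run simulates an F2 experiment with no causal locus (phenotypes
    random, bulks are random subsets) on ``n_chroms`` chromosomes carrying
    ~``n_sites`` SNPs in total, scans every retained site against the
    simulated null band, and records the fraction of sites falling inside.
    Nine chromosomes mirror the foxtail millet karyotype and, more
    importantly, decorrelate the chromosome-level allele-frequency drift
    that dominates run-to-run variation on a single chromosome.

    Returns one row per run with columns ``n_sites`` and ``fraction_inside``.
    """
    density = n_sites / (n_chroms * chrom_length)
    rows = []
    for run in range(n_runs):
        cfg = SimConfig(
            chromosome_lengths={f"chr{i + 1}": chrom_length for i in range(n_chroms)},
            snp_density=density,
            causal_chrom=None,
            causal_pos=None,
            seq_error=0.0,
            genes_per_chrom=10,
            rng_seed=(seed * 1009 + run) % (2**31),
        )
        _, _, snps = synthetic_data.simulate_genome_and_genes(cfg)
        population = synthetic_data.simulate_f2_population(cfg, snps)
        table = synthetic_data.select_and_sequence_bulks(population, cfg, snps)
        records = [
            variant_filtering.compute_snp_index(site, "XAP1")
            for site in variant_filtering.sites_from_frame(table)
        ]
        filt = variant_filtering.apply_filters(records)
        scan = qtl_scan.scan_records(
            filt.retained,
            n_bulk=cfg.n_bulk,
            n_reps=n_reps,
            level=level,
            seed=cfg.rng_seed,
        )
        n = len(scan)
        inside = sum(not r.is_candidate for r in scan)
        rows.append({"n_sites": n, "fraction_inside": inside / n})
    return pd.DataFrame(rows)


def run_recovery_experiments(
    seed: int,
    n_experiments: int = 50,
    merge_gap: int = 1_000_000,
    min_sites: int = 3,
) -> pd.DataFrame:
    """Causal-locus recovery over repeated default-scale experiments.

    Each experiment simulates the default design (one 5 Mb chromosome,
    ~2,000 SNPs, 30+30 bulks, 30x depth, recessive causal locus at the
    midpoint), runs filter + scan + merge, and records whether a called
    region contains the causal position and the delta(SNP index) observed
    at the causal SNP itself.
    """
    rows = []
    for run in range(n_experiments):
        cfg = SimConfig(rng_seed=(seed * 2003 + run) % (2**31), seq_error=0.0)
        _, _, snps = synthetic_data.simulate_genome_and_genes(cfg)
        population = synthetic_data.simulate_f2_population(cfg, snps)
        table = synthetic_data.select_and_sequence_bulks(population, cfg, snps)
        records = [
            variant_filtering.compute_snp_index(site, cfg.causal_origin)
            for site in variant_filtering.sites_from_frame(table)
        ]
        filt = variant_filtering.apply_filters(records)
        scan = qtl_scan.scan_records(
            filt.retained, n_bulk=cfg.n_bulk, seed=cfg.rng_seed
        )
        regions = qtl_scan.call_candidates_and_merge(
            scan, merge_gap=merge_gap, min_sites=min_sites
        )
        recovered = any(
            reg.chrom == cfg.causal_chrom and reg.contains(cfg.causal_pos)
            for reg in regions
        )
        causal_delta = next(
            (
                r.delta
                for r in scan
                if r.chrom == cfg.causal_chrom and r.pos == cfg.causal_pos
            ),
            float("nan"),
        )
        rows.append(
            {
                "recovered": recovered,
                "causal_delta": causal_delta,
                "n_regions": len(regions),
            }
        )
    return pd.DataFrame(rows)


def _write_text_report(
    path: Path,
    config: SimConfig,
    seg: integration.SegregationTest,
    filt: variant_filtering.FilterResult,
    scan: list[qtl_scan.ScanResult],
    regions: list[qtl_scan.CandidateRegion],
    annotated: list[effect_annotation.AnnotatedGene],
    de: de_analysis.DEIntersection,
    candidates: list[integration.CandidateGene],
) -> None:
    n_cand_sites = sum(r.is_candidate for r in scan)
    lines = [
        "bulkscan conjunctive BSA/BSR report",
        "===================================",
        "",
        f"seed: {config.rng_seed}",
        "",
        "F2 segregation",
        f"  fertile {seg.n_fertile} : sterile {seg.n_sterile} against "
        f"{seg.ratio[0]}:{seg.ratio[1]}",
        f"  chi2 = {seg.chi2:.4f} (critical {seg.critical:.3f} at alpha "
        f"{seg.alpha}); consistent: {seg.consistent}",
        "",
        "BSA scan",
        f"  sites in: {filt.n_input}; retained after filters: {len(filt.retained)}",
        f"  rejections: " + ", ".join(f"{k}={v}" for k, v in filt.tally.items()),
        f"  candidate sites outside the 95% band: {n_cand_sites}",
        f"  candidate regions: {len(regions)}",
    ]
    for i, reg in enumerate(regions, 1):
        lines.append(
            f"    region{i}: {reg.chrom}:{reg.start:,}-{reg.end:,} ({reg.n_sites} sites)"
        )
    lines += [
        f"  genes with consequential in-region variants: {len(annotated)}",
        "",
        "BSR differential expression",
    ]
    for row in de.counts.itertuples(index=False):
        lines.append(f"  {row.contrast}: {row.up} up, {row.down} down")
    lines += [
        f"  shared up: {len(de.shared_up)}; shared down: {len(de.shared_down)}",
        "",
        f"Final candidate genes (variant + shared DEG): {len(candidates)}",
    ]
    for c in candidates:
        expr = " ".join(f"{g}={c.expression.get(g, float('nan')):.2f}" for g in GROUPS)
        lines.append(
            f"  {c.gene_id} {c.chrom}:{c.start:,}-{c.end:,} "
            f"{c.worst_effect} {c.direction} [{expr}]"
        )
    lines.append("")
    path.write_text("\n".join(lines))
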