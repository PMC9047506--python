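"""Shared fixtures: small simulated experiments and site builders."""

from __future__ import annotations

from types import SimpleNamespace

import pytest

from bulkscan.synthetic_data import (
    SimConfig,
    select_and_sequence_bulks,
    simulate_f2_population,
    simulate_genome_and_genes,
)
from bulkscan.variant_filtering import SnpSite, sites_from_frame


@pytest.fixture(scope="session")
def default_experiment():
    """One default-scale experiment (5 Mb, ~2,000 SNPs, 30+30 bulks, 30x)."""
    cfg = SimConfig(rng_seed=11, seq_error=0.0)
    refs, genes, snps = simulate_genome_and_genes(cfg)
    population = simulate_f2_population(cfg, snps)
    table = select_and_sequence_bulks(population, cfg, snps)
    return SimpleNamespace(
        config=cfg,
        refs=refs,
        genes=genes,
        snps=snps,
        population=population,
        table=table,
        sites=sites_from_frame(table),
    )


@pytest.fixture(scope="session")
def dense_coding_experiment():
    """Small, gene-dense genome so many SNPs land in coding sequence."""
    cfg = SimConfig(
        chromosome_lengths={"chr1": 300_000},
        snp_density=3e-3,
        genes_per_chrom=60,
        causal_chrom="chr1",
        causal_pos=150_000,
        seq_error=0.0,
        rng_seed=23,
    )
    refs, genes, snps = simulate_genome_and_genes(cfg)
    population = simulate_f2_population(cfg, snps)
    table = select_and_sequence_bulks(population, cfg, snps)
    return SimpleNamespace(
        config=cfg, refs=refs, genes=genes, snps=snps,
        sites=sites_from_frame(table),
    )


@pytest.fixture
def make_site():
    """Builder for a SnpSite with explicit per-sample (ref, alt) depths."""

    def build(
        xap1=(10, 0),
        ayp1=(0, 10),
        by=(15, 15),
        ky=(15, 15),
        chrom="chr1",
        pos=100,
        ref="A",
        alt="G",
    ) -> SnpSite:
        return SnpSite(
            chrom, pos, ref, alt,
            {"XAP1": xap1, "AYP1": ayp1, "BY": by, "KY": ky},
        )

    return build
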