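"""Generator statistics: SNP placement, 3:1 segregation, bulk frequencies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bulkscan.genome import STOP_CODONS
from bulkscan.synthetic_data import (
    PARENTS,
    BulkSizeError,
    ExpressionSpec,
    SimConfig,
    select_and_sequence_bulks,
    simulate_expression_counts,
    simulate_f2_population,
    simulate_genome_and_genes,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_f2": 0},
            {"n_bulk": -1},
            {"seq_error": 0.5},
            {"seq_error": -0.1},
            {"snp_density": -1e-4},
            {"causal_pos": 10_000_000},  # outside the chromosome
            {"causal_chrom": "chrX"},
            {"causal_origin": "P3"},
            {"chromosome_lengths": {"chr1": 0}},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)

    def test_causal_must_be_set_together(self):
        with pytest.raises(ValueError):
            SimConfig(causal_chrom=None, causal_pos=123)


class TestGenomeAndGenes:
    def test_snp_count_matches_poisson_expectation(self):
        cfg = SimConfig(
            chromosome_lengths={"chr1": 1_000_000},
            snp_density=1e-3,
            causal_chrom="chr1",
            causal_pos=500_000,
            rng_seed=3,
        )
        _, _, snps = simulate_genome_and_genes(cfg)
        # Poisson(1000): 5 sigma is ~158
        assert 842 <= len(snps) <= 1158

    def test_zero_density_leaves_only_forced_causal_snp(self):
        cfg = SimConfig(snp_density=0.0, rng_seed=4)
        _, _, snps = simulate_genome_and_genes(cfg)
        assert len(snps) == 1
        assert snps.iloc[0]["pos"] == cfg.causal_pos
        assert snps.iloc[0]["alt_parent"] == cfg.causal_origin

    def test_gene_models_translate_cleanly_on_both_strands(self, default_experiment):
        refs, genes = default_experiment.refs, default_experiment.genes
        strands = {g.strand for g in genes}
        assert strands == {"+", "-"}
        for g in genes:
            protein = g.protein(refs[g.chrom])
            assert protein.startswith("M")
            assert protein.endswith("*")
            assert "*" not in protein[:-1]
            assert g.cds_length % 3 == 0

    def test_genes_non_overlapping_and_causal_hosted(self, default_experiment):
        genes = sorted(default_experiment.genes, key=lambda g: (g.chrom, g.start))
        for a, b in zip(genes, genes[1:]):
            if a.chrom == b.chrom:
                assert a.end < b.start
        cfg = default_experiment.config
        host = [g for g in genes if g.chrom == cfg.causal_chrom and g.contains(cfg.causal_pos)]
        assert len(host) == 1
        assert host[0].locate(cfg.causal_pos) == "cds"

    def test_engineered_causal_stopgain_codon(self, default_experiment):
        cfg = default_experiment.config
        refs = default_experiment.refs
        snps = default_experiment.snps
        row = snps[(snps.chrom == cfg.causal_chrom) & (snps.pos == cfg.causal_pos)]
        assert len(row) == 1
        host = next(
            g for g in default_experiment.genes
            if g.chrom == cfg.causal_chrom and g.contains(cfg.causal_pos)
        )
        off = host.cds_offset(cfg.causal_pos)
        cds = host.spliced_cds(refs[cfg.causal_chrom])
        codon_i, within = divmod(off, 3)
        ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
        alt = row.iloc[0]["alt"]
        mutant = ref_codon[:within] + alt + ref_codon[within + 1 :]
        assert ref_codon not in STOP_CODONS
        assert mutant in STOP_CODONS

    def test_sizing_error_when_chromosome_too_short(self):
        with pytest.raises(ValueError, match="cannot host"):
            simulate_genome_and_genes(
                SimConfig(
                    chromosome_lengths={"chr1": 5_000},
                    causal_chrom="chr1",
                    causal_pos=2_500,
                    genes_per_chrom=40,
                )
            )


class TestF2Population:
    def test_sterile_fraction_converges_to_one_quarter(self):
        # many small replicate populations; per-plant P(sterile) is exactly 1/4
        cfg_base = dict(
            chromosome_lengths={"chr1": 50_000},
            snp_density=0.0,
            causal_chrom="chr1",
            causal_pos=25_000,
            genes_per_chrom=1,
        )
        n_pops, n_f2 = 400, 200
        total_sterile = 0
        for seed in range(n_pops):
            cfg = SimConfig(rng_seed=seed, n_f2=n_f2, **cfg_base)
            _, _, snps = simulate_genome_and_genes(cfg)
            pop = simulate_f2_population(cfg, snps)
            total_sterile += sum(ind.phenotype == "sterile" for ind in pop)
        frac = total_sterile / (n_pops * n_f2)
        se = np.sqrt(0.25 * 0.75 / (n_pops * n_f2))
        assert abs(frac - 0.25) < 3 * se

    def test_zero_recombination_gives_single_origin_copies(self):
        cfg = SimConfig(recomb_rate=0.0, snp_density=1e-5, rng_seed=5)
        _, _, snps = simulate_genome_and_genes(cfg)
        pop = simulate_f2_population(cfg, snps)
        for ind in pop[:20]:
            for a, b in ind.copies.values():
                assert len(a.breakpoints) == 0
                assert len(b.breakpoints) == 0

    def test_sterile_plants_homozygous_for_causal_allele(self, default_experiment):
        cfg = default_experiment.config
        code = PARENTS.index(cfg.causal_origin)
        steriles = [p for p in default_experiment.population if p.phenotype == "sterile"]
        assert steriles
        for plant in steriles:
            assert plant.dosage(cfg.causal_chrom, cfg.causal_pos, code) == 2

    def test_breakpoints_strictly_increasing(self, default_experiment):
        for ind in default_experiment.population[:20]:
            for copy in ind.copies["chr1"]:
                assert np.all(np.diff(copy.breakpoints) > 0)

    def test_missing_causal_snp_rejected(self):
        cfg = SimConfig(rng_seed=6)
        snps = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "alt_parent"])
        with pytest.raises(ValueError, match="causal"):
            simulate_f2_population(cfg, snps)


class TestBulkSequencing:
    def test_by_bulk_pure_causal_allele_without_error(self, default_experiment):
        cfg = default_experiment.config
        table = default_experiment.table
        row = table[(table.chrom == cfg.causal_chrom) & (table.pos == cfg.causal_pos)].iloc[0]
        # causal_origin carries the alt allele at the engineered SNP: the
        # sterile bulk (all homozygous) shows exclusively that allele
        assert row["BY_ref"] == 0
        assert row["BY_alt"] > 0

    def test_parents_homozygous_without_error(self, default_experiment):
        table = default_experiment.table
        for parent in PARENTS:
            r = table[f"{parent}_ref"].to_numpy()
            a = table[f"{parent}_alt"].to_numpy()
            assert np.all((r == 0) | (a == 0))

    def test_ky_causal_frequency_one_third_and_unlinked_half(self):
        # fertile genotypes AA:Aa = 1:2 make the expected causal-allele
        # frequency 1/3 in the fertile bulk; an unlinked chromosome stays 1/2
        ky_causal, unlinked = [], []
        for seed in range(25):
            cfg = SimConfig(
                chromosome_lengths={"chr1": 1_000_000, "chr2": 1_000_000},
                snp_density=2e-5,
                causal_chrom="chr1",
                causal_pos=500_000,
                seq_error=0.0,
                genes_per_chrom=4,
                rng_seed=100 + seed,
            )
            _, _, snps = simulate_genome_and_genes(cfg)
            pop = simulate_f2_population(cfg, snps)
            table = select_and_sequence_bulks(pop, cfg, snps)
            row = table[(table.chrom == "chr1") & (table.pos == cfg.causal_pos)].iloc[0]
            ky_causal.append(row["KY_alt"] / (row["KY_ref"] + row["KY_alt"]))
            other = table[table.chrom == "chr2"]
            alt_parent = snps.set_index(["chrom", "pos"])["alt_parent"]
            for r in other.itertuples(index=False):
                for bulk in ("BY", "KY"):
                    d = getattr(r, f"{bulk}_ref") + getattr(r, f"{bulk}_alt")
                    if d:
                        unlinked.append(getattr(r, f"{bulk}_alt") / d)
        assert abs(np.mean(ky_causal) - 1 / 3) < 0.06  # ~3 SE at 25 runs
        assert abs(np.mean(unlinked) - 0.5) < 0.05

    def test_bulk_size_error_when_too_few_sterile(self):
        cfg = SimConfig(n_f2=40, rng_seed=8)  # expected ~10 sterile < 30
        _, _, snps = simulate_genome_and_genes(cfg)
        pop = simulate_f2_population(cfg, snps)
        with pytest.raises(BulkSizeError, match="plants"):
            select_and_sequence_bulks(pop, cfg, snps)

    def test_same_seed_is_byte_identical(self, tmp_path):
        from bulkscan.synthetic_data import write_vcf

        paths = []
        for name in ("a.vcf", "b.vcf"):
            cfg = SimConfig(
                chromosome_lengths={"chr1": 500_000},
                snp_density=1e-4,
                causal_chrom="chr1",
                causal_pos=250_000,
                rng_seed=9,
            )
            _, _, snps = simulate_genome_and_genes(cfg)
            pop = simulate_f2_population(cfg, snps)
            table = select_and_sequence_bulks(pop, cfg, snps)
            p = tmp_path / name
            write_vcf(table, str(p), cfg.chromosome_lengths)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestExpressionCounts:
    def test_lfc_multiplier_applies_to_by_only(self):
        spec = ExpressionSpec(
            gene_ids=["g1"],
            baseline_means=[100.0],
            dispersions=[1e-8],
            de_lfc={"g1": 2.0},
            n_replicates=300,
        )
        counts = simulate_expression_counts(spec, 1)
        groups = counts.columns.str.rsplit("_", n=1).str[0]
        by_mean = counts.loc["g1", groups == "BY"].mean()
        other_mean = counts.loc["g1", groups != "BY"].mean()
        assert abs(by_mean - 400) < 12  # Poisson(400), n=300: 3 SE ~ 3.5
        assert abs(other_mean - 100) < 4

    def test_zero_dispersion_is_poisson_like(self):
        spec = ExpressionSpec(
            gene_ids=["g1"], baseline_means=[200.0], dispersions=[0.0],
            n_replicates=500,
        )
        counts = simulate_expression_counts(spec, 2)
        x = counts.loc["g1"].to_numpy()
        assert 0.8 < x.var() / x.mean() < 1.25

    def test_null_gene_has_equal_group_means(self):
        spec = ExpressionSpec(
            gene_ids=["g1"], baseline_means=[500.0], dispersions=[0.05],
            n_replicates=400,
        )
        counts = simulate_expression_counts(spec, 3)
        groups = counts.columns.str.rsplit("_", n=1).str[0]
        means = counts.loc["g1"].groupby(groups).mean()
        assert means.max() / means.min() < 1.1

    def test_de_genes_must_exist(self):
        with pytest.raises(ValueError, match="DE genes"):
            ExpressionSpec(
                gene_ids=["g1"], baseline_means=[1.0], dispersions=[0.1],
                de_lfc={"nope": 1.0},
            )
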