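"""Generator ground truth: panel structure, evolution, expression, reads."""

import numpy as np
import pytest

from metaconserve import preprocess
from metaconserve.simdata import (
    CODON_TO_AA,
    STOP_CODONS,
    CommunityConfig,
    ConfigError,
    assign_expression,
    build_panel,
    evolve_genes,
    sample_reads,
    simulate_community,
    spike_contaminants,
)


def hamming_divergence(a: str, b: str) -> float:
    """Independent oracle: direct per-site mismatch count."""
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b)) / len(a)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(core_fraction=1.5),
            dict(divergence_expressed=-0.1),
            dict(expr_lognormal_sigma=-1),
            dict(taxon_abundances=(0.5, 0.2), n_taxa=2),
            dict(taxon_abundances=(0.5, 0.5, 0.5), n_taxa=3),
            dict(n_dna_reads=-1),
            dict(rrna_fraction=1.2),
            dict(gc_to_at_bias=0.5),
            dict(mean_gene_len_nt=601),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            CommunityConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        cfg = CommunityConfig(n_taxa=2, taxon_abundances=(0.7, 0.3), seed=5)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert CommunityConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestPanel:
    def test_core_and_sister_structure(self):
        cfg = CommunityConfig(n_taxa=2, genes_per_taxon=100, core_fraction=0.6, seed=2)
        panel = build_panel(cfg)
        for taxon, sub in panel.genes.groupby("taxon_id"):
            assert len(sub) == 100
            assert sub["is_core"].sum() == 60
            core_ids = set(sub[sub["is_core"]]["gene_id"])
            with_sister = {g for g in core_ids if g in panel.sister_pairs}
            assert with_sister == core_ids
            noncore = set(sub[~sub["is_core"]]["gene_id"])
            assert not noncore & set(panel.sister_pairs)
            assert len(panel.sister_proteomes[taxon]) == 60

    def test_no_core_means_no_sister_orthologs(self):
        cfg = CommunityConfig(n_taxa=2, genes_per_taxon=20, core_fraction=0.0, seed=2)
        panel = build_panel(cfg)
        assert panel.sister_pairs == {}
        assert all(not s for s in panel.sister_proteomes.values())

    def test_nt_translates_to_aa_without_stops(self):
        panel = build_panel(CommunityConfig(n_taxa=2, genes_per_taxon=10, seed=3))
        for row in panel.genes.itertuples():
            codons = [row.nt_seq[i : i + 3] for i in range(0, len(row.nt_seq), 3)]
            assert not set(codons) & set(STOP_CODONS)
            assert "".join(CODON_TO_AA[c] for c in codons) == row.aa_seq


class TestEvolution:
    def test_zero_divergence_is_identity(self):
        cfg = CommunityConfig(
            n_taxa=1, genes_per_taxon=5,
            divergence_expressed=0.0, divergence_nonexpressed=0.0,
            divergence_sd=0.0, seed=4,
        )
        panel = build_panel(cfg)
        genomes = evolve_genes(panel, cfg)
        for row in panel.genes.itertuples():
            assert genomes[row.gene_id].aa_seq == row.aa_seq
            assert genomes[row.gene_id].realized_divergence == 0.0

    def test_divergence_matches_hamming_oracle(self):
        cfg = CommunityConfig(
            n_taxa=1, genes_per_taxon=30, mean_gene_len_nt=900, gene_len_sd_nt=0,
            divergence_expressed=0.2, divergence_nonexpressed=0.2,
            divergence_sd=0.0, seed=5,
        )
        panel = build_panel(cfg)
        genomes = evolve_genes(panel, cfg)
        ref = dict(zip(panel.genes.gene_id, panel.genes.aa_seq))
        divs = []
        for g in genomes.values():
            d = hamming_divergence(g.aa_seq, ref[g.gene_id])
            assert d == pytest.approx(g.realized_divergence, abs=1e-12)
            divs.append(d)
        # 300-aa genes at target 0.20: binomial SD ~2.3% per gene
        assert np.mean(divs) == pytest.approx(0.20, abs=3 * 0.023 / np.sqrt(30))

    def test_unbiased_substitution_keeps_gc(self):
        base = CommunityConfig(
            n_taxa=1, genes_per_taxon=40, mean_gene_len_nt=900, gene_len_sd_nt=0,
            divergence_expressed=0.3, divergence_nonexpressed=0.3,
            divergence_sd=0.0, gc_to_at_bias=1.0, seed=6,
        )
        panel = build_panel(base)
        genomes = evolve_genes(panel, base)

        def gc(s):
            return sum(b in "GC" for b in s) / len(s)

        ref_gc = np.mean([gc(s) for s in panel.genes.nt_seq])
        evo_gc = np.mean([gc(g.nt_seq) for g in genomes.values()])
        assert evo_gc == pytest.approx(ref_gc, abs=0.01)

    def test_biased_substitution_lowers_gc(self):
        cfg = CommunityConfig(
            n_taxa=1, genes_per_taxon=40, mean_gene_len_nt=900, gene_len_sd_nt=0,
            divergence_expressed=0.3, divergence_nonexpressed=0.3,
            divergence_sd=0.0, gc_to_at_bias=4.0, seed=6,
        )
        panel = build_panel(cfg)
        genomes = evolve_genes(panel, cfg)

        def gc(s):
            return sum(b in "GC" for b in s) / len(s)

        ref_gc = np.mean([gc(s) for s in panel.genes.nt_seq])
        evo_gc = np.mean([gc(g.nt_seq) for g in genomes.values()])
        assert evo_gc < ref_gc - 0.01


class TestExpression:
    def test_degenerate_lognormal_gives_constant_levels(self):
        cfg = CommunityConfig(
            n_taxa=1, genes_per_taxon=30, expressed_fraction=1.0,
            expr_lognormal_mu=0.5, expr_lognormal_sigma=0.0,
            noncore_expr_boost=1.0, core_expression_odds=1.0, seed=7,
        )
        expr = assign_expression(build_panel(cfg), cfg)
        assert expr["expressed"].all()
        assert np.allclose(expr["level"], np.exp(0.5))

    def test_noncore_boost_recovered_in_mean_levels(self):
        cfg = CommunityConfig(
            n_taxa=4, genes_per_taxon=250, core_fraction=0.5,
            expressed_fraction=1.0, noncore_expr_boost=1.34,
            expr_lognormal_sigma=1.0, core_expression_odds=1.0, seed=8,
        )
        panel = build_panel(cfg)
        expr = assign_expression(panel, cfg).merge(
            panel.genes[["gene_id", "is_core"]], on="gene_id"
        )
        means = expr.groupby("is_core")["level"].mean()
        # lognormal(0,1) mean exp(0.5); MC error with n=2000 ~ 5%
        assert means[False] / means[True] == pytest.approx(1.34, rel=0.12)

    def test_core_expression_odds(self):
        cfg = CommunityConfig(
            n_taxa=2, genes_per_taxon=2000, core_fraction=0.5,
            expressed_fraction=0.5, core_expression_odds=3.0, seed=9,
        )
        panel = build_panel(cfg)
        expr = assign_expression(panel, cfg).merge(
            panel.genes[["gene_id", "is_core"]], on="gene_id"
        )
        rates = expr.groupby("is_core")["expressed"].mean()
        odds = (rates[True] / (1 - rates[True])) / (rates[False] / (1 - rates[False]))
        assert odds == pytest.approx(3.0, rel=0.35)
        assert expr["expressed"].mean() == pytest.approx(0.5, abs=0.05)


class TestReads:
    def test_zero_reads_gives_empty_pool(self):
        cfg = CommunityConfig(n_taxa=1, genes_per_taxon=3, n_dna_reads=0,
                              n_rna_reads=10, seed=10)
        panel = build_panel(cfg)
        dna, rna = sample_reads(evolve_genes(panel, cfg), cfg)
        assert dna == []
        assert len(rna) == 10

    def test_single_gene_truth(self):
        cfg = CommunityConfig(n_taxa=1, genes_per_taxon=1, n_dna_reads=50,
                              n_rna_reads=0, expressed_fraction=1.0, seed=11)
        panel = build_panel(cfg)
        dna, _ = sample_reads(evolve_genes(panel, cfg), cfg)
        gid = panel.genes.gene_id.iloc[0]
        assert all(r.truth[0] == gid for r in dna)

    def test_rna_reads_track_expression_ratio(self):
        cfg = CommunityConfig(
            n_taxa=1, genes_per_taxon=2, gene_len_sd_nt=0.0,
            expressed_fraction=1.0, n_dna_reads=0, n_rna_reads=8000, seed=12,
        )
        panel = build_panel(cfg)
        expr = assign_expression(panel, cfg)
        expr["level"] = [2.0, 1.0]
        genomes = evolve_genes(panel, cfg, expr)
        for g, lvl in zip(genomes.values(), [2.0, 1.0]):
            g.expression_level = lvl
        _, rna = sample_reads(genomes, cfg)
        counts = {}
        for r in rna:
            counts[r.truth[0]] = counts.get(r.truth[0], 0) + 1
        gids = list(genomes)
        assert counts[gids[0]] / counts[gids[1]] == pytest.approx(2.0, rel=0.1)

    def test_empty_genomes_error(self):
        cfg = CommunityConfig(seed=1)
        with pytest.raises(ValueError):
            sample_reads({}, cfg)


class TestContaminants:
    def test_zero_fractions_noop(self, small_sample):
        cfg = CommunityConfig(rrna_fraction=0.0, duplicate_fraction=0.0, seed=1)
        reads = small_sample.dna_reads[:100]
        out = spike_contaminants(reads, cfg, [])
        assert out == reads

    def test_duplicate_count_exact(self, rng):
        cfg = CommunityConfig(duplicate_fraction=0.1, seed=1)
        sim = simulate_community(
            CommunityConfig(n_taxa=1, genes_per_taxon=5, n_dna_reads=1000,
                            n_rna_reads=0, seed=13)
        )
        out = spike_contaminants(sim.dna_reads, cfg, [], rng)
        dups = [r for r in out if r.is_duplicate]
        assert len(out) == 1100
        assert len(dups) == 100
        originals = {r.nt_seq for r in sim.dna_reads}
        assert all(d.nt_seq in originals for d in dups)

    def test_pool_size_invariant(self, small_config, small_sample):
        expected = round(
            small_config.n_dna_reads
            * (1 + small_config.rrna_fraction + small_config.duplicate_fraction)
        )
        assert abs(len(small_sample.dna_reads) - expected) <= 2

    def test_filter_round_trip_recovers_originals(self, rng):
        base = CommunityConfig(n_taxa=2, genes_per_taxon=10, n_dna_reads=400,
                               n_rna_reads=0, seed=14)
        sim = simulate_community(base)
        cfg = CommunityConfig(rrna_fraction=0.1, duplicate_fraction=0.1, seed=15)
        spiked = spike_contaminants(sim.dna_reads, cfg, sim.panel.rrna_refs, rng)
        after_rrna, rep1 = preprocess.filter_rrna(spiked, sim.panel.rrna_refs)
        after_dedup, rep2 = preprocess.dedup_exact(after_rrna)
        assert rep1.rrna_removed == sum(r.is_rrna for r in spiked)
        assert rep2.duplicates_removed == sum(r.is_duplicate for r in spiked)
        assert len(after_dedup) == len(sim.dna_reads)


class TestDeterminism:
    def test_same_seed_byte_identical_fasta(self, tmp_path):
        cfg = CommunityConfig(n_taxa=2, genes_per_taxon=10, n_dna_reads=200,
                              n_rna_reads=200, rrna_fraction=0.05,
                              duplicate_fraction=0.05, seed=99)
        for name in ("a", "b"):
            sim = simulate_community(cfg)
            preprocess.write_fasta(sim.dna_reads, tmp_path / f"{name}_d.fasta")
            preprocess.write_fasta(sim.rna_reads, tmp_path / f"{name}_r.fasta")
        assert (tmp_path / "a_d.fasta").read_bytes() == (tmp_path / "b_d.fasta").read_bytes()
        assert (tmp_path / "a_r.fasta").read_bytes() == (tmp_path / "b_r.fasta").read_bytes()
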