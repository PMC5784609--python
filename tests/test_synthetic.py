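import json

import numpy as np
import pytest
from scipy import stats

from endcall import (GeneIndex, PipelineConfig, build_isoform_table,
                     scan_pas, usage_fractions, isoform_count_matrix)
from endcall import synthetic_data as sim
from conftest import run_site_calling


class TestMakeGenome:
    def test_seed_determinism_byte_identical(self, tmp_path):
        for i in (1, 2):
            b, _ = sim.make_genome(length=12_000, seed=99, n_traps=3)
            b.to_genome().to_fasta(tmp_path / f"g{i}.fa")
        assert (tmp_path / "g1.fa").read_bytes() == \
            (tmp_path / "g2.fa").read_bytes()

    def test_gc_content_within_tolerance(self):
        b, _ = sim.make_genome(length=1_000_000, gc=0.5, seed=4)
        seq = b.to_genome().contigs["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.01

    def test_no_a_tract_without_traps(self):
        b, traps = sim.make_genome(length=50_000, seed=5, n_traps=0)
        assert traps == []
        seq = b.to_genome().contigs["chr1"]
        assert "A" * 8 not in seq and "T" * 8 not in seq

    def test_traps_are_a_runs_with_clean_upstream(self):
        b, traps = sim.make_genome(length=30_000, seed=6, n_traps=4)
        genome = b.to_genome()
        assert len(traps) == 4
        for contig, strand, cpa in traps:
            if strand == "+":
                window = genome.fetch(contig, cpa, cpa + 4, "+")
            else:
                window = genome.fetch(contig, cpa - 4, cpa, "-")
            assert window == "AAAAA"
            assert scan_pas(contig, strand, cpa, genome) is None

    def test_short_contig_rejected(self):
        with pytest.raises(ValueError):
            sim.make_genome(length=5_000)


class TestMakeAnnotation:
    def test_sites_carry_pas_at_programmed_offset(self):
        builder, traps = sim.make_genome(length=60_000, seed=7)
        truth = sim.make_annotation(builder, traps, n_genes=8,
                                    isoforms_per_gene=2, seed=8)
        genome = builder.to_genome()
        hits = [
            scan_pas(g.contig, g.strand, s.position, genome)
            for g in truth.genes for s in g.sites
        ]
        assert all(h is not None for h in hits)
        assert all(h.motif == "AAUAAA" and h.offset == 19 for h in hits)

    def test_isoform_count_distribution_respected(self):
        builder, traps = sim.make_genome(length=60_000, seed=7)
        truth = sim.make_annotation(builder, traps, n_genes=4,
                                    isoforms_per_gene=[1, 2, 3, 2], seed=1)
        assert [len(g.sites) for g in truth.genes] == [1, 2, 3, 2]

    def test_spacing_guard(self):
        builder, traps = sim.make_genome(length=60_000, seed=7)
        with pytest.raises(ValueError, match="1500"):
            sim.make_annotation(builder, traps, n_genes=2,
                                inter_gene_space=100)

    def test_overcrowding_rejected(self):
        builder, traps = sim.make_genome(length=10_000, seed=7)
        with pytest.raises(ValueError, match="overcrowding"):
            sim.make_annotation(builder, traps, n_genes=50)

    def test_gff3_round_trip_through_reader(self, tmp_path):
        from endcall import read_annotation
        builder, traps = sim.make_genome(length=60_000, seed=7)
        truth = sim.make_annotation(builder, traps, n_genes=5, seed=2)
        path = tmp_path / "genes.gff3"
        sim.write_gff3(truth, path)
        genes = read_annotation(path)
        for g in truth.genes:
            model = genes[g.gene_id]
            assert model.exons == tuple(g.exons)
            assert model.stop_codon_position == g.stop_codon


class TestTruthSerialization:
    def test_json_round_trip_exact(self, tmp_path):
        _, truth, _ = sim.simulate_world(n_genes=5, depth=500, seed=21,
                                         n_traps=2, contig_length=40_000)
        p = tmp_path / "truth.json"
        truth.to_json(p)
        back = sim.SimTruth.from_json(p)
        assert back == truth

    def test_usage_fractions_sum_to_one(self):
        _, truth, _ = sim.simulate_world(n_genes=6, depth=100, seed=3)
        for sample in truth.samples:
            for gid, usage in truth.usage[sample].items():
                assert sum(usage) == pytest.approx(1.0)


class TestSimulateSample:
    def test_depth_zero_returns_empty(self):
        _, truth, _ = sim.simulate_world(n_genes=4, depth=10, seed=2)
        assert sim.simulate_sample(truth, "S1", 0) == []

    def test_two_seeds_differ_but_match_distributionally(self):
        _, truth, _ = sim.simulate_world(n_genes=10, depth=10, seed=2)
        r1 = sim.simulate_sample(truth, "S1", 20_000, seed=100)
        r2 = sim.simulate_sample(truth, "S1", 20_000, seed=200)
        assert r1 != r2
        t1 = {(r.contig, r.strand, r.cpa_position): r.count for r in r1}
        t2 = {(r.contig, r.strand, r.cpa_position): r.count for r in r2}
        common = set(t1) & set(t2)
        a = np.array([t1[k] for k in common])
        b = np.array([t2[k] for k in common])
        assert stats.pearsonr(a, b).statistic > 0.99

    def test_gene_totals_multinomial_consistent(self):
        """Chi-square goodness of fit of per-gene read totals against the
        programmed expression weights at depth 1e5."""
        _, truth, _ = sim.simulate_world(n_genes=12, depth=10, seed=31)
        site_counts = {}
        sim.simulate_sample(truth, "S1", 100_000, seed=7,
                            site_counts=site_counts)
        per_gene = {
            g.gene_id: sum(site_counts.get((g.contig, g.strand, s.position), 0)
                           for s in g.sites)
            for g in truth.genes
        }
        weights = np.array([truth.expression["S1"][g] for g in per_gene])
        observed = np.array(list(per_gene.values()))
        expected = weights / weights.sum() * observed.sum()
        p = stats.chisquare(observed, expected).pvalue
        assert p > 0.001

    def test_jitter_profile_matches_programmed_distribution(self):
        _, truth, _ = sim.simulate_world(
            n_genes=1, isoforms_per_gene=1, depth=10, seed=13)
        records = sim.simulate_sample(truth, "S1", 50_000, seed=3)
        site = truth.genes[0].sites[0].position
        sign = 1 if truth.genes[0].strand == "+" else -1
        total = sum(r.count for r in records)
        exact = sum(r.count for r in records if r.cpa_position == site)
        within5 = sum(r.count for r in records
                      if abs((r.cpa_position - site) * sign) <= 5)
        assert exact / total == pytest.approx(0.61, abs=0.02)
        assert within5 / total >= 0.90


class TestNoiseFreeIntegration:
    """Master integration test: with jitter and traps off, pipeline output
    equals simulator truth exactly."""

    def test_full_pipeline_equals_truth(self, noise_free_world):
        genome, truth, reads, site_counts = noise_free_world
        config = PipelineConfig()
        clusters = run_site_calling(reads, config)
        true_sites = {(g.contig, g.strand, s.position): (g, s)
                      for g in truth.genes for s in g.sites}
        # sites: exact one-to-one recovery
        got = {(c.contig, c.strand, c.representative) for c in clusters}
        assert got == set(true_sites)
        assert all(c.n_members == 1 for c in clusters)
        # assignments, UTR lengths, PAS offsets
        index = GeneIndex(truth.gene_models())
        records = build_isoform_table(clusters, index, genome, config)
        for rec in records:
            gene, site = true_sites[(rec.contig, rec.strand, rec.cpa_position)]
            assert rec.gene_id == gene.gene_id
            assert rec.apa_class == "tandem"
            assert rec.utr_length == site.utr_length
            assert rec.pas is not None and rec.pas.offset == 19
            assert rec.pas.motif == "AAUAAA"
        # per-sample counts equal the emitted reads exactly (no jitter means
        # every read sits on its true site), hence usage fractions equal the
        # emitted read proportions
        samples = sorted(truth.samples)
        for rec in records:
            key = (rec.contig, rec.strand, rec.cpa_position)
            for sample in samples:
                observed = sum(r.count for r in reads[sample]
                               if (r.contig, r.strand, r.cpa_position) == key)
                assert rec.per_sample.get(sample, 0) == observed
        iso = isoform_count_matrix(records, samples)
        usage = usage_fractions(iso)
        gene_totals = iso.groupby(level="gene_id").transform("sum")
        assert np.allclose(usage.to_numpy(),
                           (iso / gene_totals).fillna(0).to_numpy())
        per_gene_sum = usage.groupby(level="gene_id").sum()
        assert np.allclose(per_gene_sum.to_numpy(), 1.0)
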