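import random

import pytest

from endcall import (GenomeSequence, PipelineConfig, read_annotation,
                     read_cpa_bed, write_cpa_bed)
from endcall.cpa_clustering import CpaCluster
from endcall.formats_io import AnnotationError


# --- genome ---------------------------------------------------------------

class TestGenomeSequence:
    def test_strand_aware_fetch(self):
        g = GenomeSequence({"I": "ACGTACGTAC"})
        assert g.fetch("I", 1, 4, "+") == "ACGT"
        assert g.fetch("I", 1, 4, "-") == "ACGT"   # palindromic
        assert g.fetch("I", 2, 5, "-") == "TACG"   # revcomp of CGTA

    @pytest.mark.parametrize("start,end", [(0, 3), (5, 12), (-1, 2), (9, 8)])
    def test_out_of_range_rejected(self, start, end):
        g = GenomeSequence({"I": "ACGTACGTAC"})
        with pytest.raises((ValueError, KeyError)):
            g.fetch("I", start, end)

    def test_padded_fetch_fills_n(self):
        g = GenomeSequence({"I": "ACGT"})
        assert g.fetch_padded("I", -1, 2) == "NNAC"
        assert g.fetch_padded("I", 3, 6) == "GTNN"

    def test_fasta_round_trip(self, tmp_path):
        g = GenomeSequence({"I": "ACGTN" * 30, "II": "GGCC" * 10})
        path = tmp_path / "g.fa"
        g.to_fasta(path)
        back = GenomeSequence.from_fasta(path)
        assert back.contigs == g.contigs


# --- annotation -----------------------------------------------------------

GFF3 = """##gff-version 3
I\tsrc\tgene\t100\t900\t.\t{strand}\t.\tID=geneA;biotype=protein_coding
I\tsrc\tmRNA\t100\t900\t.\t{strand}\t.\tID=geneA.t1;Parent=geneA
I\tsrc\texon\t100\t300\t.\t{strand}\t.\tParent=geneA.t1
I\tsrc\texon\t500\t900\t.\t{strand}\t.\tParent=geneA.t1
I\tsrc\tCDS\t150\t300\t.\t{strand}\t0\tParent=geneA.t1
I\tsrc\tCDS\t500\t700\t.\t{strand}\t0\tParent=geneA.t1
"""

GTF = (
    'I\tsrc\texon\t100\t300\t.\t+\t.\tgene_id "geneA"; transcript_id "t1";\n'
    'I\tsrc\texon\t500\t900\t.\t+\t.\tgene_id "geneA"; transcript_id "t1";\n'
    'I\tsrc\tCDS\t150\t700\t.\t+\t0\tgene_id "geneA"; transcript_id "t1";\n'
)


class TestReadAnnotation:
    def test_gff3_single_gene(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF3.format(strand="+"))
        genes = read_annotation(p)
        g = genes["geneA"]
        assert g.exons == ((100, 300), (500, 900))
        assert g.biotype == "protein_coding"
        assert g.stop_codon_position == 700  # max CDS end on '+'

    def test_minus_strand_stop_codon_is_min_cds_coordinate(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF3.format(strand="-"))
        genes = read_annotation(p)
        assert genes["geneA"].stop_codon_position == 150

    def test_gtf_dialect(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(GTF)
        genes = read_annotation(p)
        assert genes["geneA"].exons == ((100, 300), (500, 900))
        assert genes["geneA"].stop_codon_position == 700

    def test_exon_without_gene_id_errors(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("##gff-version 3\nI\tsrc\texon\t10\t20\t.\t+\t.\tID=orphan\n")
        with pytest.raises(AnnotationError, match="gene identifier"):
            read_annotation(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("##gff-version 3\nI\tsrc\texon\t10\n")
        with pytest.raises(AnnotationError, match="line 2"):
            read_annotation(p)

    def test_parse_is_order_independent(self, tmp_path):
        lines = GFF3.format(strand="+").strip().split("\n")
        body = lines[1:]
        rng = random.Random(7)
        models = []
        for _ in range(5):
            rng.shuffle(body)
            p = tmp_path / "s.gff3"
            p.write_text("\n".join([lines[0]] + body) + "\n")
            models.append(read_annotation(p)["geneA"])
        assert all(m == models[0] for m in models)


# --- CPA BED --------------------------------------------------------------

def _cluster(contig, strand, site, count, cid="c1"):
    return CpaCluster(cluster_id=cid, contig=contig, strand=strand,
                      representative=site, members=((site, count),),
                      per_sample={"S1": count})


class TestCpaBed:
    def test_convention_plus(self, tmp_path):
        path = tmp_path / "c.bed"
        write_cpa_bed([_cluster("I", "+", 100, 13)], path)
        assert path.read_text() == "I\t99\t100\tc1\t13\t+\n"

    def test_convention_minus(self, tmp_path):
        path = tmp_path / "c.bed"
        write_cpa_bed([_cluster("I", "-", 200, 5)], path)
        assert path.read_text() == "I\t199\t200\tc1\t5\t-\n"

    def test_empty(self, tmp_path):
        path = tmp_path / "c.bed"
        write_cpa_bed([], path)
        assert path.read_text() == ""

    def test_round_trip_exact(self, tmp_path):
        rng = random.Random(3)
        clusters = [
            _cluster(rng.choice("IVX"), rng.choice("+-"),
                     rng.randint(1, 10**6), rng.randint(1, 10**4), f"c{i}")
            for i in range(50)
        ]
        path = tmp_path / "c.bed"
        write_cpa_bed(clusters, path)
        back = read_cpa_bed(path)
        assert back == [(c.contig, c.strand, c.representative, c.total,
                         c.cluster_id) for c in clusters]


# --- config ---------------------------------------------------------------

class TestPipelineConfig:
    def test_defaults_validate(self):
        cfg = PipelineConfig()
        assert cfg.cluster_window == 12
        assert cfg.pas_window == (8, 25)
        assert cfg.pas_motifs[0] == "AAUAAA"
        assert len(cfg.pas_motifs) == 15

    @pytest.mark.parametrize("kw", [
        {"cluster_window": 0},
        {"min_isoform_fraction": 0.0},
        {"min_isoform_fraction": 1.5},
        {"pas_window": (0, 25)},
        {"pas_window": (25, 8)},
        {"mispriming_min_A": 9},
        {"pas_motifs": ("AAUAA",)},
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            PipelineConfig(**kw)

    def test_motifs_normalised_to_rna(self):
        cfg = PipelineConfig(pas_motifs=("AATAAA", "attaaa"))
        assert cfg.pas_motifs == ("AAUAAA", "AUUAAA")

    def test_from_file(self, tmp_path):
        p = tmp_path / "cfg.txt"
        p.write_text("cluster_window = 10\nfdr_threshold = 0.01\n"
                     "# comment\npas_window = 5, 30\n")
        cfg = PipelineConfig.from_file(p)
        assert (cfg.cluster_window, cfg.fdr_threshold, cfg.pas_window) == \
            (10, 0.01, (5, 30))

    def test_from_file_unknown_key(self, tmp_path):
        p = tmp_path / "cfg.txt"
        p.write_text("wrong_name = 3\n")
        with pytest.raises(ValueError, match="unknown parameter"):
            PipelineConfig.from_file(p)

    def test_parameters_echoed_to_log(self, caplog):
        import dataclasses
        with caplog.at_level("INFO", logger="endcall"):
            PipelineConfig().log_parameters()
        logged = [r for r in caplog.records if r.message.startswith("config ")]
        assert len(logged) == len(dataclasses.fields(PipelineConfig))
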