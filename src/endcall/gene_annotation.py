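"""Assign CPA clusters to genes, classify 3'UTR isoforms, measure 3'UTR
lengths and annotate polyadenylation signals (PAS).

Assignment follows the two-tier rule: unambiguous overlap of the CPA base
with a gene's exons on the same strand, otherwise the nearest same-strand
gene whose 3'-most exon end lies at most ``max_upstream_assign`` nt upstream
of the site.  Sites overlapping exons of more than one gene are left
unassigned (ambiguous); sites near nothing are novel.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

from intervaltree import IntervalTree

from .cpa_clustering import CpaCluster
from .formats_io import GeneModel, GenomeSequence, PipelineConfig

# assignment modes
EXON_OVERLAP = "exon_overlap"
UPSTREAM_PROXIMITY = "upstream_proximity"
UNASSIGNED_NOVEL = "unassigned_novel"
UNASSIGNED_AMBIGUOUS = "unassigned_ambiguous"
NCRNA_END = "ncRNA_end"

# APA classes
TANDEM = "tandem"
CDS_INTERNAL = "cds_internal"
NCRNA_CLASS = "ncRNA"


@dataclass(frozen=True)
class Assignment:
    mode: str
    gene_id: str | None
    distance: int = 0           # 0 for exon overlap; nt upstream otherwise

    @property
    def assigned(self) -> bool:
        return self.gene_id is not None


class GeneIndex:
    """Strand-aware exon interval index plus sorted gene 3'-end lists."""

    def __init__(self, genes: dict[str, GeneModel]):
        self.genes = genes
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self._ends: dict[tuple[str, str], list[tuple[int, str]]] = {}
        for gene in genes.values():
            key = (gene.contig, gene.strand)
            tree = self._trees.setdefault(key, IntervalTree())
            for (s, e) in gene.exons:
                tree.addi(s, e + 1, gene.gene_id)   # half-open storage
            self._ends.setdefault(key, []).append(
                (gene.three_prime_end, gene.gene_id)
            )
        for ends in self._ends.values():
            ends.sort()

    def exon_overlaps(self, contig: str, strand: str, pos: int) -> set[str]:
        tree = self._trees.get((contig, strand))
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos)}

    def nearest_upstream_gene(
        self, contig: str, strand: str, pos: int, max_dist: int
    ) -> tuple[str, int] | None:
        """Nearest same-strand gene whose 3' end is upstream of ``pos``
        within ``max_dist`` nt; ties broken by gene id for determinism."""
        ends = self._ends.get((contig, strand))
        if not ends:
            return None
        best: tuple[int, str] | None = None
        if strand == "+":
            i = bisect_left(ends, (pos, "")) - 1
            while i >= 0:
                end3, gid = ends[i]
                dist = pos - end3
                if dist > max_dist:
                    break
                if dist >= 1 and (best is None or (dist, gid) < best):
                    best = (dist, gid)
                i -= 1
        else:
            i = bisect_left(ends, (pos + 1, ""))
            while i < len(ends):
                end3, gid = ends[i]
                dist = end3 - pos
                if dist > max_dist:
                    break
                if dist >= 1 and (best is None or (dist, gid) < best):
                    best = (dist, gid)
                i += 1
        if best is None:
            return None
        return best[1], best[0]


def assign_cluster(
    cluster: CpaCluster, index: GeneIndex, config: PipelineConfig | None = None
) -> Assignment:
    """Assign one CPA cluster to a gene (or leave it unassigned)."""
    config = config or PipelineConfig()
    overlaps = index.exon_overlaps(
        cluster.contig, cluster.strand, cluster.representative
    )
    if len(overlaps) > 1:
        return Assignment(UNASSIGNED_AMBIGUOUS, None)
    if len(overlaps) == 1:
        gid = next(iter(overlaps))
        mode = NCRNA_END if index.genes[gid].biotype != "protein_coding" else EXON_OVERLAP
        return Assignment(mode, gid, 0)
    hit = index.nearest_upstream_gene(
        cluster.contig, cluster.strand, cluster.representative,
        config.max_upstream_assign,
    )
    if hit is not None:
        gid, dist = hit
        mode = NCRNA_END if index.genes[gid].biotype != "protein_coding" else UPSTREAM_PROXIMITY
        return Assignment(mode, gid, dist)
    return Assignment(UNASSIGNED_NOVEL, None)


def classify_and_measure(
    cpa_position: int, gene: GeneModel, spliced: bool | None = None
) -> tuple[str, int | None]:
    """APA class and 3'UTR length for a CPA site assigned to ``gene``.

    Tandem if the site lies strictly 3' of the gene's 3'-most stop codon on
    the transcript strand; the length counts genomic bases from the first
    base past the stop codon through the CPA base inclusive.  When the
    annotation supplies explicit three_prime_UTR features (or ``spliced`` is
    forced), intronic gaps are subtracted using those features.
    """
    if gene.biotype != "protein_coding":
        return NCRNA_CLASS, None
    stop = gene.stop_codon_position
    if stop is None:
        return NCRNA_CLASS, None
    if gene.strand == "+":
        if cpa_position <= stop:
            return CDS_INTERNAL, None
        lo, hi = stop + 1, cpa_position
    else:
        if cpa_position >= stop:
            return CDS_INTERNAL, None
        lo, hi = cpa_position, stop - 1
    use_spliced = bool(gene.utr3) if spliced is None else spliced
    if use_spliced and gene.utr3:
        length = sum(
            max(0, min(hi, e) - max(lo, s) + 1) for (s, e) in gene.utr3
        )
        length = max(length, 1)
    else:
        length = hi - lo + 1
    return TANDEM, length


@dataclass(frozen=True)
class PasHit:
    motif: str          # RNA alphabet, e.g. AAUAAA
    rank: int           # 1 = canonical
    offset: int         # nt from motif end to the CPA base


def scan_pas(
    contig: str,
    strand: str,
    cpa_position: int,
    genome: GenomeSequence,
    config: PipelineConfig | None = None,
) -> PasHit | None:
    """Scan the sense-strand window upstream of a CPA site for ranked PAS
    hexamers.

    A hexamer qualifies if its last base lies ``pas_window`` ([8, 25] by
    default) nt upstream of the CPA base.  Preference: motif rank first,
    then offset closest to the 19 nt mode, then 3'-most (smallest offset).
    Windows truncated by a contig edge scan the available portion.
    """
    config = config or PipelineConfig()
    lo, hi = config.pas_window
    span = hi + 5           # motif start at offset hi sits hi+5 upstream
    if strand == "+":
        upstream = genome.fetch_padded(
            contig, cpa_position - span, cpa_position - 1, "+"
        )
    else:
        upstream = genome.fetch_padded(
            contig, cpa_position + 1, cpa_position + span, "-"
        )
    upstream = upstream.replace("T", "U")
    best: tuple[int, int, int, PasHit] | None = None
    n = len(upstream)
    for start in range(0, n - 5):
        offset = span - (start + 5)     # motif-end distance to the CPA base
        if not (lo <= offset <= hi):
            continue
        hexamer = upstream[start : start + 6]
        for rank, motif in enumerate(config.pas_motifs, start=1):
            if hexamer == motif:
                key = (rank, abs(offset - 19), offset)
                hit = PasHit(motif=motif, rank=rank, offset=offset)
                if best is None or key < best[:3]:
                    best = (*key, hit)
                break
    return best[3] if best else None


@dataclass
class IsoformRecord:
    """A CPA cluster assigned to a gene, with class, 3'UTR length, PAS
    annotation and per-sample counts.  ``isoform_index`` orders a gene's
    isoforms 5'→3' (1 = most proximal)."""

    gene_id: str | None
    cluster_id: str
    contig: str
    strand: str
    cpa_position: int
    mode: str
    apa_class: str | None
    utr_length: int | None
    pas: PasHit | None
    per_sample: dict[str, int]
    isoform_index: int = 0

    @property
    def total(self) -> int:
        return sum(self.per_sample.values())


def build_isoform_table(
    clusters: list[CpaCluster],
    index: GeneIndex,
    genome: GenomeSequence | None = None,
    config: PipelineConfig | None = None,
) -> list[IsoformRecord]:
    """Assign every cluster, classify it against its gene and annotate PAS.

    Isoforms of each gene are indexed 5'→3' along the transcript so that
    proximal/distal labels are well defined downstream.
    """
    config = config or PipelineConfig()
    records: list[IsoformRecord] = []
    for cluster in clusters:
        a = assign_cluster(cluster, index, config)
        apa_class = utr_len = None
        if a.assigned:
            gene = index.genes[a.gene_id]
            apa_class, utr_len = classify_and_measure(cluster.representative, gene)
        pas = (
            scan_pas(cluster.contig, cluster.strand, cluster.representative,
                     genome, config)
            if genome is not None else None
        )
        records.append(
            IsoformRecord(
                gene_id=a.gene_id,
                cluster_id=cluster.cluster_id,
                contig=cluster.contig,
                strand=cluster.strand,
                cpa_position=cluster.representative,
                mode=a.mode,
                apa_class=apa_class,
                utr_length=utr_len,
                pas=pas,
                per_sample=dict(cluster.per_sample),
            )
        )
    _index_isoforms(records, index)
    return records


def _index_isoforms(records: list[IsoformRecord], index: GeneIndex) -> None:
    by_gene: dict[str, list[IsoformRecord]] = {}
    for rec in records:
        if rec.gene_id is not None:
            by_gene.setdefault(rec.gene_id, []).append(rec)
    for gid, recs in by_gene.items():
        distal_last = index.genes[gid].strand == "+"
        recs.sort(key=lambda r: r.cpa_position, reverse=not distal_last)
        for i, rec in enumerate(recs, start=1):
            rec.isoform_index = i
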