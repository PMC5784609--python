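"""Readers/writers for the standard formats the pipeline touches, the validated
pipeline configuration, and structured logging.

Coordinate conventions
----------------------
Internally every position is 1-based and fully closed, on the forward
reference strand; strand-awareness is explicit in every record.  BED output is
0-based half-open; GFF3/GTF input is 1-based closed.  These match the dominant
conventions of each format and keep the "first base of Read 2" definition of a
cleavage-and-polyadenylation (CPA) site unambiguous.
"""

from __future__ import annotations

import logging
import os
import sys
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Iterator

import gffutils
import pysam
from Bio import SeqIO

logger = logging.getLogger("endcall")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Ranked polyadenylation-signal hexamers (RNA alphabet), canonical AAUAAA
#: first.  The set of "most common" PAS hexamers is an assumption of this
#: package (see docs/methods.md) and is fully configurable.
DEFAULT_PAS_MOTIFS: tuple[str, ...] = (
    "AAUAAA", "AUUAAA", "UAUAAA", "AGUAAA", "AAGAAA",
    "AAUAUA", "AAUACA", "CAUAAA", "GAUAAA", "AAUGAA",
    "UUUAAA", "ACUAAA", "AAUAGA", "AUUACA", "AACAAA",
)


def setup_logging(level: int = logging.INFO, stream=None) -> None:
    """Configure the package logger with a timestamped single-line format."""
    handler = logging.StreamHandler(stream or sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genome sequence
# ---------------------------------------------------------------------------

class GenomeSequence:
    """In-memory genome: contig name -> uppercase nucleotide string.

    ``fetch`` is strand-aware and 1-based closed; out-of-range queries raise
    rather than silently truncating.
    """

    def __init__(self, contigs: dict[str, str]):
        if len(set(contigs)) != len(contigs):
            raise ValueError("duplicate contig names")
        self._contigs = {name: seq.upper() for name, seq in contigs.items()}
        bad = {
            name
            for name, seq in self._contigs.items()
            if set(seq) - set("ACGTN")
        }
        if bad:
            raise ValueError(f"non-ACGTN characters in contigs: {sorted(bad)}")

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "GenomeSequence":
        records = SeqIO.parse(str(path), "fasta")
        return cls({rec.id: str(rec.seq) for rec in records})

    @property
    def contigs(self) -> dict[str, str]:
        return self._contigs

    def contig_length(self, contig: str) -> int:
        return len(self._contigs[contig])

    def __contains__(self, contig: str) -> bool:
        return contig in self._contigs

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end]`` (1-based closed); reverse-complemented
        when ``strand`` is '-'."""
        if contig not in self._contigs:
            raise KeyError(f"unknown contig {contig!r}")
        seq = self._contigs[contig]
        if not (1 <= start <= end <= len(seq)):
            raise ValueError(
                f"query {contig}:{start}-{end} out of range (contig length {len(seq)})"
            )
        sub = seq[start - 1 : end]
        return reverse_complement(sub) if strand == "-" else sub

    def fetch_padded(
        self, contig: str, start: int, end: int, strand: str = "+"
    ) -> str:
        """Like :meth:`fetch` but pads out-of-range flanks with ``N``.

        Used where a window may run off a contig end and unavailable bases
        must be treated as non-informative rather than an error.
        """
        length = self.contig_length(contig)
        left_pad = max(0, 1 - start)
        right_pad = max(0, end - length)
        s, e = max(1, start), min(length, end)
        core = self._contigs[contig][s - 1 : e] if s <= e else ""
        seq = "N" * left_pad + core + "N" * right_pad
        return reverse_complement(seq) if strand == "-" else seq

    def to_fasta(self, path: str | os.PathLike, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene with merged exon structure and, for coding genes, the genomic
    coordinate of the 3'-most base of the 3'-most stop codon."""

    gene_id: str
    biotype: str              # protein_coding | ncRNA | other
    contig: str
    strand: str               # '+' or '-'
    exons: tuple[tuple[int, int], ...]       # merged, ascending genomic order
    cds: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()   # explicit three_prime_UTR features

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        for (s, e) in self.exons:
            if s > e:
                raise ValueError(f"inverted exon {s}-{e} in {self.gene_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the gene's 3'-most exonic base."""
        return self.end if self.strand == "+" else self.start

    @property
    def stop_codon_position(self) -> int | None:
        """3'-most CDS genomic coordinate: max CDS end on '+', min CDS start
        on '-'.  ``None`` for non-coding genes."""
        if self.biotype != "protein_coding" or not self.cds:
            return None
        if self.strand == "+":
            return max(e for _, e in self.cds)
        return min(s for s, _ in self.cds)


class AnnotationError(ValueError):
    pass


def _merge_intervals(ivals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    ivals = sorted(ivals)
    merged: list[list[int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


_NC_BIOTYPES = {
    "ncrna", "lincrna", "mirna", "snorna", "snrna", "rrna", "trna", "pirna",
    "antisense", "lncrna", "pseudogene",
}


def _normalise_biotype(raw: str | None, has_cds: bool) -> str:
    if raw:
        b = raw.lower()
        if b == "protein_coding":
            return "protein_coding"
        if b in _NC_BIOTYPES:
            return "ncRNA"
        return "other" if not has_cds else "protein_coding"
    return "protein_coding" if has_cds else "ncRNA"


def _validate_gff_lines(path: str | os.PathLike) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):   # trailing FASTA section
                break
            if len(line.split("\t")) != 9:
                raise AnnotationError(
                    f"{path}: malformed annotation line {lineno}: "
                    f"expected 9 tab-separated columns"
                )


def read_annotation(path: str | os.PathLike) -> dict[str, GeneModel]:
    """Parse a GFF3 or GTF file into GeneModels keyed by gene id.

    Gene id resolution order per feature: ``gene_id`` attribute, then ``ID``
    of a gene-type feature, then the ``Parent`` chain up to a gene.  Exons are
    merged per gene; a CDS whose gene cannot be resolved is an error.
    """
    _validate_gff_lines(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils message passthrough
        raise AnnotationError(f"{path}: failed to parse annotation: {exc}") from exc

    def resolve_gene(feature) -> str | None:
        if "gene_id" in feature.attributes:
            return feature.attributes["gene_id"][0]
        for parent in db.parents(feature):
            if parent.featuretype == "gene":
                return parent.id
            if "gene_id" in parent.attributes:
                return parent.attributes["gene_id"][0]
        if feature.featuretype == "gene":
            return feature.id
        return None

    gene_meta: dict[str, dict] = {}

    def bucket(gene_id, feature):
        info = gene_meta.setdefault(
            gene_id,
            {"contig": feature.seqid, "strand": feature.strand,
             "exons": [], "cds": [], "utr3": [], "biotype": None},
        )
        return info

    for feature in db.all_features():
        ftype = feature.featuretype.lower()
        if ftype == "gene":
            gid = resolve_gene(feature)
            info = bucket(gid, feature)
            for key in ("biotype", "gene_biotype", "gene_type"):
                if key in feature.attributes:
                    info["biotype"] = feature.attributes[key][0]
                    break
            continue
        if ftype not in ("exon", "cds", "three_prime_utr"):
            continue
        gid = resolve_gene(feature)
        if gid is None:
            raise AnnotationError(
                f"{path}: {feature.featuretype} feature at "
                f"{feature.seqid}:{feature.start}-{feature.end} has no "
                f"resolvable gene identifier"
            )
        info = bucket(gid, feature)
        key = {"exon": "exons", "cds": "cds", "three_prime_utr": "utr3"}[ftype]
        info[key].append((feature.start, feature.end))

    genes: dict[str, GeneModel] = {}
    for gid, info in gene_meta.items():
        exons = _merge_intervals(info["exons"]) if info["exons"] else ()
        cds = _merge_intervals(info["cds"]) if info["cds"] else ()
        if not exons:
            if cds:
                exons = cds
            else:
                continue  # gene with no structural children: nothing to index
        biotype = _normalise_biotype(info["biotype"], bool(cds))
        genes[gid] = GeneModel(
            gene_id=gid,
            biotype=biotype,
            contig=info["contig"],
            strand=info["strand"],
            exons=exons,
            cds=cds,
            utr3=_merge_intervals(info["utr3"]) if info["utr3"] else (),
        )
    return genes


# ---------------------------------------------------------------------------
# Alignment reading
# ---------------------------------------------------------------------------

@dataclass
class PairStats:
    yielded: int = 0
    skipped_unpaired: int = 0
    skipped_secondary: int = 0


def read_alignments(
    path: str | os.PathLike,
    sample_id: str,
    stats: PairStats | None = None,
) -> Iterator[tuple[pysam.AlignedSegment, pysam.AlignedSegment]]:
    """Yield proper (Read 1, Read 2) pairs from a SAM/BAM file.

    Secondary/supplementary alignments are ignored (primary only); records
    whose mate is missing or unmapped are counted and skipped.
    """
    stats = stats if stats is not None else PairStats()
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                stats.skipped_secondary += 1
                continue
            if (not rec.is_paired) or rec.is_unmapped or rec.mate_is_unmapped:
                stats.skipped_unpaired += 1
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            r1, r2 = (rec, mate) if rec.is_read1 else (mate, rec)
            if not (r1.is_read1 and r2.is_read2):
                stats.skipped_unpaired += 2
                continue
            stats.yielded += 1
            yield r1, r2
    if pending:
        stats.skipped_unpaired += len(pending)
        logger.info(
            "sample %s: %d unpaired records skipped", sample_id, len(pending)
        )


# ---------------------------------------------------------------------------
# BED output for CPA clusters
# ---------------------------------------------------------------------------

def write_cpa_bed(clusters, path: str | os.PathLike) -> None:
    """Write representative CPA sites as BED6 (0-based half-open, 1-nt
    interval at the CPA base; name = cluster id, score = total support)."""
    tmp = str(path) + ".tmp"
    try:
        with open(tmp, "w") as fh:
            for c in clusters:
                fh.write(
                    f"{c.contig}\t{c.representative - 1}\t{c.representative}\t"
                    f"{c.cluster_id}\t{c.total}\t{c.strand}\n"
                )
        os.replace(tmp, path)
    except Exception:
        if os.path.exists(tmp):
            os.remove(tmp)
        raise


def read_cpa_bed(path: str | os.PathLike) -> list[tuple[str, str, int, int, str]]:
    """Read a CPA BED6 back as (contig, strand, site, count, name) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            contig, start, end, name, score, strand = line.split("\t")[:6]
            out.append((contig, strand, int(end), int(score), name))
    return out


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All numeric rules of the pipeline in one validated object.

    Defaults encode the published protocol: ±12 nt clustering window, ≥2
    sample universe support, 1500 nt upstream gene assignment, 5% isoform
    floor, PAS scan 8–25 nt upstream, 5-base downstream A-window with a
    ≥4-of-5 adenosine rule, 5% FDR, 50 nt minimum read length and 6 nt sample
    barcodes.
    """

    cluster_window: int = 12
    min_samples_support: int = 2
    max_upstream_assign: int = 1500
    min_isoform_fraction: float = 0.05
    pas_window: tuple[int, int] = (8, 25)
    pas_motifs: tuple[str, ...] = DEFAULT_PAS_MOTIFS
    mispriming_downstream_window: int = 5
    mispriming_min_A: int = 4
    fdr_threshold: float = 0.05
    min_read_len: int = 50
    barcode_len: int = 6
    rng_seed: int = 0

    def __post_init__(self):
        self.pas_window = tuple(self.pas_window)  # type: ignore[assignment]
        self.pas_motifs = tuple(m.upper().replace("T", "U") for m in self.pas_motifs)
        for name in (
            "cluster_window", "min_samples_support", "max_upstream_assign",
            "mispriming_downstream_window", "mispriming_min_A",
            "min_read_len", "barcode_len",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("min_isoform_fraction", "fdr_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        lo, hi = self.pas_window
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid pas_window {self.pas_window}")
        if self.mispriming_min_A > self.mispriming_downstream_window:
            raise ValueError("mispriming_min_A exceeds the downstream window")
        for m in self.pas_motifs:
            if len(m) != 6 or set(m) - set("ACGU"):
                raise ValueError(f"PAS motif {m!r} is not an RNA hexamer")

    def log_parameters(self) -> None:
        """Echo every parameter to the log (called at run start)."""
        for f in fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        """Read a simple ``key = value`` config file; unknown keys error."""
        known = {f.name: f for f in fields(cls)}
        kw: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, raw = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
                if key == "pas_motifs":
                    kw[key] = tuple(s.strip() for s in raw.split(","))
                elif key == "pas_window":
                    lo, hi = (int(s) for s in raw.split(","))
                    kw[key] = (lo, hi)
                elif key in ("min_isoform_fraction", "fdr_threshold"):
                    kw[key] = float(raw)
                else:
                    kw[key] = int(raw)
        return cls(**kw)
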