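"""Seeded, ground-truthed synthetic test world: genome, annotation and
per-sample 3'-end reads with the statistical structure the pipeline assumes.

The generator emulates the features that matter to every downstream stage:

* cleavage jitter around each true CPA site — by default 61% of reads at the
  exact position and ~99% within ±5 nt, a symmetric discrete distribution
  matching the cleavage precision the protocol exhibits;
* a PAS hexamer written into the genome ending 19 nt upstream of every true
  site (the modal PAS offset), with the rest of the upstream scan window kept
  free of competing motifs so recovered offsets are identifiable;
* genomic A-homopolymer "traps" in intergenic space that attract internal
  oligo-dT mispriming reads, with no PAS in their upstream window;
* programmed per-gene expression, per-isoform usage fractions and
  between-condition usage switches;
* optional X-vs-autosome expression ratios via a contig named ``X``.

Everything is reproducible bit-for-bit from the seeds, and the full ground
truth serializes to JSON so recovery tests can compare pipeline output
against it exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .end_extraction import EndRecord
from .formats_io import GeneModel, GenomeSequence, reverse_complement

# --------------------------------------------------------------------------
# Jitter model
# --------------------------------------------------------------------------

def default_jitter(max_offset: int = 12) -> dict[int, float]:
    """Symmetric cleavage-jitter distribution: P(0)=0.61, P(±1)=0.08,
    P(±2)=0.05, P(±3..±5)=0.02 each, remaining 1% uniform on ±6..±12."""
    probs = {0: 0.61, 1: 0.08, -1: 0.08, 2: 0.05, -2: 0.05}
    for d in (3, 4, 5):
        probs[d] = probs[-d] = 0.02
    outer = [d for d in range(6, max_offset + 1)]
    rem = 1.0 - sum(probs.values())
    for d in outer:
        probs[d] = probs[-d] = rem / (2 * len(outer))
    return probs


NO_JITTER = {0: 1.0}

#: pentamer written (in sense orientation) at [cpa, cpa+4] of every true
#: site so true sites never satisfy the A-rich mispriming rule
_SAFE_DOWNSTREAM = "TCAGC"


# --------------------------------------------------------------------------
# Truth containers
# --------------------------------------------------------------------------

@dataclass
class SimSite:
    position: int           # 1-based CPA coordinate (last transcribed base)
    pas_motif: str          # RNA hexamer written upstream ('' if PAS-less)
    pas_offset: int         # nt from motif end to the CPA base
    utr_length: int         # genomic UTR length from stop codon


@dataclass
class SimGene:
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    stop_codon: int
    sites: list[SimSite] = field(default_factory=list)
    biotype: str = "protein_coding"

    def to_gene_model(self) -> GeneModel:
        return GeneModel(
            gene_id=self.gene_id, biotype=self.biotype,
            contig=self.contig, strand=self.strand,
            exons=tuple(tuple(e) for e in self.exons),
            cds=tuple(tuple(c) for c in self.cds),
        )


@dataclass
class SimTruth:
    """Full simulator ground truth; the oracle for every recovery test."""

    seed: int
    contig_lengths: dict[str, int]
    genes: list[SimGene] = field(default_factory=list)
    traps: list[tuple[str, str, int]] = field(default_factory=list)
    jitter: dict[int, float] = field(default_factory=default_jitter)
    # sample -> condition label
    samples: dict[str, str] = field(default_factory=dict)
    # sample -> gene_id -> relative expression weight
    expression: dict[str, dict[str, float]] = field(default_factory=dict)
    # sample -> gene_id -> usage fraction per isoform (5'->3' order)
    usage: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    switched_genes: list[str] = field(default_factory=list)

    def gene(self, gene_id: str) -> SimGene:
        return next(g for g in self.genes if g.gene_id == gene_id)

    def gene_models(self) -> dict[str, GeneModel]:
        return {g.gene_id: g.to_gene_model() for g in self.genes}

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | os.PathLike) -> None:
        payload = asdict(self)
        payload["jitter"] = {str(k): v for k, v in self.jitter.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["jitter"] = {int(k): v for k, v in payload["jitter"].items()}
        payload["genes"] = [
            SimGene(
                gene_id=g["gene_id"], contig=g["contig"], strand=g["strand"],
                exons=[tuple(e) for e in g["exons"]],
                cds=[tuple(c) for c in g["cds"]],
                stop_codon=g["stop_codon"],
                sites=[SimSite(**s) for s in g["sites"]],
                biotype=g["biotype"],
            )
            for g in payload["genes"]
        ]
        payload["traps"] = [tuple(t) for t in payload["traps"]]
        return cls(**payload)


# --------------------------------------------------------------------------
# Genome construction
# --------------------------------------------------------------------------

class GenomeBuilder:
    """Mutable genome the annotation step writes motifs into."""

    def __init__(self, contigs: dict[str, list[str]]):
        self.contigs = contigs

    def write_sense(self, contig: str, strand: str,
                    lo: int, hi: int, sense_seq: str) -> None:
        """Place ``sense_seq`` so the transcript strand reads it 5'->3' over
        the genomic interval [lo, hi] (1-based closed)."""
        assert hi - lo + 1 == len(sense_seq)
        ref = sense_seq if strand == "+" else reverse_complement(sense_seq)
        seq = self.contigs[contig]
        seq[lo - 1 : hi] = list(ref)

    def to_genome(self) -> GenomeSequence:
        return GenomeSequence({c: "".join(s) for c, s in self.contigs.items()})


def _break_at_runs(bases: np.ndarray, run_base: str, max_run: int,
                   sub: str) -> None:
    run = 0
    for i in range(len(bases)):
        if bases[i] == run_base:
            run += 1
            if run >= max_run:
                bases[i] = sub
                run = 0
        else:
            run = 0


def make_genome(
    n_contigs: int = 1,
    length: int = 20_000,
    gc: float = 0.5,
    n_traps: int = 0,
    seed: int = 0,
    contig_names: list[str] | None = None,
    trap_run: int = 10,
) -> tuple[GenomeBuilder, list[tuple[str, str, int]]]:
    """Random genome plus A-homopolymer mispriming traps.

    Background sequence contains no A- or T-run of 8+ so the only A-rich
    tracts are the programmed traps; each trap is an A-run of ``trap_run``
    bases (alternating strands) whose upstream PAS window is scrubbed of
    A/U so no PAS hexamer can rescue it.  Returns the mutable builder and
    the trap list as (contig, strand, cpa_position).
    """
    if length < 10_000:
        raise ValueError("contig length must be >= 10,000")
    rng = np.random.default_rng(seed)
    if contig_names is None:
        contig_names = [f"chr{i+1}" for i in range(n_contigs)]
    if len(contig_names) != n_contigs:
        raise ValueError("contig_names length mismatch")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))
    contigs: dict[str, list[str]] = {}
    for name in contig_names:
        bases = alphabet[rng.choice(4, size=length, p=p)]
        _break_at_runs(bases, "A", 7, "C")
        _break_at_runs(bases, "T", 7, "G")
        contigs[name] = list(bases)
    builder = GenomeBuilder(contigs)

    traps: list[tuple[str, str, int]] = []
    if n_traps:
        per_contig = [n_traps // n_contigs + (1 if i < n_traps % n_contigs else 0)
                      for i in range(n_contigs)]
        for name, k in zip(contig_names, per_contig):
            # deterministic, well-separated slots in the back half of the contig
            zone_lo, zone_hi = length // 2, length - 200
            if k and (zone_hi - zone_lo) // max(k, 1) < 120:
                raise ValueError("trap density too high for contig length")
            for j in range(k):
                s = zone_lo + j * ((zone_hi - zone_lo) // max(k, 1)) + 100
                strand = "+" if j % 2 == 0 else "-"
                if strand == "+":
                    cpa = s
                    builder.write_sense(name, "+", s, s + trap_run - 1,
                                        "A" * trap_run)
                    scrub_lo, scrub_hi = s - 30, s - 1
                else:
                    cpa = s + trap_run - 1
                    builder.write_sense(name, "-", s, s + trap_run - 1,
                                        "A" * trap_run)
                    scrub_lo, scrub_hi = s + trap_run, s + trap_run + 29
                scrub = "".join(rng.choice(["C", "G"], size=30))
                builder.write_sense(name, strand, scrub_lo, scrub_hi, scrub)
                traps.append((name, strand, cpa))
    return builder, traps


# --------------------------------------------------------------------------
# Annotation construction
# --------------------------------------------------------------------------

# offsets of the '+' layout relative to the gene slot start (1-based below)
_EXON1_LEN = 150
_INTRON_LEN = 100
_CDS1 = (30, 149)
_STOP_OFF = 350           # 3'-most CDS base
_FIRST_UTR = 60           # proximal site sits 60 nt past the stop codon
_SITE_SPACING = 90
_TAIL = 30                # terminal exon extends past the distal site


def _gene_span(n_sites: int) -> int:
    return _STOP_OFF + _FIRST_UTR + _SITE_SPACING * (n_sites - 1) + _TAIL


def make_annotation(
    builder: GenomeBuilder,
    traps: list[tuple[str, str, int]],
    n_genes: int,
    isoforms_per_gene: int | list[int] = 2,
    seed: int = 0,
    inter_gene_space: int = 1700,
    pas_offset: int = 19,
    pas_motif: str = "AAUAAA",
    x_contig: str | None = None,
) -> SimTruth:
    """Place genes with tandem CPA sites on the builder's contigs.

    Each gene gets a two-exon structure with CDS ending at a stop codon and
    ``isoforms_per_gene`` tandem CPA sites downstream of it; a PAS hexamer
    is written ending ``pas_offset`` nt upstream of every site, the
    surrounding scan window is scrubbed of competing motifs, and the
    downstream pentamer is made non-A-rich so true sites are never
    misprime-filtered by construction.  Genes alternate strands; spacing
    exceeds the 1500 nt assignment window so assignments are unambiguous.
    Raises on overcrowding.
    """
    if inter_gene_space <= 1500:
        raise ValueError(
            "inter_gene_space must exceed the 1500 nt assignment window; "
            "closer spacing would make gene assignment ambiguous"
        )
    rng = np.random.default_rng(seed)
    if isinstance(isoforms_per_gene, int):
        n_sites_list = [isoforms_per_gene] * n_genes
    else:
        n_sites_list = list(isoforms_per_gene)
        if len(n_sites_list) != n_genes:
            raise ValueError("isoforms_per_gene list length != n_genes")
    if any(k < 1 or k > 3 for k in n_sites_list):
        raise ValueError("isoforms per gene must be 1..3")

    contig_names = list(builder.contigs)
    lengths = {c: len(builder.contigs[c]) for c in contig_names}
    trap_zones: dict[str, list[tuple[int, int]]] = {}
    for (c, _, pos) in traps:
        trap_zones.setdefault(c, []).append((pos - 60, pos + 60))

    truth = SimTruth(seed=seed, contig_lengths=lengths,
                     jitter=default_jitter())
    cursors = {c: 200 for c in contig_names}
    ci = 0
    dna_motif = pas_motif.replace("U", "T")

    for gi in range(n_genes):
        k = n_sites_list[gi]
        span = _gene_span(k)
        placed = False
        for _ in range(len(contig_names)):
            contig = contig_names[ci % len(contig_names)]
            ci += 1
            s = cursors[contig]
            # skip trap zones
            moved = True
            while moved:
                moved = False
                for (lo, hi) in trap_zones.get(contig, ()):
                    if s <= hi and s + span >= lo:
                        s = hi + 50
                        moved = True
            if s + span < lengths[contig] - 200:
                cursors[contig] = s + span + inter_gene_space
                placed = True
                break
        if not placed:
            raise ValueError(
                f"overcrowding: gene {gi} (span {span}) does not fit; "
                f"increase contig length or reduce n_genes"
            )
        strand = "+" if gi % 2 == 0 else "-"
        gene_id = f"g{gi:04d}"
        L = span

        def m(off: int) -> int:
            """Map a '+'-layout offset to a genomic coordinate."""
            return s + off if strand == "+" else s + L - off

        def ival(o1: int, o2: int) -> tuple[int, int]:
            a, b = m(o1), m(o2)
            return (a, b) if a <= b else (b, a)

        site_offs = [_STOP_OFF + _FIRST_UTR + _SITE_SPACING * j
                     for j in range(k)]
        exon1 = ival(0, _EXON1_LEN - 1)
        exon2 = ival(_EXON1_LEN + _INTRON_LEN, site_offs[-1] + _TAIL - 1)
        cds1 = ival(*_CDS1)
        cds2 = ival(_EXON1_LEN + _INTRON_LEN, _STOP_OFF)
        stop = m(_STOP_OFF)
        gene = SimGene(
            gene_id=gene_id, contig=contig, strand=strand,
            exons=sorted([exon1, exon2]), cds=sorted([cds1, cds2]),
            stop_codon=stop,
        )
        for j, off in enumerate(site_offs):
            pos = m(off)
            # scrub the PAS scan region, then write the PAS at pas_offset
            lo, hi = (pos - 31, pos - 1) if strand == "+" else (pos + 1, pos + 31)
            scrub = "".join(rng.choice(["C", "G"], size=31))
            builder.write_sense(contig, strand, lo, hi, scrub)
            mlo, mhi = ((pos - pas_offset - 5, pos - pas_offset)
                        if strand == "+"
                        else (pos + pas_offset, pos + pas_offset + 5))
            builder.write_sense(contig, strand, mlo, mhi, dna_motif)
            dlo, dhi = ((pos, pos + 4) if strand == "+" else (pos - 4, pos))
            builder.write_sense(contig, strand, dlo, dhi, _SAFE_DOWNSTREAM)
            gene.sites.append(SimSite(
                position=pos, pas_motif=pas_motif, pas_offset=pas_offset,
                utr_length=off - _STOP_OFF,
            ))
        truth.genes.append(gene)
    truth.traps = list(traps)
    if x_contig is not None and x_contig not in contig_names:
        raise ValueError(f"x_contig {x_contig!r} not among contigs")
    return truth


def write_gff3(truth: SimTruth, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in truth.genes:
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            fh.write(f"{g.contig}\tsim\tgene\t{min(s for s,_ in g.exons)}\t"
                     f"{max(e for _,e in g.exons)}\t.\t{g.strand}\t.\t{attrs}\n")
            mrna_id = f"{g.gene_id}.t1"
            fh.write(f"{g.contig}\tsim\tmRNA\t{min(s for s,_ in g.exons)}\t"
                     f"{max(e for _,e in g.exons)}\t.\t{g.strand}\t.\t"
                     f"ID={mrna_id};Parent={g.gene_id}\n")
            for (s, e) in g.exons:
                fh.write(f"{g.contig}\tsim\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                         f"Parent={mrna_id}\n")
            for (s, e) in g.cds:
                fh.write(f"{g.contig}\tsim\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                         f"Parent={mrna_id}\n")


# --------------------------------------------------------------------------
# Expression / usage programming
# --------------------------------------------------------------------------

def program_samples(
    truth: SimTruth,
    samples: dict[str, str],
    seed: int = 0,
    switch_genes: list[str] | None = None,
    switch_shift: float = 0.6,
    conditions: tuple[str, str] | None = None,
    x_contig: str | None = None,
    x_ratio: float | dict[str, float] = 1.0,
) -> None:
    """Assign per-sample expression weights and per-isoform usage fractions.

    Expression weights are lognormal(0, 1) per gene, shared across samples
    (scaled by ``x_ratio`` for genes on ``x_contig``).  Base usage fractions
    come from a flat Dirichlet tightened toward the proximal isoform; genes
    in ``switch_genes`` have their usage vector shifted by ``switch_shift``
    (in usage-fraction units, >= 0.4 meaning a 40-percentage-point switch)
    from the first condition to the second.
    """
    rng = np.random.default_rng(seed)
    truth.samples = dict(samples)
    labels = list(dict.fromkeys(samples.values()))
    if conditions is None:
        conditions = tuple(labels[:2]) if len(labels) >= 2 else (labels[0],) * 2
    switch_genes = switch_genes or []
    base_expr = {g.gene_id: float(rng.lognormal(0.0, 1.0)) for g in truth.genes}
    base_usage: dict[str, list[float]] = {}
    for g in truth.genes:
        k = len(g.sites)
        if k == 1:
            base_usage[g.gene_id] = [1.0]
        else:
            u = rng.dirichlet(np.full(k, 8.0))
            base_usage[g.gene_id] = [float(x) for x in u]

    def shifted(u: list[float]) -> list[float]:
        # move `switch_shift` of usage from the most-used to the least-used
        v = list(u)
        hi = int(np.argmax(v))
        lo = int(np.argmin(v))
        delta = min(switch_shift, v[hi] - 1e-6)
        v[hi] -= delta
        v[lo] += delta
        return v

    for sample, cond in samples.items():
        expr = {}
        usage = {}
        for g in truth.genes:
            w = base_expr[g.gene_id]
            if x_contig is not None and g.contig == x_contig:
                r = x_ratio.get(sample, 1.0) if isinstance(x_ratio, dict) else x_ratio
                w *= r
            expr[g.gene_id] = w
            u = base_usage[g.gene_id]
            if g.gene_id in switch_genes and cond == conditions[1]:
                u = shifted(u)
            usage[g.gene_id] = list(u)
        truth.expression[sample] = expr
        truth.usage[sample] = usage
    truth.switched_genes = list(switch_genes)


# --------------------------------------------------------------------------
# Read simulation
# --------------------------------------------------------------------------

def simulate_sample(
    truth: SimTruth,
    sample_id: str,
    depth: int,
    seed: int = 0,
    jitter: dict[int, float] | None = None,
    trap_rate: float = 0.0,
    site_counts: dict[tuple[str, str, int], int] | None = None,
) -> list[EndRecord]:
    """Draw ``depth`` 3'-end reads for one sample.

    Reads are allocated multinomially across genes by programmed expression,
    within genes across isoforms by programmed usage, and each read's
    observed end is its true site plus a jitter offset (applied in
    transcript orientation).  An additional ``trap_rate`` fraction of depth
    is emitted at mispriming trap positions.  Returns position-collapsed
    EndRecords sorted by coordinate; when ``site_counts`` (a dict keyed by
    (contig, strand, true position)) is passed, the number of reads emitted
    from each true site is accumulated into it — the sidecar truth labels
    for recovery tests.
    """
    if sample_id not in truth.expression:
        raise KeyError(f"sample {sample_id!r} has no programmed expression")
    rng = np.random.default_rng(seed)
    if depth <= 0:
        from .formats_io import logger
        logger.warning("sample %s simulated with zero depth", sample_id)
        return []
    jitter = truth.jitter if jitter is None else jitter
    offsets = np.array(sorted(jitter))
    probs = np.array([jitter[o] for o in offsets])
    probs = probs / probs.sum()

    gene_ids = [g.gene_id for g in truth.genes]
    weights = np.array([truth.expression[sample_id][gid] for gid in gene_ids])
    gene_reads = rng.multinomial(depth, weights / weights.sum())

    counts: dict[tuple[str, str, int], int] = {}
    for gene, n in zip(truth.genes, gene_reads):
        if n == 0:
            continue
        usage = np.array(truth.usage[sample_id][gene.gene_id])
        iso_reads = rng.multinomial(n, usage / usage.sum())
        sign = 1 if gene.strand == "+" else -1
        for site, m in zip(gene.sites, iso_reads):
            if m == 0:
                continue
            if site_counts is not None:
                skey = (gene.contig, gene.strand, site.position)
                site_counts[skey] = site_counts.get(skey, 0) + int(m)
            deltas = offsets[rng.choice(len(offsets), size=m, p=probs)]
            length = truth.contig_lengths[gene.contig]
            for d in deltas:
                pos = int(np.clip(site.position + sign * d, 1, length))
                key = (gene.contig, gene.strand, pos)
                counts[key] = counts.get(key, 0) + 1
    if trap_rate > 0.0 and truth.traps:
        n_trap = rng.binomial(depth, trap_rate)
        if n_trap:
            picks = rng.choice(len(truth.traps), size=n_trap)
            for i in picks:
                contig, strand, pos = truth.traps[i]
                key = (contig, strand, pos)
                counts[key] = counts.get(key, 0) + 1
    return [
        EndRecord(contig=c, strand=st, cpa_position=p,
                  sample=sample_id, count=n)
        for (c, st, p), n in sorted(counts.items())
    ]


# --------------------------------------------------------------------------
# Output writers
# --------------------------------------------------------------------------

def write_sample_bed(records: list[EndRecord], path: str | os.PathLike) -> None:
    """BED-like intermediate: contig, pos-1, pos, sample, count, strand."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.contig}\t{r.cpa_position - 1}\t{r.cpa_position}\t"
                     f"{r.sample}\t{r.count}\t{r.strand}\n")


def read_sample_bed(path: str | os.PathLike) -> list[EndRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            contig, _, pos, sample, count, strand = line.split("\t")[:6]
            out.append(EndRecord(contig=contig, strand=strand,
                                 cpa_position=int(pos), sample=sample,
                                 count=int(count)))
    return out


def write_sample_sam(
    records: list[EndRecord],
    genome: GenomeSequence,
    path: str | os.PathLike,
    read_len: int = 30,
) -> None:
    """Fabricate proper paired-end alignments whose Read 2 first sequenced
    base sits on each record's CPA position, so end extraction can be
    exercised from SAM input.  Read 2 is antisense to the transcript."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for contig, seq in genome.contigs.items():
            fh.write(f"@SQ\tSN:{contig}\tLN:{len(seq)}\n")
        n = 0
        lines = []
        for r in records:
            clen = genome.contig_length(r.contig)
            for _ in range(r.count):
                n += 1
                qname = f"sim{n:07d}"
                if r.strand == "+":
                    r2_start = max(1, r.cpa_position - read_len + 1)
                    r2_len = r.cpa_position - r2_start + 1
                    r1_start = max(1, r2_start - 50)
                    r1_len = min(read_len, r2_start - r1_start + 1)
                    r1 = (r.contig, r1_start, 99, r1_len)
                    r2 = (r.contig, r2_start, 147, r2_len)
                else:
                    r2_start = r.cpa_position
                    r2_len = min(read_len, clen - r2_start + 1)
                    r1_start = min(clen, r2_start + r2_len + 20)
                    r1_len = min(read_len, clen - r1_start + 1)
                    r1 = (r.contig, r1_start, 83, r1_len)
                    r2 = (r.contig, r2_start, 163, r2_len)
                for (contig, start, flag, length), mate in ((r1, r2), (r2, r1)):
                    seq = genome.fetch(contig, start, start + length - 1, "+")
                    lines.append((
                        start,
                        f"{qname}\t{flag}\t{contig}\t{start}\t60\t{length}M\t="
                        f"\t{mate[1]}\t0\t{seq}\t{'I' * length}\tNM:i:0\n",
                    ))
        for _, line in sorted(lines, key=lambda t: t[0]):
            fh.write(line)


# --------------------------------------------------------------------------
# One-call world builder
# --------------------------------------------------------------------------

def simulate_world(
    n_genes: int = 20,
    isoforms_per_gene: int | list[int] = 2,
    samples: dict[str, str] | None = None,
    depth: int = 5_000,
    seed: int = 0,
    n_contigs: int = 1,
    contig_length: int = 80_000,
    n_traps: int = 0,
    trap_rate: float = 0.0,
    jitter: dict[int, float] | None = None,
    switch_genes: list[str] | None = None,
    switch_shift: float = 0.6,
    x_contig: str | None = None,
    x_ratio: float | dict[str, float] = 1.0,
    contig_names: list[str] | None = None,
    site_counts: dict[tuple[str, str, int], int] | None = None,
) -> tuple[GenomeSequence, SimTruth, dict[str, list[EndRecord]]]:
    """Build genome + annotation + per-sample reads in one seeded call."""
    samples = samples or {"S1": "A", "S2": "A", "S3": "B", "S4": "B"}
    builder, traps = make_genome(
        n_contigs=n_contigs, length=contig_length, gc=0.5,
        n_traps=n_traps, seed=seed, contig_names=contig_names,
    )
    truth = make_annotation(
        builder, traps, n_genes=n_genes,
        isoforms_per_gene=isoforms_per_gene, seed=seed + 1,
        x_contig=x_contig,
    )
    program_samples(
        truth, samples, seed=seed + 2, switch_genes=switch_genes,
        switch_shift=switch_shift, x_contig=x_contig, x_ratio=x_ratio,
    )
    genome = builder.to_genome()
    reads = {
        sample: simulate_sample(
            truth, sample, depth, seed=seed + 10 + i,
            jitter=jitter, trap_rate=trap_rate, site_counts=site_counts,
        )
        for i, sample in enumerate(samples)
    }
    return genome, truth, reads
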