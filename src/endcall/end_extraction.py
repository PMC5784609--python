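"""Convert paired alignments into strand-aware transcript 3'-end observations
and build the cross-sample position universe.

The library design sequences Read 2 from inside the polyA tail into the
transcript, so Read 2 is antisense to the mRNA and its first sequenced base
sits on the cleavage-and-polyadenylation (CPA) site — the last transcribed
base.  On the genome this means:

* transcript on '+': Read 2 maps to the reverse strand and its first
  sequenced base is the highest aligned coordinate (alignment end);
* transcript on '-': Read 2 maps forward and its first base is the alignment
  start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam

from .formats_io import PipelineConfig, logger
from .read_prep import passes_identity


@dataclass(frozen=True)
class EndRecord:
    """One observed transcript 3' end (1-based CPA coordinate)."""

    contig: str
    strand: str
    cpa_position: int
    sample: str
    count: int = 1

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.count < 1:
            raise ValueError("count must be >= 1")


PositionKey = tuple[str, str, int]   # (contig, strand, cpa_position)


@dataclass
class PositionTally:
    """Per-sample read counts keyed by (contig, strand, position)."""

    counts: dict[PositionKey, dict[str, int]] = field(default_factory=dict)
    samples: set[str] = field(default_factory=set)

    def add(self, record: EndRecord) -> None:
        key = (record.contig, record.strand, record.cpa_position)
        per_sample = self.counts.setdefault(key, {})
        per_sample[record.sample] = per_sample.get(record.sample, 0) + record.count
        self.samples.add(record.sample)

    def add_all(self, records: Iterable[EndRecord]) -> None:
        for rec in records:
            self.add(rec)

    def register_sample(self, sample: str) -> None:
        """Declare a library even if it contributed no reads yet."""
        self.samples.add(sample)

    def total_reads(self) -> int:
        return sum(sum(d.values()) for d in self.counts.values())

    def total_at(self, key: PositionKey) -> int:
        return sum(self.counts.get(key, {}).values())


def extract_ends(
    pairs: Iterable[tuple[pysam.AlignedSegment, pysam.AlignedSegment]],
    sample_id: str,
    identity_threshold: float | None = 0.95,
) -> Iterator[EndRecord]:
    """Yield one EndRecord per proper pair, from Read 2's first sequenced
    base.

    Pairs whose mates map to the same strand (ambiguous transcript strand)
    are skipped and tallied; when ``identity_threshold`` is set, Read 2
    alignments with NM-based identity ≤ threshold are excluded.
    """
    skipped = 0
    for r1, r2 in pairs:
        if r1.is_reverse == r2.is_reverse:
            skipped += 1
            continue
        if identity_threshold is not None and r2.has_tag("NM"):
            aligned = r2.query_alignment_length or 0
            if not passes_identity(r2.get_tag("NM"), aligned, identity_threshold):
                skipped += 1
                continue
        if r2.is_reverse:
            strand = "+"
            cpa = r2.reference_end          # pysam end is exclusive 0-based
        else:
            strand = "-"
            cpa = r2.reference_start + 1
        yield EndRecord(
            contig=r2.reference_name, strand=strand,
            cpa_position=cpa, sample=sample_id,
        )
    if skipped:
        logger.info("sample %s: %d pairs skipped during end extraction",
                    sample_id, skipped)


def tally_ends(records: Iterable[EndRecord],
               tally: PositionTally | None = None) -> PositionTally:
    tally = tally if tally is not None else PositionTally()
    tally.add_all(records)
    return tally


def build_universe(
    tally: PositionTally, config: PipelineConfig | None = None
) -> PositionTally:
    """Apply the cross-sample support rule: a position enters the universe
    only if at least one read supports it in at least ``min_samples_support``
    libraries; retained positions keep their full summed counts.
    """
    config = config or PipelineConfig()
    k = config.min_samples_support
    if len(tally.samples) < k:
        raise ValueError(
            f"universe requires >= {k} libraries, got {len(tally.samples)}"
        )
    kept = PositionTally(samples=set(tally.samples))
    removed_positions = removed_reads = 0
    for key, per_sample in tally.counts.items():
        if sum(1 for c in per_sample.values() if c > 0) >= k:
            kept.counts[key] = dict(per_sample)
        else:
            removed_positions += 1
            removed_reads += sum(per_sample.values())
    logger.info(
        "universe: kept %d positions, removed %d (%d reads) below %d-sample support",
        len(kept.counts), removed_positions, removed_reads, k,
    )
    return kept
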