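"""Pre-alignment read handling: barcode demultiplexing, length filtering and
the Read-2 rescue trims applied before remapping.

Alignment itself is out of scope; the pipeline consumes SAM/BAM produced by an
external spliced aligner (or by the simulator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .formats_io import logger

UNDETERMINED = "undetermined"


@dataclass
class RawReadPair:
    """One paired-end read prior to alignment.

    The sample barcode is the first ``barcode_len`` bases of Read 1; in the
    library design Read 2 begins at the last transcribed base before the
    polyA tail, so mis-anchored reads start with a run of templated T.
    """

    read1_seq: str
    read1_qual: str
    read2_seq: str
    read2_qual: str
    barcode: str = ""


@dataclass
class DemuxReport:
    assigned: dict[str, int] = field(default_factory=dict)
    undetermined: int = 0
    dropped_short: int = 0

    @property
    def total(self) -> int:
        return sum(self.assigned.values()) + self.undetermined

    def to_tsv(self) -> str:
        lines = ["sample\tpairs\tdropped_short\tundetermined"]
        for sample in sorted(self.assigned):
            lines.append(f"{sample}\t{self.assigned[sample]}\t\t")
        lines.append(f"TOTAL\t{self.total}\t{self.dropped_short}\t{self.undetermined}")
        return "\n".join(lines) + "\n"


def _hamming1_variants(code: str) -> Iterator[str]:
    for i in range(len(code)):
        for base in "ACGT":
            if base != code[i]:
                yield code[:i] + base + code[i + 1 :]


def demultiplex(
    pairs: Iterable[RawReadPair],
    barcode_map: dict[str, str],
    barcode_len: int = 6,
    allow_one_mismatch: bool = False,
    report: DemuxReport | None = None,
) -> Iterator[tuple[str, RawReadPair]]:
    """Route each pair to a sample by the barcode at the start of Read 1.

    The barcode is removed from Read 1.  Matching is exact by default; with
    ``allow_one_mismatch`` a barcode uniquely within Hamming distance 1 of an
    expected code is accepted.  Yields ``(sample, trimmed_pair)`` where
    sample is :data:`UNDETERMINED` for unassignable barcodes.
    """
    for code, sample in barcode_map.items():
        if len(code) != barcode_len:
            raise ValueError(f"barcode {code!r} is not {barcode_len} nt")
    lookup = {code.upper(): sample for code, sample in barcode_map.items()}
    if len(lookup) != len(barcode_map):
        raise ValueError("duplicate barcodes in barcode_map")
    if allow_one_mismatch:
        fuzzy: dict[str, str | None] = {}
        for code, sample in list(lookup.items()):
            for variant in _hamming1_variants(code):
                # a variant reachable from two barcodes is ambiguous
                fuzzy[variant] = None if variant in fuzzy else sample
        for variant, sample in fuzzy.items():
            if sample is not None and variant not in lookup:
                lookup[variant] = sample

    report = report if report is not None else DemuxReport()
    for pair in pairs:
        code = pair.read1_seq[:barcode_len].upper()
        sample = lookup.get(code)
        trimmed = RawReadPair(
            read1_seq=pair.read1_seq[barcode_len:],
            read1_qual=pair.read1_qual[barcode_len:],
            read2_seq=pair.read2_seq,
            read2_qual=pair.read2_qual,
            barcode=code,
        )
        if sample is None:
            report.undetermined += 1
            yield UNDETERMINED, trimmed
        else:
            report.assigned[sample] = report.assigned.get(sample, 0) + 1
            yield sample, trimmed


def length_filter(
    pairs: Iterable[RawReadPair],
    min_read_len: int = 50,
    report: DemuxReport | None = None,
) -> Iterator[RawReadPair]:
    """Drop pairs where either mate is shorter than ``min_read_len`` (<50 nt
    by default; a mate of exactly 50 nt is kept)."""
    dropped = 0
    for pair in pairs:
        if len(pair.read1_seq) < min_read_len or len(pair.read2_seq) < min_read_len:
            dropped += 1
            continue
        yield pair
    if report is not None:
        report.dropped_short += dropped
    if dropped:
        logger.info("length filter dropped %d short pairs", dropped)


def trim_leading_T(seq: str) -> tuple[str, int]:
    """Remove the maximal leading run of T (templated polyA read-through on
    the antisense Read 2).  Returns (trimmed, run length)."""
    n = len(seq) - len(seq.lstrip("Tt"))
    return seq[n:], n


def truncate_for_remap(seq: str, length: int = 50) -> str:
    """Truncate Read 2 to its first ``length`` bases before remapping, to
    strip occasional palindromic artifacts at the read tail."""
    return seq[:length]


def alignment_identity(edit_distance: int, aligned_length: int) -> float:
    """Fractional identity of an alignment (1 - edits/length)."""
    if aligned_length <= 0:
        return 0.0
    return 1.0 - edit_distance / aligned_length


def passes_identity(edit_distance: int, aligned_length: int,
                    threshold: float = 0.95) -> bool:
    """Identity filter applied when consuming alignments: reads with
    identity ≤ ``threshold`` are excluded (i.e. strictly greater passes)."""
    return alignment_identity(edit_distance, aligned_length) > threshold
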