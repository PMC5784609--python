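"""Greedy abundance-ranked clustering of 3'-end positions into representative
CPA sites.

Positions are processed in descending order of summed read count; each seed
absorbs every still-unassigned position within ± ``cluster_window`` nt on the
same contig and strand, and absorbed positions cannot seed later clusters.
Ties in count are broken toward the 3'-most position of the transcript strand
(higher coordinate on '+', lower on '-'); across contigs, lexical contig
order makes the procedure a total order and hence deterministic regardless of
input iteration order.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

from .end_extraction import PositionTally
from .formats_io import PipelineConfig


@dataclass(frozen=True)
class CpaCluster:
    """A representative CPA site with its absorbed member positions."""

    cluster_id: str
    contig: str
    strand: str
    representative: int
    members: tuple[tuple[int, int], ...]     # (position, total count), ascending
    per_sample: dict[str, int]

    @property
    def total(self) -> int:
        return sum(c for _, c in self.members)

    @property
    def n_members(self) -> int:
        return len(self.members)


def _seed_order_key(item):
    (contig, strand, pos), total = item
    # descending count; then contigs lexically; then 3'-most first
    three_prime_first = -pos if strand == "+" else pos
    return (-total, contig, strand, three_prime_first)


def cluster_sites(
    universe: PositionTally, config: PipelineConfig | None = None
) -> list[CpaCluster]:
    """Partition the filtered position universe into CPA clusters.

    Every position belongs to exactly one cluster; cluster per-sample counts
    are the per-sample sums over members (members are treated as imprecise
    reads of the representative site).
    """
    config = config or PipelineConfig()
    window = config.cluster_window

    totals = {key: sum(d.values()) for key, d in universe.counts.items()}
    # per (contig, strand): ascending positions for window lookups
    by_group: dict[tuple[str, str], list[int]] = {}
    for (contig, strand, pos) in totals:
        by_group.setdefault((contig, strand), []).append(pos)
    for positions in by_group.values():
        positions.sort()

    assigned: set[tuple[str, str, int]] = set()
    clusters: list[CpaCluster] = []
    for (contig, strand, rep), total in sorted(totals.items(), key=_seed_order_key):
        key = (contig, strand, rep)
        if key in assigned:
            continue
        positions = by_group[(contig, strand)]
        lo = bisect_left(positions, rep - window)
        hi = bisect_right(positions, rep + window)
        members: list[tuple[int, int]] = []
        per_sample: dict[str, int] = {}
        for pos in positions[lo:hi]:
            mkey = (contig, strand, pos)
            if mkey in assigned:
                continue
            assigned.add(mkey)
            members.append((pos, totals[mkey]))
            for sample, count in universe.counts[mkey].items():
                per_sample[sample] = per_sample.get(sample, 0) + count
        clusters.append(
            CpaCluster(
                cluster_id=f"{contig}:{rep}:{strand}",
                contig=contig,
                strand=strand,
                representative=rep,
                members=tuple(members),
                per_sample=per_sample,
            )
        )
    clusters.sort(key=lambda c: (c.contig, c.representative, c.strand))
    return clusters


def clusters_to_rows(clusters: list[CpaCluster], samples: list[str]) -> list[dict]:
    """Flatten clusters to table rows with one count column per sample."""
    rows = []
    for c in clusters:
        row = {
            "cluster_id": c.cluster_id,
            "contig": c.contig,
            "strand": c.strand,
            "representative": c.representative,
            "n_members": c.n_members,
            "total": c.total,
        }
        for s in samples:
            row[s] = c.per_sample.get(s, 0)
        rows.append(row)
    return rows
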