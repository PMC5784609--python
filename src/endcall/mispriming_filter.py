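"""Filter CPA clusters caused by internal oligo-dT priming on genomically
templated A-rich tracts.

A cluster is suspect when the sense-strand genomic window of five bases
anchored at the representative CPA base starts with an adenosine and contains
at least four adenosines: an oligo-dT primer annealing there is
indistinguishable from one annealing to a real polyA tail.  Suspect clusters
with no recognisable PAS hexamer 8–25 nt upstream are removed as mispriming
artifacts; suspect clusters that do carry a PAS are set aside as potential
true positives (flagged) but excluded from the final site set.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cpa_clustering import CpaCluster
from .formats_io import GenomeSequence, PipelineConfig, logger
from .gene_annotation import PasHit, scan_pas

RETAINED = "retained"
REMOVED_MISPRIMING = "removed_mispriming"
FLAGGED_PAS_POSITIVE = "flagged_pas_positive"


@dataclass(frozen=True)
class FilterVerdict:
    cluster_id: str
    status: str
    downstream_seq: str
    pas: PasHit | None


def downstream_window(
    cluster: CpaCluster, genome: GenomeSequence, width: int
) -> str:
    """Sense-strand bases at [cpa, cpa + width - 1] in transcript
    orientation; bases past the contig edge read as N (non-A)."""
    if cluster.strand == "+":
        return genome.fetch_padded(
            cluster.contig, cluster.representative,
            cluster.representative + width - 1, "+",
        )
    return genome.fetch_padded(
        cluster.contig, cluster.representative - width + 1,
        cluster.representative, "-",
    )


def is_a_rich(window: str, min_a: int) -> bool:
    """First base A and at least ``min_a`` adenosines in the window."""
    return bool(window) and window[0] == "A" and window.count("A") >= min_a


def apply_mispriming_filter(
    clusters: list[CpaCluster],
    genome: GenomeSequence,
    config: PipelineConfig | None = None,
) -> tuple[list[CpaCluster], list[FilterVerdict]]:
    """Classify every cluster as retained / removed / flagged.

    Returns the final (retained-only) cluster list and the full verdict
    table; flagged clusters are excluded from the final set.
    """
    config = config or PipelineConfig()
    width = config.mispriming_downstream_window
    final: list[CpaCluster] = []
    verdicts: list[FilterVerdict] = []
    n_removed = n_flagged = 0
    for cluster in clusters:
        window = downstream_window(cluster, genome, width)
        pas = scan_pas(
            cluster.contig, cluster.strand, cluster.representative,
            genome, config,
        )
        if is_a_rich(window, config.mispriming_min_A):
            if pas is None:
                status = REMOVED_MISPRIMING
                n_removed += 1
            else:
                status = FLAGGED_PAS_POSITIVE
                n_flagged += 1
        else:
            status = RETAINED
            final.append(cluster)
        verdicts.append(
            FilterVerdict(cluster.cluster_id, status, window, pas)
        )
    logger.info(
        "mispriming filter: retained %d, removed %d, flagged (PAS-positive) %d",
        len(final), n_removed, n_flagged,
    )
    return final, verdicts
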