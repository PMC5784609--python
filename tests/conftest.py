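import numpy as np
import pytest

from endcall import (GeneIndex, GenomeSequence, PipelineConfig, PositionTally,
                     build_isoform_table, build_universe, cluster_sites)
from endcall import synthetic_data as sim


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def noise_free_world():
    """Jitter off, traps off: pipeline output must equal truth exactly."""
    site_counts = {}
    genome, truth, reads = sim.simulate_world(
        n_genes=10, isoforms_per_gene=2, depth=6000, seed=41,
        jitter=sim.NO_JITTER, site_counts=site_counts,
    )
    return genome, truth, reads, site_counts


def run_site_calling(reads_by_sample, config=None):
    """extract/tally -> universe -> cluster, from simulator end records."""
    config = config or PipelineConfig()
    tally = PositionTally()
    for sample, records in reads_by_sample.items():
        tally.register_sample(sample)
        tally.add_all(records)
    universe = build_universe(tally, config)
    return cluster_sites(universe, config)


def make_genome_with(contig: str, length: int, inserts: dict[int, str],
                     fill: str = "C") -> GenomeSequence:
    """Toy genome: background of ``fill`` with sequences written at 1-based
    positions."""
    seq = [fill] * length
    for pos, sub in inserts.items():
        seq[pos - 1 : pos - 1 + len(sub)] = list(sub)
    return GenomeSequence({contig: "".join(seq)})
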