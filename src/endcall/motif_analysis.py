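"""Count cis-regulatory motifs (UUGUU, Puf/GLD-1-class patterns) in 3'UTR and
transcript sequences and relate motif density to expression fold-changes.

Motif patterns use the IUPAC nucleotide alphabet over RNA (T and U are
equivalent); overlapping occurrences are counted, so UUGUUGUU contains two
UUGUU matches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import GeneModel, GenomeSequence, logger

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

#: Default GLD-1 (STAR/quaking family) binding element.  The consensus is a
#: package assumption (see docs/methods.md) and is configurable.
GLD1_DEFAULT_PATTERN = "UACUCAH"


@dataclass(frozen=True)
class MotifSpec:
    name: str
    pattern: str          # IUPAC over {A,C,G,U(,T)} plus degeneracy codes

    def __post_init__(self):
        if len(self.pattern) < 3:
            raise ValueError("motif patterns must be at least 3 nt")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"unknown IUPAC codes {sorted(bad)} in {self.pattern!r}")

    @property
    def expanded(self) -> tuple[frozenset, ...]:
        return tuple(frozenset(IUPAC[c]) for c in self.pattern.upper())


UUGUU = MotifSpec("UUGUU", "UUGUU")


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def count_motif(sequence: str, motif: MotifSpec) -> int:
    """Number of (possibly overlapping) match start positions of ``motif``
    in ``sequence`` (DNA or RNA alphabet)."""
    seq = _to_rna(sequence)
    sets = motif.expanded
    k = len(sets)
    n = 0
    for i in range(len(seq) - k + 1):
        if all(seq[i + j] in sets[j] for j in range(k)):
            n += 1
    return n


def spliced_sequence(gene: GeneModel, genome: GenomeSequence,
                     three_prime_end: int | None = None) -> str:
    """Sense-strand spliced sequence of a gene's exons, optionally extended
    (or truncated) to a called 3' end such as a CPA site."""
    exons = list(gene.exons)
    if three_prime_end is not None:
        if gene.strand == "+":
            exons = [(s, min(e, three_prime_end)) for s, e in exons
                     if s <= three_prime_end]
            if exons and exons[-1][1] < three_prime_end:
                exons[-1] = (exons[-1][0], three_prime_end)
        else:
            exons = [(max(s, three_prime_end), e) for s, e in exons
                     if e >= three_prime_end]
            if exons and exons[0][0] > three_prime_end:
                exons[0] = (three_prime_end, exons[0][1])
    parts = [genome.fetch(gene.contig, s, e, "+") for s, e in exons]
    seq = "".join(parts)
    if gene.strand == "-":
        from .formats_io import reverse_complement
        seq = reverse_complement(seq)
    return seq


def utr_sequence(gene: GeneModel, genome: GenomeSequence,
                 cpa_position: int) -> str:
    """Sense-strand genomic 3'UTR sequence from the first base past the
    3'-most stop codon through the CPA base."""
    stop = gene.stop_codon_position
    if stop is None:
        raise ValueError(f"{gene.gene_id} has no stop codon")
    if gene.strand == "+":
        return genome.fetch(gene.contig, stop + 1, cpa_position, "+")
    return genome.fetch(gene.contig, cpa_position, stop - 1, "-")


def per_transcript_motif_table(
    isoforms,                      # iterable of IsoformRecord (tandem class)
    genes: dict[str, GeneModel],
    genome: GenomeSequence,
    motifs: list[MotifSpec],
) -> pd.DataFrame:
    """Motif counts in each isoform's called 3'UTR and in its full spliced
    transcript (exons extended to the called 3' end).

    Junction-spanning motifs are counted in the spliced sequence, never the
    genomic one.  Isoforms whose sequence cannot be retrieved are flagged.
    """
    rows = []
    for rec in isoforms:
        if rec.gene_id is None or rec.utr_length is None:
            continue
        gene = genes[rec.gene_id]
        row = {"gene_id": rec.gene_id, "cluster_id": rec.cluster_id,
               "utr_length": rec.utr_length, "flagged": False}
        try:
            utr = utr_sequence(gene, genome, rec.cpa_position)
            tx = spliced_sequence(gene, genome, rec.cpa_position)
        except (KeyError, ValueError):
            for m in motifs:
                row[f"{m.name}_utr"] = row[f"{m.name}_transcript"] = -1
            row["flagged"] = True
            rows.append(row)
            continue
        for m in motifs:
            row[f"{m.name}_utr"] = count_motif(utr, m)
            row[f"{m.name}_transcript"] = count_motif(tx, m)
        rows.append(row)
    return pd.DataFrame(rows)


def motif_density_vs_foldchange(
    motif_counts: pd.Series,
    fold_changes: pd.Series,
    bins: tuple[int, ...] = (0, 1, 2, 3),
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Bucket isoforms by motif count, summarize fold-change per bucket and
    report the Spearman rank correlation between motif count and
    fold-change with a seeded permutation p-value.

    The last bin is open-ended ("3+" by default).  With fewer than 10
    isoforms or a degenerate motif-count vector the correlation is reported
    as NaN with a warning flag.
    """
    common = motif_counts.index.intersection(fold_changes.index)
    x = motif_counts.loc[common].to_numpy(dtype=float)
    y = fold_changes.loc[common].to_numpy(dtype=float)
    buckets = {}
    for i, lo in enumerate(bins):
        if i + 1 < len(bins):
            mask = x == lo
            label = str(lo)
        else:
            mask = x >= lo
            label = f"{lo}+"
        buckets[label] = {
            "n": int(mask.sum()),
            "median_fc": float(np.median(y[mask])) if mask.any() else float("nan"),
        }
    warn = len(x) < 10 or len(np.unique(x)) < 2 or len(np.unique(y)) < 2
    if warn:
        if len(x) < 10:
            logger.warning("motif correlation on <10 isoforms")
        return {"buckets": buckets, "rho": float("nan"),
                "p_perm": float("nan"), "warning": True, "n": int(len(x))}
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = stats.spearmanr(x, rng.permutation(y)).statistic
    p_perm = float((np.sum(np.abs(null) >= abs(rho)) + 1) / (n_permutations + 1))
    return {"buckets": buckets, "rho": rho, "p_perm": p_perm,
            "warning": False, "n": int(len(x))}
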