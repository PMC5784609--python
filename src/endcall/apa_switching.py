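"""Differential alternative-polyadenylation (APA) testing between two
conditions, major-isoform bookkeeping and 3'UTR length-distribution
statistics.

For each gene with at least two retained isoforms, each isoform's counts are
contrasted against the collective counts of all its other isoforms in a 2x2
table (isoform vs rest, condition A vs B) and tested with Fisher's exact
test (two-sided, probability-mass method).  p-values are pooled genome-wide
and adjusted with Benjamini-Hochberg; isoforms with q below the FDR
threshold are called significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import PipelineConfig, logger

PROXIMAL_SHIFT = "proximal_shift"
DISTAL_SHIFT = "distal_shift"


@dataclass
class SwitchResult:
    gene_id: str
    isoform_id: str
    usage_a: float
    usage_b: float
    table: tuple[tuple[int, int], tuple[int, int]]   # [[iso_A, rest_A], [iso_B, rest_B]]
    p_value: float
    q_value: float = float("nan")
    direction: str = ""          # proximal_shift | distal_shift (in B vs A)
    significant: bool = False


def major_isoform(counts: pd.Series, isoform_order: dict[str, int]) -> str | None:
    """Isoform with the maximal count in one sample; ties broken toward the
    most distal isoform (highest 5'→3' index).  None when the gene has no
    reads."""
    if counts.sum() <= 0:
        return None
    top = counts.max()
    tied = [iso for iso, c in counts.items() if c == top]
    return max(tied, key=lambda iso: isoform_order.get(iso, 0))


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def test_switch(
    gene_id: str,
    counts: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    min_reads: int = 20,
) -> list[SwitchResult]:
    """Per-isoform usage tests for one gene.

    ``counts`` has isoform ids as index and the two condition columns with
    pooled counts.  Genes with fewer than two isoforms, a zero-total
    condition, or totals below ``min_reads`` per condition are skipped.
    """
    tot_a = int(counts[condition_a].sum())
    tot_b = int(counts[condition_b].sum())
    if len(counts) < 2 or tot_a == 0 or tot_b == 0:
        return []
    if tot_a < min_reads or tot_b < min_reads:
        return []
    results = []
    for iso, row in counts.iterrows():
        a, b = int(row[condition_a]), int(row[condition_b])
        table = ((a, tot_a - a), (b, tot_b - b))
        results.append(
            SwitchResult(
                gene_id=gene_id,
                isoform_id=str(iso),
                usage_a=a / tot_a,
                usage_b=b / tot_b,
                table=table,
                p_value=fisher_two_sided(table),
            )
        )
    return results


def test_switches_genomewide(
    isoform_counts: pd.DataFrame,
    condition_of: dict[str, str],
    condition_a: str,
    condition_b: str,
    config: PipelineConfig | None = None,
    min_reads: int = 20,
) -> list[SwitchResult]:
    """Pool libraries per condition, test every eligible gene, then apply
    Benjamini-Hochberg across all isoform-level tests (one family)."""
    config = config or PipelineConfig()
    cols_a = [s for s in isoform_counts.columns if condition_of.get(s) == condition_a]
    cols_b = [s for s in isoform_counts.columns if condition_of.get(s) == condition_b]
    if not cols_a or not cols_b:
        raise ValueError("both conditions need at least one library")
    pooled = pd.DataFrame({
        condition_a: isoform_counts[cols_a].sum(axis=1),
        condition_b: isoform_counts[cols_b].sum(axis=1),
    })
    results: list[SwitchResult] = []
    skipped = 0
    for gene_id, block in pooled.groupby(level="gene_id"):
        block = block.droplevel("gene_id")
        res = test_switch(str(gene_id), block, condition_a, condition_b,
                          min_reads=min_reads)
        if not res and len(block) >= 2:
            skipped += 1
        results.extend(res)
    if skipped:
        logger.info("APA test skipped %d multi-isoform genes (coverage/zero totals)",
                    skipped)
    if results:
        pvals = [r.p_value for r in results]
        reject, qvals, _, _ = multipletests(pvals, alpha=config.fdr_threshold,
                                            method="fdr_bh")
        for r, q, rej in zip(results, qvals, reject):
            r.q_value = float(q)
            r.significant = bool(rej)
    return results


@dataclass
class GeneSwitch:
    gene_id: str
    major_a: str
    major_b: str
    major_changed: bool
    any_significant: bool
    direction: str          # direction of B's major isoform relative to A's


def switch_catalog(
    results: list[SwitchResult],
    isoform_counts: pd.DataFrame,
    condition_of: dict[str, str],
    condition_a: str,
    condition_b: str,
    isoform_order: dict[str, int],
) -> tuple[list[GeneSwitch], dict[str, int]]:
    """Per-gene switch summary: genes whose major isoform differs between
    conditions AND that carry at least one significant isoform, labelled
    proximal/distal from the gene's 5'→3' isoform ordering.

    Returns the catalog plus summary counts (major switches by direction and
    significant usage changes without a major-isoform switch).
    """
    sig_genes = {r.gene_id for r in results if r.significant}
    tested_genes = {r.gene_id for r in results}
    cols_a = [s for s in isoform_counts.columns if condition_of.get(s) == condition_a]
    cols_b = [s for s in isoform_counts.columns if condition_of.get(s) == condition_b]
    catalog: list[GeneSwitch] = []
    summary = {PROXIMAL_SHIFT: 0, DISTAL_SHIFT: 0, "usage_change_only": 0}
    for gene_id, block in isoform_counts.groupby(level="gene_id"):
        gene_id = str(gene_id)
        if gene_id not in tested_genes:
            continue
        block = block.droplevel("gene_id")
        maj_a = major_isoform(block[cols_a].sum(axis=1), isoform_order)
        maj_b = major_isoform(block[cols_b].sum(axis=1), isoform_order)
        if maj_a is None or maj_b is None:
            continue
        changed = maj_a != maj_b
        significant = gene_id in sig_genes
        if not significant:
            continue
        if not changed:
            summary["usage_change_only"] += 1
            continue
        direction = (
            DISTAL_SHIFT
            if isoform_order.get(maj_b, 0) > isoform_order.get(maj_a, 0)
            else PROXIMAL_SHIFT
        )
        summary[direction] += 1
        catalog.append(
            GeneSwitch(gene_id, maj_a, maj_b, changed, significant, direction)
        )
    return catalog, summary


def utr_length_stats(
    lengths: pd.Series,
    expression: pd.Series | None = None,
    exclude_genes: set[str] | None = None,
    exclude_top_fraction: float = 0.0,
) -> dict:
    """Median/quartile summary of 3'UTR lengths for one sample.

    ``lengths`` is indexed by gene (or gene-like) id.  Optional exclusions:
    an explicit gene list (e.g. ribosomal/sperm-protein families) and/or the
    top ``exclude_top_fraction`` most highly expressed isoforms (requires
    ``expression`` on the same index).
    """
    kept = lengths.dropna()
    if exclude_genes:
        drop = kept.index.get_level_values(0) if isinstance(kept.index, pd.MultiIndex) \
            else kept.index
        kept = kept[~pd.Index(drop).isin(exclude_genes)]
    if exclude_top_fraction > 0.0:
        if expression is None:
            raise ValueError("expression required for top-fraction exclusion")
        expr = expression.reindex(kept.index)
        n_drop = int(np.floor(len(kept) * exclude_top_fraction))
        if n_drop:
            kept = kept.drop(expr.nlargest(n_drop).index)
    if len(kept) == 0:
        return {"n": 0, "median": float("nan"),
                "q1": float("nan"), "q3": float("nan")}
    return {
        "n": int(len(kept)),
        "median": float(kept.median()),
        "q1": float(kept.quantile(0.25)),
        "q3": float(kept.quantile(0.75)),
    }
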