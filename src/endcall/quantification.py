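"""Count matrices, median-of-ratios size-factor normalization, the <5%
isoform filter, and expression summaries (fold-changes, per-chromosome
profiles).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .formats_io import GeneModel, PipelineConfig, logger
from .gene_annotation import IsoformRecord


def isoform_count_matrix(records: list[IsoformRecord],
                         samples: list[str]) -> pd.DataFrame:
    """Isoform-level counts: rows indexed by (gene_id, cluster_id), one
    column per sample library.  Unassigned clusters are excluded."""
    rows, idx = [], []
    for rec in records:
        if rec.gene_id is None:
            continue
        idx.append((rec.gene_id, rec.cluster_id))
        rows.append([rec.per_sample.get(s, 0) for s in samples])
    index = pd.MultiIndex.from_tuples(idx, names=["gene_id", "cluster_id"]) \
        if idx else pd.MultiIndex.from_arrays([[], []], names=["gene_id", "cluster_id"])
    return pd.DataFrame(rows, index=index, columns=samples, dtype=np.int64)


def gene_count_matrix(isoform_counts: pd.DataFrame) -> pd.DataFrame:
    """Gene-level counts: per-gene sums of isoform rows (pre-filter)."""
    return isoform_counts.groupby(level="gene_id").sum()


def size_factors(matrix: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios library size factors.

    factor_j = median over reference rows g of count[g, j] / geomean_j'
    count[g, j'].  Reference rows are rows with nonzero counts in every
    library; with ``pseudo_reference`` the geometric mean is instead taken
    over the nonzero entries of each row (all-zero rows still excluded).
    """
    counts = matrix.to_numpy(dtype=float)
    if pseudo_reference:
        logs = np.full_like(counts, np.nan)
        np.log(counts, out=logs, where=counts > 0)
        nz = (counts > 0).any(axis=1)
        log_ref = np.nanmean(logs[nz], axis=1)
        ratios = np.log(np.where(counts[nz] > 0, counts[nz], np.nan)) - log_ref[:, None]
        factors = np.exp(np.nanmedian(ratios, axis=0))
    else:
        all_pos = (counts > 0).all(axis=1)
        if not all_pos.any():
            raise ValueError(
                "no row has nonzero counts in every library; rerun with "
                "pseudo_reference=True to use a nonzero-mean reference"
            )
        ref_rows = counts[all_pos]
        log_ref = np.log(ref_rows).mean(axis=1)
        factors = np.exp(np.median(np.log(ref_rows) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def normalize(matrix: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    return matrix / factors


def filter_low_abundance_isoforms(
    isoform_counts: pd.DataFrame, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Per-sample retention mask for the <5% isoform filter.

    Within each sample an isoform is retained iff its count is at least
    ``min_isoform_fraction`` of its gene's total in that sample; the gene's
    maximal isoform in that sample is always retained (so an expressed gene
    never loses all isoforms).  Genes with zero total in a sample retain
    nothing there.  The cross-sample reported set is the row-wise union.
    """
    config = config or PipelineConfig()
    frac = config.min_isoform_fraction
    gene_totals = isoform_counts.groupby(level="gene_id").transform("sum")
    gene_max = isoform_counts.groupby(level="gene_id").transform("max")
    with np.errstate(invalid="ignore", divide="ignore"):
        share = isoform_counts / gene_totals
    retained = (gene_totals > 0) & (
        (share >= frac) | ((isoform_counts == gene_max) & (isoform_counts > 0))
    )
    return retained


def apply_isoform_filter(isoform_counts: pd.DataFrame,
                         config: PipelineConfig | None = None) -> pd.DataFrame:
    """Counts with non-retained entries zeroed and never-retained rows
    dropped (the union rule keeps a row if any sample retains it)."""
    mask = filter_low_abundance_isoforms(isoform_counts, config)
    filtered = isoform_counts.where(mask, 0)
    return filtered.loc[mask.any(axis=1)]


def usage_fractions(isoform_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-gene per-sample usage fractions over the given isoform set (sum
    to 1 wherever the gene has reads)."""
    gene_totals = isoform_counts.groupby(level="gene_id").transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = isoform_counts / gene_totals
    return out.fillna(0.0)


def expression_table(
    gene_counts: pd.DataFrame,
    factors: pd.Series,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalized expression plus all pairwise log2 fold-changes.

    Fold-change columns are named ``B_vs_A`` = log2((B + pc) / (A + pc)) on
    normalized counts.
    """
    norm = normalize(gene_counts, factors)
    fcs = {}
    cols = list(norm.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            fcs[f"{b}_vs_{a}"] = np.log2(
                (norm[b] + pseudocount) / (norm[a] + pseudocount)
            )
    return norm, pd.DataFrame(fcs, index=norm.index)


def chromosome_profile(
    norm_counts: pd.DataFrame,
    genes: dict[str, GeneModel],
    x_contig: str = "X",
    expressed_floor: float = 1.0,
) -> pd.DataFrame:
    """Per-contig, per-sample mean/median normalized expression over
    expressed genes, plus an X:autosome mean-expression ratio row.

    Genes missing from the annotation are excluded with a warning; a sample
    with zero expressed X-linked genes reports ratio 0 with a flag column.
    """
    contig_of = {}
    missing = 0
    for gid in norm_counts.index:
        g = genes.get(gid)
        if g is None:
            missing += 1
            continue
        contig_of[gid] = g.contig
    if missing:
        logger.warning("chromosome_profile: %d genes absent from annotation", missing)
    sub = norm_counts.loc[list(contig_of)]
    contigs = pd.Series(contig_of, name="contig")
    rows = []
    for contig, block in sub.groupby(contigs):
        for sample in sub.columns:
            vals = block[sample]
            expressed = vals[vals >= expressed_floor]
            rows.append({
                "contig": contig, "sample": sample,
                "n_expressed": len(expressed),
                "mean": float(expressed.mean()) if len(expressed) else 0.0,
                "median": float(expressed.median()) if len(expressed) else 0.0,
            })
    prof = pd.DataFrame(rows)
    ratios = []
    for sample in sub.columns:
        block = prof[prof["sample"] == sample]
        x = block.loc[block["contig"] == x_contig, "mean"]
        auto = block.loc[block["contig"] != x_contig, "mean"]
        x_mean = float(x.iloc[0]) if len(x) else 0.0
        auto_mean = float(auto.mean()) if len(auto) else 0.0
        degenerate = x_mean == 0.0 or auto_mean == 0.0
        ratios.append({
            "contig": "X:A_ratio", "sample": sample,
            "n_expressed": int(block["n_expressed"].sum()),
            "mean": 0.0 if degenerate else x_mean / auto_mean,
            "median": float("nan"),
            "degenerate": degenerate,
        })
    prof["degenerate"] = False
    return pd.concat([prof, pd.DataFrame(ratios)], ignore_index=True)
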