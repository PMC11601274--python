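"""Cell QC, per-cell-type pseudobulk aggregation, and rank-percentile transforms.

Quality control keeps cells with total counts strictly below 10,000 (doublet
guard) and mitochondrial fraction strictly below 10%. Aggregation sums counts
per (gene, individual) for one cell type and requires a minimum number of
cells for the type (125 by default, the floor used for training data).

Expression targets are rank percentiles: ranks are averaged over ties and
mapped by (rank-1)/(m-1), so the range is exactly [0, 1]. Two modes exist —
one percentile per gene from the cross-individual mean (the training target),
and per-individual gene percentiles (the observed side of across-individual
evaluation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import CellMatrix

logger = logging.getLogger(__name__)


@dataclass
class PseudobulkMatrix:
    """Gene x individual summed counts for one cell type."""

    cell_type: str
    counts: pd.DataFrame  # genes x individuals
    n_cells: pd.Series  # per-individual cell tallies

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("pseudobulk counts must be non-negative")
        if (self.n_cells <= 0).any():
            raise ValueError("individuals with 0 cells must be excluded")
        if list(self.counts.columns) != list(self.n_cells.index):
            raise ValueError("count columns and cell tallies disagree")

    @property
    def total_cells(self) -> int:
        return int(self.n_cells.sum())


@dataclass
class RankExpression:
    """Rank-percentile expression, values in [0, 1]."""

    mode: str  # "cross_gene_mean" | "within_individual"
    values: pd.Series | pd.DataFrame

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError("percentiles must lie in [0, 1]")
        if self.mode not in ("cross_gene_mean", "within_individual"):
            raise ValueError(f"unknown mode {self.mode!r}")


def qc_filter_cells(cm: CellMatrix, max_total: float = 10000,
                    max_mito_pct: float = 10) -> CellMatrix:
    """Keep cells with n_count_total < max_total and mito_pct < max_mito_pct.

    Both filters are strict inequalities; a cell exactly at a threshold is
    removed.
    """
    meta = cm.cell_meta
    keep = (meta["n_count_total"] < max_total) & (meta["mito_pct"] < max_mito_pct)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("qc_filter_cells: removed %d of %d cells", n_removed, cm.n_cells)
    return cm.subset_cells(keep.to_numpy())


def aggregate(cm: CellMatrix, cell_type: str, min_cells: int = 125) -> PseudobulkMatrix:
    """Sum counts per (gene, individual) for one cell type.

    Raises if the cell type is absent or has fewer than ``min_cells`` cells in
    total; individuals contributing no cells of the type are excluded.
    """
    meta = cm.cell_meta
    mask = (meta["cell_type"] == cell_type).to_numpy()
    if not mask.any():
        raise KeyError(f"unknown cell type {cell_type!r}")
    if mask.sum() < min_cells:
        raise ValueError(
            f"insufficient cells for {cell_type!r}: {int(mask.sum())} < {min_cells}"
        )
    sub = cm.subset_cells(mask)
    individuals = pd.unique(sub.cell_meta["individual_id"])
    cols, tallies = {}, {}
    for ind in individuals:
        rows = (sub.cell_meta["individual_id"] == ind).to_numpy()
        tallies[ind] = int(rows.sum())
        cols[ind] = np.asarray(sub.counts[np.flatnonzero(rows)].sum(axis=0)).ravel()
    counts = pd.DataFrame(cols, index=sub.gene_ids)
    return PseudobulkMatrix(
        cell_type=cell_type,
        counts=counts,
        n_cells=pd.Series(tallies, dtype=int).loc[counts.columns],
    )


def _percentile(values: np.ndarray) -> np.ndarray:
    """Average-rank percentiles mapped to [0, 1] by (rank-1)/(m-1)."""
    m = len(values)
    if m < 2:
        raise ValueError("rank percentiles need at least 2 genes")
    return (rankdata(values, method="average") - 1) / (m - 1)


def rank_percentile_crossgene(pb: PseudobulkMatrix) -> RankExpression:
    """One percentile per gene: mean count across individuals, ranked over genes."""
    means = pb.counts.mean(axis=1)
    return RankExpression(
        mode="cross_gene_mean",
        values=pd.Series(_percentile(means.to_numpy()), index=pb.counts.index),
    )


def rank_percentile_within_individual(pb: PseudobulkMatrix) -> RankExpression:
    """Per individual, rank that individual's genes and convert to percentiles."""
    mat = np.column_stack([_percentile(pb.counts[c].to_numpy()) for c in pb.counts.columns])
    return RankExpression(
        mode="within_individual",
        values=pd.DataFrame(mat, index=pb.counts.index, columns=pb.counts.columns),
    )
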