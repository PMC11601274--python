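"""Evaluation statistics: pi1/m1, LD-block yield, QQ data, sharing, precision/recall.

``estimate_pi1`` follows the q-value framework's pi0 estimator: pi0(lambda) =
#{p > lambda} / (m (1 - lambda)) over a lambda grid, smoothed with a natural
cubic spline and read off at the largest lambda. ``m1 = pi1 * m`` counts
tests drawn from the alternative — the robust way to compare predictors that
converge for very different numbers of genes.

LD-block counting assigns each significant gene to the pre-defined
approximately independent block containing its TSS and counts distinct
blocks hit — locus-level yield rather than gene-level. QQ coordinates can pad
a method's p-values with uniform draws up to a common gene universe so that
frameworks converging for different gene sets are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .io_formats import GeneAnnotation, LDBlockSet

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)


@dataclass
class Pi1Estimate:
    pi1: float
    m: int
    m1: float
    lambda_grid: np.ndarray

    def __post_init__(self) -> None:
        assert 0 <= self.pi1 <= 1 and 0 <= self.m1 <= self.m


@dataclass
class SharingSummary:
    n_total_hits: int
    n_shared_all: int
    n_shared_ge2: int
    n_unique: int
    pct_shared_all: float
    pct_shared_ge2: float
    pct_unique: float


def estimate_pi1(p_values, lambda_grid=None, method: str = "spline") -> Pi1Estimate:
    """Proportion of tests from the alternative, 1 - pi0.

    ``method="spline"`` smooths pi0(lambda) with a natural cubic spline and
    evaluates at the largest lambda (the q-value default); ``method="fixed"``
    uses pi0(0.5) directly.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    m = p.size
    pi0_lambda = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in grid])
    if method == "fixed":
        lam = 0.5
        pi0 = (p > lam).sum() / (m * (1 - lam))
    elif method == "spline":
        # natural cubic smoothing spline (GCV-chosen penalty), read at max lambda
        spline = make_smoothing_spline(grid, pi0_lambda)
        pi0 = float(spline(grid[-1]))
    else:
        raise ValueError(f"unknown method {method!r}")
    pi0 = float(min(max(pi0, 0.0), 1.0))
    pi1 = 1.0 - pi0
    return Pi1Estimate(pi1=pi1, m=m, m1=pi1 * m, lambda_grid=grid)


def count_ld_blocks(significant_genes, annotation: GeneAnnotation,
                    blocks: LDBlockSet) -> tuple[int, pd.DataFrame]:
    """Distinct LD blocks containing the TSS of at least one significant gene.

    Membership is by TSS with blocks treated as 1-based inclusive intervals
    (converted from half-open BED on read, so a TSS at a BED block's
    half-open end belongs to the following block). Genes outside every block
    are assigned "unassigned" and do not contribute to the count.
    """
    rows = []
    t = blocks.table
    for gene in significant_genes:
        rec = annotation.record(gene)
        hit = t[
            (t["chrom"].astype(str) == str(rec["chrom"]))
            & (t["start"] <= rec["tss"])
            & (rec["tss"] <= t["end"])
        ]
        rows.append(
            {
                "gene": gene,
                "block_id": hit["block_id"].iloc[0] if len(hit) else "unassigned",
            }
        )
    assignment = pd.DataFrame(rows, columns=["gene", "block_id"])
    n_hit = assignment.loc[assignment["block_id"] != "unassigned", "block_id"].nunique()
    return int(n_hit), assignment


def qq_with_uniform_imputation(p_values, total_genes: int,
                               seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """-log10 QQ coordinates, padding up to ``total_genes`` with Uniform(0,1).

    Returns (expected, observed) sorted so expected is increasing; expected
    quantiles are (i - 0.5) / n.
    """
    p = np.asarray(p_values, dtype=float)
    if total_genes < p.size:
        raise ValueError("total_genes smaller than the number of p-values")
    pad = np.random.default_rng(seed).uniform(size=total_genes - p.size)
    full = np.sort(np.concatenate([p, pad]))[::-1]  # descending p = ascending -log10
    n = total_genes
    expected = -np.log10((np.arange(n, 0, -1) - 0.5) / n)
    observed = -np.log10(full)
    return expected, observed


def sharing_summary(sig_matrix: pd.DataFrame) -> SharingSummary:
    """Cell-type sharing counts from a gene x cell-type significance matrix.

    Hits are genes significant in >= 1 cell type; with a single cell type
    every hit is unique. Percentages are of total hits, at 1 decimal.
    """
    mat = sig_matrix.to_numpy(bool)
    n_types = mat.shape[1] if mat.ndim == 2 else 1
    per_gene = mat.sum(axis=1)
    hits = per_gene >= 1
    n_total = int(hits.sum())
    n_all = int((per_gene == n_types).sum()) if n_types >= 2 else 0
    n_ge2 = int((per_gene >= 2).sum())
    n_unique = int((per_gene == 1).sum())
    pct = lambda c: round(100 * c / n_total, 1) if n_total else 0.0
    return SharingSummary(
        n_total_hits=n_total,
        n_shared_all=n_all,
        n_shared_ge2=n_ge2,
        n_unique=n_unique,
        pct_shared_all=pct(n_all),
        pct_shared_ge2=pct(n_ge2),
        pct_unique=pct(n_unique),
    )


def precision_recall(nominated_genes, silver_genes) -> tuple[float, float]:
    """Precision and recall of gene nomination against a silver-standard list.

    Precision is NaN (flagged) when nothing was nominated; recall is then 0.
    """
    nominated, silver = set(nominated_genes), set(silver_genes)
    if not silver:
        raise ValueError("silver-standard list must be non-empty")
    tp = len(nominated & silver)
    precision = tp / len(nominated) if nominated else float("nan")
    recall = tp / len(silver)
    return precision, recall
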