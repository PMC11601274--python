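"""Gene-trait association from GWAS summary statistics.

The gene-level test statistic follows the summary-based PrediXcan form:

    Z_g = sum_{l in model} w_{g,l} * (sigma_l / sigma_g) * (beta_l / se_l)

where ``w_{g,l}`` are the elastic-net SNP weights, ``sigma_l`` is the SNP's
dosage standard deviation and ``sigma_g = sqrt(w' Gamma_g w)`` the standard
deviation of predicted expression, both computed from the stored
reference-panel covariance ``Gamma_g`` (SNP variances and expression
variances are not available in summary statistics). ``beta_l / se_l`` is the
GWAS marginal z-score after allele harmonization. Gene p-values are
two-sided normal, evaluated in log space for extreme z.

Cross-cell-type aggregation uses the Cauchy combination test (ACAT), and
genes Bonferroni-significant in exactly one cell type are classified by the
ACAT-aggregated p-value over the remaining cell types: below the non-focal
Bonferroni threshold, below 0.05 (cell-type-enriched), or neither
(cell-type-specific).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .io_formats import GWASSummary, WeightDB

logger = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = frozenset({frozenset({"A", "T"}), frozenset({"C", "G"})})


@dataclass
class AssociationResult:
    gene_id: str
    cell_type: str
    z: float
    p: float
    sigma_g: float
    n_snps_used: int
    n_snps_in_model: int


@dataclass
class SpecificityCall:
    gene_id: str
    focal_cell_type: str
    klass: str  # shared | unique-bonferroni | unique-enriched | unique-specific
    aggregated_nonfocal_p: float


def normal_p_two_sided(z: float) -> float:
    """2*Phi(-|z|) with a log-space tail so p underflows gracefully.

    ``special.ndtr`` is accurate to |z| ~ 37; beyond that the asymptotic
    expansion in log space keeps tiny p-values (e.g. 1e-48) representable.
    """
    az = abs(z)
    if az < 8:
        return float(2 * special.ndtr(-az))
    log_p = math.log(2) + special.log_ndtr(-az)
    return float(math.exp(log_p)) if log_p > -745 else 5e-324


def harmonize(gwas: GWASSummary, db: WeightDB, drop_ambiguous: bool = True) -> pd.DataFrame:
    """Join model SNPs to GWAS rows by (chrom, pos, allele pair).

    The GWAS beta is re-signed onto the model's effect allele; strand
    ambiguous (A/T, C/G) variants are dropped by default. Returns one row per
    matched (gene, SNP) with columns weight, beta, se; genes with zero
    matches simply contribute no rows.
    """
    key_index = gwas.variant_key_index()
    table = gwas.table
    rows = []
    n_ambiguous = n_unmatched = 0
    for row in db.weights.itertuples(index=False):
        chrom, pos, ref, eff = row.varID.split("_")
        alleles = frozenset({ref, eff})
        if drop_ambiguous and alleles in AMBIGUOUS_PAIRS:
            n_ambiguous += 1
            continue
        idx = key_index.get((chrom, int(pos), alleles))
        if idx is None:
            n_unmatched += 1
            continue
        g = table.iloc[idx]
        beta = g["beta"] if g["effect_allele"] == eff else -g["beta"]
        rows.append(
            {
                "gene": row.gene,
                "rsid": row.rsid,
                "weight": row.weight,
                "beta": float(beta),
                "se": float(g["standard_error"]),
            }
        )
    if n_ambiguous or n_unmatched:
        logger.info("harmonize: dropped %d ambiguous, %d unmatched model SNPs",
                    n_ambiguous, n_unmatched)
    return pd.DataFrame(rows, columns=["gene", "rsid", "weight", "beta", "se"])


def spredixcan_z(gene: str, db: WeightDB, harmonized: pd.DataFrame,
                 cell_type: str = "") -> AssociationResult | None:
    """Summary-based association z-score for one gene.

    Returns ``None`` (flagged in the log) when no SNPs match or the predicted
    expression variance is degenerate.
    """
    gene_rows = harmonized[harmonized["gene"] == gene]
    if gene_rows.empty:
        logger.warning("gene %s: no harmonized SNPs; skipped", gene)
        return None
    rsids, cov = db.covariances[gene]
    model_w = db.gene_weights(gene).set_index("rsid")["weight"]
    w_full = model_w.reindex(rsids).to_numpy(float)
    sigma_g2 = float(w_full @ cov @ w_full)
    if sigma_g2 <= 0:
        logger.warning("gene %s: degenerate expression variance; skipped", gene)
        return None
    sigma_g = math.sqrt(sigma_g2)
    idx = {r: i for i, r in enumerate(rsids)}
    z = 0.0
    for row in gene_rows.itertuples(index=False):
        sigma_l = math.sqrt(max(cov[idx[row.rsid], idx[row.rsid]], 0.0))
        z += row.weight * (sigma_l / sigma_g) * (row.beta / row.se)
    return AssociationResult(
        gene_id=gene,
        cell_type=cell_type,
        z=float(z),
        p=normal_p_two_sided(z),
        sigma_g=sigma_g,
        n_snps_used=len(gene_rows),
        n_snps_in_model=len(rsids),
    )


def associate_all(db: WeightDB, gwas: GWASSummary, cell_type: str = "",
                  drop_ambiguous: bool = True) -> pd.DataFrame:
    """Run the summary-based test for every gene in the database."""
    harmonized = harmonize(gwas, db, drop_ambiguous=drop_ambiguous)
    rows = []
    for gene in db.genes:
        res = spredixcan_z(gene, db, harmonized, cell_type)
        if res is None:
            continue
        rows.append(
            {
                "gene": res.gene_id,
                "cell_type": res.cell_type,
                "zscore": res.z,
                "pvalue": res.p,
                "sigma_g": res.sigma_g,
                "n_snps_used": res.n_snps_used,
                "n_snps_in_model": res.n_snps_in_model,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "cell_type", "zscore", "pvalue", "sigma_g",
                 "n_snps_used", "n_snps_in_model"],
    )


def acat(p_values, weights=None) -> float:
    """Cauchy combination of dependent p-values.

    ``T = sum_i w_i tan((0.5 - p_i) pi) / sum_i w_i``; the combined p-value is
    ``0.5 - arctan(T)/pi``. Inputs below 1e-15 use the small-p surrogate
    ``w_i / (p_i pi)`` for the tangent term, and a very large T returns the
    matching tail approximation ``1/(pi T)``. Identical inputs are a fixed
    point: ACAT(p, ..., p) = p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("p-values must lie strictly inside (0, 1)")
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != p.shape or (w < 0).any() or w.sum() == 0:
        raise ValueError("invalid ACAT weights")
    w = w / w.sum()
    small = p < 1e-15
    terms = np.empty_like(p)
    terms[~small] = np.tan((0.5 - p[~small]) * np.pi)
    terms[small] = 1.0 / (p[small] * np.pi)
    t = float((w * terms).sum())
    if t > 1e15:
        return 1.0 / (t * np.pi)
    return float(0.5 - math.atan(t) / math.pi)


def bonferroni(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def aggregate_across_cell_types(results: pd.DataFrame) -> pd.Series:
    """One ACAT-combined p-value per gene across its cell-type results."""
    return results.groupby("gene")["pvalue"].apply(lambda p: acat(p.to_numpy()))


def classify_specificity(results: pd.DataFrame, gene: str, focal_cell_type: str,
                         thresholds: dict[str, float],
                         aggregated_threshold: float | None = None,
                         alpha: float = 0.05) -> SpecificityCall:
    """Classify a single-cell-type hit by its aggregated non-focal p-value.

    ``thresholds`` maps cell type -> its Bonferroni threshold. A gene that is
    Bonferroni-significant in two or more cell types is "shared" (not
    eligible for the unique classes). ``aggregated_threshold`` is the
    Bonferroni threshold of the aggregated follow-up test (the ACAT
    combination over non-focal cell types is one test per gene, so its family
    is the set of unique-hit genes, not the full gene grid); it defaults to
    the strictest non-focal per-type threshold.
    """
    sub = results[results["gene"] == gene]
    sig_types = [
        row.cell_type
        for row in sub.itertuples(index=False)
        if row.pvalue < thresholds[row.cell_type]
    ]
    if len(sig_types) >= 2 or focal_cell_type not in sig_types:
        return SpecificityCall(gene, focal_cell_type, "shared", float("nan"))
    nonfocal = sub[sub["cell_type"] != focal_cell_type]
    agg = acat(nonfocal["pvalue"].to_numpy())
    if aggregated_threshold is None:
        aggregated_threshold = min(
            (thresholds[ct] for ct in nonfocal["cell_type"]), default=alpha
        )
    if agg < aggregated_threshold:
        klass = "unique-bonferroni"
    elif agg < alpha:
        klass = "unique-enriched"
    else:
        klass = "unique-specific"
    return SpecificityCall(gene, focal_cell_type, klass, agg)
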