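"""Distil the expression MLP into per-gene cis-SNP elastic-net predictors.

The nonlinear predictor is applied to a reference genotype panel (several
hundred individuals) to produce an in-silico expression panel containing only
the genetically determined component of expression. Each gene's in-silico
expression is then regressed on the dosages of SNPs within a cis window
(TSS +/- 1 Mb) with an elastic net (mixing parameter 0.5, penalty chosen at
the minimum of 10-fold cross-validated error). The same machinery fitted to
*observed* pseudobulk expression is the canonical TWAS baseline (PEN); it
converges for far fewer genes because observed expression carries
environmental noise and is limited to the study sample size.

Conventions: dosages are standardized before fitting and weights are
back-transformed to per-allele (dosage) scale; a gene "converges" when the
selected model has at least one nonzero weight and positive out-of-fold
correlation with the expression it was fitted to; cross-validation folds are
assigned by hashing individual ids with the run seed, so fits are invariant
to input order.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV

from .ctpred import CtPredModel
from .io_formats import GeneAnnotation, GenotypePanel, WeightDB
from .pseudobulk import PseudobulkMatrix, rank_percentile_within_individual

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ElasticNetConfig:
    cis_window_bp: int = 1_000_000
    l1_ratio: float = 0.5
    folds: int = 10
    n_alphas: int = 50
    alpha_eps: float = 1e-5  # smallest grid penalty relative to alpha_max
    max_iter: int = 5000
    seed: int = 0


@dataclass
class GenePredictor:
    """Per-gene cis-SNP weights on dosage scale (the unit stored in the DB)."""

    gene_id: str
    weights: pd.DataFrame  # snp_id, chrom, pos, ref_allele, eff_allele, weight
    intercept: float
    cv_metric: float
    converged: bool
    cis_window_bp: int

    def predict(self, panel: GenotypePanel) -> pd.Series:
        """Apply dosage-scale weights; reproduces training fitted values."""
        idx = {s: j for j, s in enumerate(panel.snp_records["snp_id"])}
        cols = [idx[s] for s in self.weights["snp_id"]]
        vals = panel.dosages[:, cols] @ self.weights["weight"].to_numpy() + self.intercept
        return pd.Series(vals, index=panel.individual_ids)


@dataclass
class InSilicoPanel:
    """Gene x individual predicted-expression matrix with provenance."""

    expression: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.expression.to_numpy()).all():
            raise ValueError("in-silico expression contains non-finite values")


def build_insilico_panel(model: CtPredModel, extractor, panel: GenotypePanel,
                         genes: list[str]) -> InSilicoPanel:
    """Predict expression for every (gene, panel individual) pair."""
    rows = {}
    for gene in genes:
        if hasattr(extractor, "personalized_matrix"):
            feats = extractor.personalized_matrix(gene)
        else:
            feats = np.vstack(
                [extractor.personalized(gene, ind).values for ind in panel.individual_ids]
            )
        rows[gene] = model.predict(feats)
    expr = pd.DataFrame.from_dict(rows, orient="index", columns=panel.individual_ids)
    weight_digest = hashlib.sha256(
        b"".join(np.ascontiguousarray(w).tobytes() for w in model.weights)
    ).hexdigest()[:16]
    return InSilicoPanel(
        expression=expr,
        provenance={
            "model_hash": weight_digest,
            "extractor": type(extractor).__name__,
            "panel_n": panel.n_individuals,
        },
    )


def _fold_assignment(individual_ids: list[str], folds: int, seed: int) -> np.ndarray:
    """Balanced, order-invariant folds from hashed individual ids."""
    digests = {
        ind: hashlib.sha256(f"{seed}:{ind}".encode()).hexdigest() for ind in individual_ids
    }
    ranked = sorted(individual_ids, key=lambda i: digests[i])
    fold_of = {ind: r % folds for r, ind in enumerate(ranked)}
    return np.array([fold_of[i] for i in individual_ids])


def _cis_snp_idx(panel: GenotypePanel, chrom: str, tss: int, window: int) -> np.ndarray:
    recs = panel.snp_records
    mask = (recs["chrom"].astype(str) == str(chrom)) & (
        (recs["pos"] - tss).abs() <= window
    )
    return np.flatnonzero(mask.to_numpy())


def fit_elastic_net(gene_id: str, expression: pd.Series, panel: GenotypePanel,
                    tss_chrom: str, tss_pos: int,
                    config: ElasticNetConfig = ElasticNetConfig(),
                    ) -> tuple[GenePredictor, pd.Series]:
    """Fit one gene's cis elastic net; returns the predictor and out-of-fold
    predictions (for linearization-fidelity validation).

    ``expression`` is indexed by individual id and must cover the panel.
    Raises ``ValueError`` when the gene has no cis SNPs.
    """
    if panel.n_individuals < config.folds:
        raise ValueError("need at least as many individuals as CV folds")
    y = expression.loc[panel.individual_ids].to_numpy(float)
    cis = _cis_snp_idx(panel, tss_chrom, tss_pos, config.cis_window_bp)
    if cis.size == 0:
        raise ValueError(f"no cis SNPs for {gene_id}")
    x = panel.dosages[:, cis]
    mu, sd = x.mean(axis=0), x.std(axis=0)
    usable = sd > 0
    x_std = np.zeros_like(x)
    x_std[:, usable] = (x[:, usable] - mu[usable]) / sd[usable]

    fold = _fold_assignment(panel.individual_ids, config.folds, config.seed)
    cv_iter = [
        (np.flatnonzero(fold != k), np.flatnonzero(fold == k)) for k in range(config.folds)
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if y.std() == 0:
            best_alpha = np.inf
            coef = np.zeros(x.shape[1])
            oof = np.full_like(y, y.mean())
        else:
            cv_model = ElasticNetCV(
                l1_ratio=config.l1_ratio, alphas=config.n_alphas,
                eps=config.alpha_eps, cv=cv_iter, max_iter=config.max_iter,
            )
            cv_model.fit(x_std, y)
            best_alpha = cv_model.alpha_
            coef = cv_model.coef_
            oof = np.empty_like(y)
            for tr, te in cv_iter:
                m = ElasticNet(alpha=best_alpha, l1_ratio=config.l1_ratio,
                               max_iter=config.max_iter)
                m.fit(x_std[tr], y[tr])
                oof[te] = m.predict(x_std[te])

    nonzero = np.flatnonzero(coef)
    if nonzero.size and np.std(oof) > 0:
        cv_metric = float(stats.pearsonr(oof, y).statistic)
    else:
        cv_metric = float("nan")
    # a predictor exists when the selected model is non-empty and tracks
    # held-out expression in the right direction
    converged = bool(nonzero.size > 0 and np.isfinite(cv_metric) and cv_metric > 0)
    recs = panel.snp_records.iloc[cis[nonzero]]
    w_dosage = coef[nonzero] / sd[nonzero]
    intercept = float(y.mean() - (coef[nonzero] * mu[nonzero] / sd[nonzero]).sum())
    weights = pd.DataFrame(
        {
            "snp_id": recs["snp_id"].to_numpy(),
            "chrom": recs["chrom"].to_numpy(),
            "pos": recs["pos"].to_numpy(),
            "ref_allele": recs["ref_allele"].to_numpy(),
            "eff_allele": recs["eff_allele"].to_numpy(),
            "weight": w_dosage,
        }
    )
    predictor = GenePredictor(
        gene_id=gene_id, weights=weights, intercept=intercept,
        cv_metric=cv_metric, converged=converged,
        cis_window_bp=config.cis_window_bp,
    )
    return predictor, pd.Series(oof, index=panel.individual_ids)


def _weight_db_from_predictors(predictors: list[GenePredictor],
                               panel: GenotypePanel) -> WeightDB:
    """Assemble converged predictors and reference-panel covariances into a DB."""
    snp_index = {s: j for j, s in enumerate(panel.snp_records["snp_id"])}
    w_rows, e_rows, covs = [], [], {}
    for p in predictors:
        if not p.converged:
            continue
        for row in p.weights.itertuples(index=False):
            w_rows.append(
                {
                    "gene": p.gene_id,
                    "rsid": row.snp_id,
                    "varID": f"{row.chrom}_{row.pos}_{row.ref_allele}_{row.eff_allele}",
                    "ref_allele": row.ref_allele,
                    "eff_allele": row.eff_allele,
                    "weight": row.weight,
                }
            )
        e_rows.append(
            {
                "gene": p.gene_id,
                "genename": p.gene_id,
                "n_snps_in_model": len(p.weights),
                "cv_performance": p.cv_metric,
            }
        )
        cols = [snp_index[s] for s in p.weights["snp_id"]]
        dos = panel.dosages[:, cols]
        cov = np.atleast_2d(np.cov(dos, rowvar=False))
        covs[p.gene_id] = (p.weights["snp_id"].tolist(), cov)
    weights = pd.DataFrame(
        w_rows, columns=["gene", "rsid", "varID", "ref_allele", "eff_allele", "weight"]
    )
    extra = pd.DataFrame(
        e_rows, columns=["gene", "genename", "n_snps_in_model", "cv_performance"]
    )
    return WeightDB(weights=weights, extra=extra, covariances=covs)


def weight_db_from_weights(gene_weights: dict[str, dict[str, float]],
                           panel: GenotypePanel,
                           cv_performance: float = float("nan")) -> WeightDB:
    """Build a WeightDB from explicit dosage-scale weights per gene.

    ``gene_weights`` maps gene -> {snp_id: weight}; SNP metadata and per-gene
    covariances come from the panel. Useful for applying externally derived
    weights (e.g. bulk-trained predictors) or known planted architectures.
    """
    snp_index = {s: j for j, s in enumerate(panel.snp_records["snp_id"])}
    predictors = []
    for gene, wmap in gene_weights.items():
        recs = panel.snp_records.iloc[[snp_index[s] for s in wmap]]
        weights = pd.DataFrame(
            {
                "snp_id": recs["snp_id"].to_numpy(),
                "chrom": recs["chrom"].to_numpy(),
                "pos": recs["pos"].to_numpy(),
                "ref_allele": recs["ref_allele"].to_numpy(),
                "eff_allele": recs["eff_allele"].to_numpy(),
                "weight": [wmap[s] for s in recs["snp_id"]],
            }
        )
        predictors.append(
            GenePredictor(
                gene_id=gene, weights=weights, intercept=0.0,
                cv_metric=cv_performance, converged=True,
                cis_window_bp=0,
            )
        )
    return _weight_db_from_predictors(predictors, panel)


def linearize_all(insilico: InSilicoPanel, panel: GenotypePanel,
                  annotation: GeneAnnotation,
                  config: ElasticNetConfig = ElasticNetConfig(),
                  ) -> tuple[WeightDB, pd.DataFrame]:
    """Fit every gene in the in-silico panel; returns the weight database and
    a per-gene summary (converged flag, cv_metric, n_snps)."""
    predictors, rows = [], []
    for gene in insilico.expression.index:
        try:
            rec = annotation.record(gene)
        except KeyError:
            logger.warning("gene %s not annotated; skipped", gene)
            continue
        try:
            pred, _ = fit_elastic_net(
                gene, insilico.expression.loc[gene], panel,
                rec["chrom"], int(rec["tss"]), config,
            )
        except ValueError as err:
            logger.warning("gene %s skipped: %s", gene, err)
            continue
        predictors.append(pred)
        rows.append(
            {
                "gene": gene,
                "converged": pred.converged,
                "cv_metric": pred.cv_metric,
                "n_snps": len(pred.weights),
            }
        )
    db = _weight_db_from_predictors(predictors, panel)
    return db, pd.DataFrame(rows, columns=["gene", "converged", "cv_metric", "n_snps"])


def validate_linearization(insilico: InSilicoPanel, panel: GenotypePanel,
                           annotation: GeneAnnotation,
                           config: ElasticNetConfig = ElasticNetConfig(),
                           ) -> pd.Series:
    """Per-gene Spearman correlation between the nonlinear predictions and
    out-of-fold linear predictions (10-fold CV by default).

    Genes whose nonlinear predictions are constant are skipped (rho
    undefined); the median of the returned series is the headline fidelity
    number.
    """
    rhos = {}
    for gene in insilico.expression.index:
        y = insilico.expression.loc[gene]
        if y.std() == 0:
            logger.warning("gene %s has constant predictions; flagged", gene)
            rhos[gene] = np.nan
            continue
        rec = annotation.record(gene)
        try:
            _, oof = fit_elastic_net(gene, y, panel, rec["chrom"], int(rec["tss"]), config)
        except ValueError:
            continue
        if oof.std() == 0:
            rhos[gene] = np.nan
            continue
        rhos[gene] = float(stats.spearmanr(oof.to_numpy(), y.to_numpy()).statistic)
    return pd.Series(rhos, dtype=float)


def fit_pen_baseline(pb: PseudobulkMatrix, panel: GenotypePanel,
                     annotation: GeneAnnotation,
                     config: ElasticNetConfig = ElasticNetConfig(),
                     ) -> tuple[WeightDB, pd.DataFrame]:
    """Canonical TWAS baseline: elastic net on observed pseudobulk expression.

    Observed expression is rank-transformed within each individual; only
    individuals present in both the pseudobulk and the genotype panel are
    used. Shares the fitting code path with the in-silico route.
    """
    if pb.counts.shape[1] == 0:
        raise ValueError("no individuals in pseudobulk matrix")
    ranks = rank_percentile_within_individual(pb).values
    common = [i for i in panel.individual_ids if i in ranks.columns]
    if not common:
        raise ValueError("no overlap between pseudobulk individuals and panel")
    sub_panel = GenotypePanel(
        dosages=panel.dosages[[panel.individual_ids.index(i) for i in common]],
        snp_records=panel.snp_records.copy(),
        individual_ids=common,
    )
    observed = InSilicoPanel(
        expression=ranks[common], provenance={"source": "observed_pseudobulk"}
    )
    return linearize_all(observed, sub_panel, annotation, config)
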