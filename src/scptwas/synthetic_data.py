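"""Synthetic inputs with the statistical structure the TWAS framework assumes.

The generator emulates, end to end, the data a cell-type TWAS consumes:

* LD-structured genotype dosages (latent-Gaussian AR(1) haplotypes thresholded
  to per-SNP minor-allele frequencies, so adjacent-SNP correlation has a
  closed tetrachoric form),
* a sparse cis architecture per gene (latent genetic expression
  ``g_i = sum_causal effect * standardized dosage``),
* per-gene epigenomic feature vectors that are (partly nonlinear) functions of
  local genotype, standing in for sequence-model track summaries,
* sparse negative-binomial single-cell counts aggregated to pseudobulk,
* GWAS summary statistics from exact per-SNP marginal OLS on a fresh cohort
  with planted gene-trait effects.

Every draw flows from ``SimConfig.seed`` through named substreams, so a fixed
config yields bit-identical outputs.

Feature model
-------------
``x_{g,i} = u_g * s(b_g + g_i) + eps`` with ``s(u) = u + c*tanh(u)``
(``c = nonlinearity_strength``), ``u_g`` a seeded loading sharing a common
direction across genes (plus per-gene jitter), ``b_g`` a per-gene baseline,
and ``eps ~ N(0, feature_noise_sd^2)``. The shared direction and the baseline
term are what make cross-gene training of an expression predictor
informative: the reference vector of a gene encodes its baseline expression,
while the individual term carries the genetic dosage signal that
linearization must recover.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import ndtri

from .io_formats import CellMatrix, GeneAnnotation, GenotypePanel, GWASSummary

__all__ = [
    "SimConfig",
    "GroundTruth",
    "FeatureSet",
    "simulate_genotypes",
    "simulate_cis_architecture",
    "simulate_features",
    "simulate_single_cell",
    "simulate_gwas",
    "simulate_all",
]

_GENE_SPACING_BP = 3_000_000  # cis windows (±1 Mb) of neighbouring genes stay disjoint
_SNP_SPACING_BP = 1_000
_N_CHROMS = 22


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the reference-panel scale of the real pipeline (462
    individuals, tens of cis SNPs per gene) at a desk-scale gene count; the
    feature width defaults to the full 5313-track summary but is configurable
    (tests run narrower).
    """

    n_genes: int = 20
    n_individuals: int = 462
    snps_per_gene: int = 30
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.5
    n_causal_snps_per_gene: int = 2
    effect_sd: float = 1.0
    feature_dim: int = 5313
    feature_noise_sd: float = 0.1
    nonlinearity_strength: float = 0.5
    loading_jitter: float = 0.3
    cells_per_individual: int = 50
    nb_dispersion: float = 2.0
    library_size_mean: float = 2000.0
    gwas_n: int = 2000
    n_causal_genes: int = 5
    gene_trait_effect_sd: float = 0.5
    h2_trait: float = 0.2
    cell_type: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")
        if self.n_causal_snps_per_gene > self.snps_per_gene:
            raise ValueError("n_causal_snps_per_gene exceeds snps_per_gene")
        for name in ("n_genes", "n_individuals", "snps_per_gene", "cells_per_individual", "gwas_n"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream seeded from the config seed (process-independent)."""
        key = zlib.crc32(stream.encode())  # stable across processes, unlike hash()
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(key,)))


@dataclass
class GroundTruth:
    """Registry of planted effects for recovery tests."""

    gene_ids: list[str]
    baselines: dict[str, float]
    causal_snps: dict[str, list[str]]
    causal_effects: dict[str, np.ndarray]
    latent_expression: pd.DataFrame  # genes x panel individuals
    trait_causal_genes: list[str] = field(default_factory=list)
    trait_effects: dict[str, float] = field(default_factory=dict)

    def latent_for(self, panel: GenotypePanel) -> pd.DataFrame:
        """Latent genetic expression of each gene for an arbitrary cohort.

        Dosages are standardized with population moments (mean ``2*maf``,
        variance ``2*maf*(1-maf)`` implied by the stored per-SNP frequency of
        the panel), so the same causal weights apply to any cohort drawn from
        the generating process.
        """
        recs = panel.snp_records
        idx = {s: j for j, s in enumerate(recs["snp_id"])}
        out = np.zeros((len(self.gene_ids), panel.n_individuals))
        for gi, gene in enumerate(self.gene_ids):
            for snp, eff in zip(self.causal_snps[gene], self.causal_effects[gene]):
                j = idx[snp]
                maf = recs["maf"].iloc[j] if "maf" in recs else panel.dosages[:, j].mean() / 2
                sd = np.sqrt(max(2 * maf * (1 - maf), 1e-12))
                out[gi] += eff * (panel.dosages[:, j] - 2 * maf) / sd
        return pd.DataFrame(out, index=self.gene_ids, columns=panel.individual_ids)


@dataclass
class FeatureSet:
    """Per-gene reference and personalized feature vectors."""

    reference: dict[str, np.ndarray]  # gene -> (D,)
    personalized: dict[str, np.ndarray]  # gene -> (n_individuals, D)
    individual_ids: list[str]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _snp_layout(config: SimConfig) -> pd.DataFrame:
    """Deterministic SNP map: ids, positions, per-SNP MAF, gene block labels."""
    rng = config.rng("layout")
    rows = []
    per_chrom_blocks: dict[int, int] = {}
    for g in range(config.n_genes):
        chrom = 1 + g % _N_CHROMS
        block = per_chrom_blocks.get(chrom, 0)
        per_chrom_blocks[chrom] = block + 1
        base = block * _GENE_SPACING_BP + 1_500_000
        mafs = rng.uniform(*config.maf_range, size=config.snps_per_gene)
        for j in range(config.snps_per_gene):
            pos = base + (j - config.snps_per_gene // 2) * _SNP_SPACING_BP
            rows.append(
                {
                    "snp_id": f"rs{g}_{j}",
                    "chrom": str(chrom),
                    "pos": pos,
                    "ref_allele": "A",
                    "eff_allele": "G",
                    "maf": mafs[j],
                    "gene": f"gene{g}",
                    "tss": base,
                }
            )
    return pd.DataFrame(rows)


def gene_annotation(config: SimConfig) -> GeneAnnotation:
    """TSS annotation consistent with the simulated SNP layout."""
    layout = _snp_layout(config)
    genes = layout.drop_duplicates("gene")
    table = pd.DataFrame(
        {
            "gene_id": genes["gene"].to_numpy(),
            "chrom": genes["chrom"].to_numpy(),
            "tss": genes["tss"].to_numpy(),
            "strand": "+",
        }
    )
    return GeneAnnotation(table=table)


def _draw_dosages(config: SimConfig, layout: pd.DataFrame, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """AR(1) latent-Gaussian haplotypes thresholded at Phi^-1(maf), summed."""
    m = len(layout)
    thresholds = ndtri(layout["maf"].to_numpy())
    dosage = np.zeros((n, m))
    rho = config.ld_rho
    scale = np.sqrt(1 - rho**2)
    new_block = (layout["gene"] != layout["gene"].shift()).to_numpy()
    for _hap in range(2):
        z = np.empty((n, m))
        innov = rng.standard_normal((n, m))
        for j in range(m):
            if new_block[j]:
                z[:, j] = innov[:, j]
            else:
                z[:, j] = rho * z[:, j - 1] + scale * innov[:, j]
        dosage += z < thresholds
    return dosage


def simulate_genotypes(config: SimConfig, n_individuals: int | None = None,
                       stream: str = "genotypes") -> GenotypePanel:
    """Simulate an LD-structured dosage panel (one cis block per gene)."""
    layout = _snp_layout(config)
    n = config.n_individuals if n_individuals is None else n_individuals
    dosages = _draw_dosages(config, layout, n, config.rng(stream))
    return GenotypePanel(
        dosages=dosages,
        snp_records=layout[["snp_id", "chrom", "pos", "ref_allele", "eff_allele", "maf", "gene"]].copy(),
        individual_ids=[f"ind{i}" for i in range(n)],
    )


def expected_adjacent_dosage_corr(maf: float, rho: float) -> float:
    """Closed-form adjacent-SNP dosage correlation under the AR(1) threshold model.

    Dosages are sums of two iid haplotypes, so their correlation equals the
    haplotype allele-indicator correlation, a tetrachoric orthant probability.
    """
    from scipy.stats import multivariate_normal

    t = ndtri(maf)
    p11 = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf([t, t])
    return (p11 - maf**2) / (maf * (1 - maf))


# ---------------------------------------------------------------------------
# cis architecture and trait effects
# ---------------------------------------------------------------------------


def simulate_cis_architecture(panel: GenotypePanel, config: SimConfig) -> GroundTruth:
    """Plant sparse cis effects per gene and trait effects for a subset of genes."""
    rng = config.rng("architecture")
    recs = panel.snp_records
    genes = recs["gene"].drop_duplicates().tolist()
    baselines, causal_snps, causal_effects = {}, {}, {}
    for gene in genes:
        baselines[gene] = float(rng.normal())
        snps = recs.loc[recs["gene"] == gene, "snp_id"].tolist()
        k = config.n_causal_snps_per_gene
        chosen = list(rng.choice(snps, size=k, replace=False)) if k else []
        causal_snps[gene] = chosen
        causal_effects[gene] = rng.normal(0, config.effect_sd, size=k)
    truth = GroundTruth(
        gene_ids=genes,
        baselines=baselines,
        causal_snps=causal_snps,
        causal_effects=causal_effects,
        latent_expression=pd.DataFrame(),
    )
    truth.latent_expression = truth.latent_for(panel)
    n_causal = min(config.n_causal_genes, len(genes))
    trait_genes = list(rng.choice(genes, size=n_causal, replace=False))
    truth.trait_causal_genes = trait_genes
    # random sign, magnitude floored at half the nominal scale so a gene
    # labelled causal carries a detectable effect rather than one drawn at ~0
    truth.trait_effects = {
        g: float(rng.choice([-1.0, 1.0]) * config.gene_trait_effect_sd
                 * (0.5 + abs(rng.normal())))
        for g in trait_genes
    }
    return truth


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


def _gene_loadings(config: SimConfig) -> dict[str, np.ndarray]:
    rng = config.rng("loadings")
    d = config.feature_dim
    shared = rng.standard_normal(d) / np.sqrt(d)
    loadings = {}
    for g in range(config.n_genes):
        jitter = rng.standard_normal(d) / np.sqrt(d)
        loadings[f"gene{g}"] = shared + config.loading_jitter * jitter
    return loadings


def _saturating(u: np.ndarray, strength: float) -> np.ndarray:
    return u + strength * np.tanh(u)


def simulate_features(panel: GenotypePanel, truth: GroundTruth,
                      config: SimConfig, stream: str = "features") -> FeatureSet:
    """Per-gene feature vectors as noisy (optionally nonlinear) images of genotype."""
    rng = config.rng(stream)
    loadings = _gene_loadings(config)
    latent = truth.latent_for(panel)
    reference, personalized = {}, {}
    for gene in truth.gene_ids:
        u = loadings[gene]
        g = latent.loc[gene].to_numpy()
        signal = _saturating(truth.baselines[gene] + g, config.nonlinearity_strength)
        ref_signal = _saturating(
            truth.baselines[gene] + g.mean(), config.nonlinearity_strength
        )
        if config.feature_noise_sd > 0:
            noise = rng.normal(
                0, config.feature_noise_sd, size=(panel.n_individuals, config.feature_dim)
            )
            ref_noise = rng.normal(0, config.feature_noise_sd, size=config.feature_dim)
        else:
            noise = 0.0
            ref_noise = 0.0
        personalized[gene] = np.outer(signal, u) + noise
        reference[gene] = ref_signal * u + ref_noise
    return FeatureSet(
        reference=reference,
        personalized=personalized,
        individual_ids=list(panel.individual_ids),
    )


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------


def simulate_single_cell(truth: GroundTruth, config: SimConfig) -> CellMatrix:
    """Sparse NB single-cell counts whose pseudobulk tracks the latent expression.

    Per cell, relative gene abundance is ``softplus(b_g + g_i)`` normalized
    across genes, scaled by a lognormal library size; counts are negative
    binomial with size ``nb_dispersion`` (Poisson in the infinite-dispersion
    limit).
    """
    rng = config.rng("cells")
    genes = truth.gene_ids
    individuals = list(truth.latent_expression.columns)
    n_cells = config.cells_per_individual * len(individuals)
    rows, metas, cell_ids = [], [], []
    for i, ind in enumerate(individuals):
        rel = softplus(
            np.array([truth.baselines[g] for g in genes])
            + truth.latent_expression[ind].to_numpy()
        )
        total = rel.sum()
        props = rel / total if total > 0 else np.zeros_like(rel)
        lib = rng.lognormal(np.log(config.library_size_mean), 0.3, size=config.cells_per_individual)
        mu = np.outer(lib, props)
        if np.isinf(config.nb_dispersion):
            counts = rng.poisson(mu)
        else:
            r = config.nb_dispersion
            p = r / (r + np.maximum(mu, 1e-300))
            counts = np.where(mu > 0, rng.negative_binomial(r, p), 0)
        rows.append(counts)
        for c in range(config.cells_per_individual):
            cell_ids.append(f"{ind}_cell{c}")
            metas.append(
                {
                    "individual_id": ind,
                    "cell_type": config.cell_type,
                    "n_count_total": int(counts[c].sum()),
                    "mito_pct": float(100 * rng.beta(2, 30)),
                }
            )
    counts = sp.csr_matrix(np.vstack(rows) if rows else np.zeros((0, len(genes))), dtype=np.int64)
    meta = pd.DataFrame(metas, index=pd.Index(cell_ids, name="cell_id"))
    return CellMatrix(counts=counts, gene_ids=genes, cell_ids=cell_ids, cell_meta=meta)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------


def marginal_ols(dosages: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-SNP simple-regression effect sizes and standard errors."""
    n = len(y)
    xc = dosages - dosages.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    sxx = np.where(sxx > 0, sxx, np.nan)
    beta = xc.T @ yc / sxx
    rss = (yc**2).sum() - beta**2 * sxx
    se = np.sqrt(np.maximum(rss, 0) / (n - 2) / sxx)
    return beta, se


def simulate_gwas(config: SimConfig, truth: GroundTruth,
                  null: bool = False) -> tuple[GWASSummary, np.ndarray, GenotypePanel]:
    """Marginal GWAS summary statistics from a fresh cohort.

    Returns the summary table, the individual-level trait vector, and the
    cohort genotype panel (kept for individual-level oracle comparisons).
    With ``null=True`` the planted gene effects are ignored and the trait is
    pure noise.
    """
    cohort = simulate_genotypes(config, n_individuals=config.gwas_n, stream="gwas_genotypes")
    rng = config.rng("gwas_trait")
    latent = truth.latent_for(cohort)
    genetic = np.zeros(config.gwas_n)
    if not null and config.h2_trait > 0:
        for gene, eff in truth.trait_effects.items():
            genetic += eff * latent.loc[gene].to_numpy()
    var_g = genetic.var()
    if var_g == 0:  # null model (no effects, or h2 = 0)
        noise_sd = 1.0
    elif config.h2_trait >= 1:
        noise_sd = 0.0
    else:
        noise_sd = np.sqrt(var_g * (1 - config.h2_trait) / config.h2_trait)
    y = genetic + rng.normal(0, noise_sd, size=config.gwas_n)
    beta, se = marginal_ols(cohort.dosages, y)
    ok = np.isfinite(beta) & np.isfinite(se) & (se > 0)
    recs = cohort.snp_records
    table = pd.DataFrame(
        {
            "variant_id": recs["snp_id"],
            "chromosome": recs["chrom"],
            "position": recs["pos"],
            "effect_allele": recs["eff_allele"],
            "non_effect_allele": recs["ref_allele"],
            "beta": beta,
            "standard_error": se,
        }
    )[ok]
    return GWASSummary(table=table, n_dropped=int((~ok).sum())), y, cohort


# ---------------------------------------------------------------------------
# convenience bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    config: SimConfig
    panel: GenotypePanel
    truth: GroundTruth
    features: FeatureSet
    cells: CellMatrix
    annotation: GeneAnnotation


def simulate_all(config: SimConfig) -> SimulatedStudy:
    """Generate the full input bundle (panel, truth, features, cells, annotation)."""
    panel = simulate_genotypes(config)
    truth = simulate_cis_architecture(panel, config)
    features = simulate_features(panel, truth, config)
    cells = simulate_single_cell(truth, config)
    return SimulatedStudy(
        config=config,
        panel=panel,
        truth=truth,
        features=features,
        cells=cells,
        annotation=gene_annotation(config),
    )


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
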