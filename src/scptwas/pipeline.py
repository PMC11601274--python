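"""End-to-end orchestration of the three framework steps with one seed.

``run_pipeline`` executes, on a synthetic study: data generation ->
pseudobulk QC/aggregation/rank targets -> MLP training on reference features
-> in-silico panel -> elastic-net linearization (weight DB) -> GWAS summary
statistics -> gene-trait association -> evaluation summaries. Each stage
draws from a named substream of the global seed, results are written as TSV/
JSON under the run directory, and a manifest records content hashes so
deterministic stages are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, ctpred, evaluation, io_formats, linearization, pseudobulk
from .feature_extraction import SyntheticExtractor
from .synthetic_data import SimConfig, simulate_all, simulate_gwas

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Structured configuration for a full synthetic run."""

    sim: SimConfig = field(default_factory=SimConfig)
    ctpred_hidden_dim: int = 64
    ctpred_dropout: float = 0.05
    ctpred_weight_decay: float = 5e-4
    ctpred_learning_rate: float = 1e-3
    ctpred_max_epochs: int = 80
    min_cells: int = 125
    qc_max_total: float = 10000
    qc_max_mito_pct: float = 10
    en_folds: int = 10
    en_l1_ratio: float = 0.5
    cis_window_bp: int = 1_000_000
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sim_kwargs = raw.pop("sim", {})
        known = {f.name for f in dataclasses.fields(SimConfig)}
        bad = set(sim_kwargs) - known
        if bad:
            raise ValueError(f"unknown sim config keys: {sorted(bad)}")
        cfg = cls(sim=SimConfig(**sim_kwargs), **raw)
        return cfg


def validate_config(config: RunConfig) -> dict:
    """Range checks and advisory warnings; report-based, never raises."""
    errors, warnings_ = [], []
    if not (0 <= config.ctpred_dropout < 1):
        errors.append(f"dropout {config.ctpred_dropout} outside [0, 1)")
    if config.min_cells < 125:
        warnings_.append(
            f"min_cells={config.min_cells} is below the 125-cell floor used for training data"
        )
    if config.qc_max_mito_pct > 100 or config.qc_max_mito_pct < 0:
        errors.append("qc_max_mito_pct outside [0, 100]")
    if config.en_folds < 2:
        errors.append("en_folds must be >= 2")
    if not (0 < config.alpha < 1):
        errors.append("alpha must lie in (0, 1)")
    if config.sim.n_individuals < config.en_folds:
        errors.append("panel smaller than the number of CV folds")
    return {"errors": errors, "warnings": warnings_, "valid": not errors}


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run all stages; returns the manifest dict (also written to manifest.json)."""
    report = validate_config(config)
    if not report["valid"]:
        raise ValueError(f"invalid config: {report['errors']}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.sim, seed=config.seed)
    manifest: dict = {"config_seed": config.seed, "stages": {}, "warnings": report["warnings"]}

    # stage 1: synthetic study + pseudobulk targets
    study = simulate_all(sim)
    cells = pseudobulk.qc_filter_cells(study.cells, config.qc_max_total, config.qc_max_mito_pct)
    pb = pseudobulk.aggregate(cells, sim.cell_type, min_cells=min(config.min_cells, cells.n_cells))
    targets = pseudobulk.rank_percentile_crossgene(pb)
    manifest["stages"]["pseudobulk"] = {
        "n_cells_kept": cells.n_cells, "total_cells": pb.total_cells,
    }

    # stage 2: train the expression MLP on reference features
    tr, va, te = ctpred.default_split_chroms(study.annotation)
    split = ctpred.split_by_chromosome(study.annotation, tr, va, te)
    mlp_config = ctpred.CtPredConfig(
        input_dim=sim.feature_dim,
        hidden_dim=config.ctpred_hidden_dim,
        dropout=config.ctpred_dropout,
        weight_decay=config.ctpred_weight_decay,
        learning_rate=config.ctpred_learning_rate,
        max_epochs=config.ctpred_max_epochs,
        seed=config.seed,
    )
    model = ctpred.train(study.features.reference, targets.values, split, mlp_config)
    manifest["stages"]["ctpred"] = {
        "n_parameters": model.n_parameters,
        "best_val_loss": float(model.history["best_val"].iloc[-1]),
        "epochs_run": int(len(model.history)),
    }

    # stage 3: linearize into a weight database
    extractor = SyntheticExtractor(sim, study.panel, study.truth)
    insilico = linearization.build_insilico_panel(
        model, extractor, study.panel, study.truth.gene_ids
    )
    en_config = linearization.ElasticNetConfig(
        cis_window_bp=config.cis_window_bp, l1_ratio=config.en_l1_ratio,
        folds=config.en_folds, seed=config.seed,
    )
    db, fit_summary = linearization.linearize_all(insilico, study.panel, study.annotation, en_config)
    db_path, cov_path = out / "weights.db", out / "covariances.txt.gz"
    io_formats.write_weight_db(db, db_path, cov_path)
    fit_summary.to_csv(out / "linearization.tsv", sep="\t", index=False)
    manifest["stages"]["linearization"] = {
        "n_converged": int(fit_summary["converged"].sum()),
        "n_attempted": int(len(fit_summary)),
        "db_sha": _sha(db_path),
    }

    # stage 4: GWAS + association + evaluation
    gwas, _, _ = simulate_gwas(sim, study.truth)
    io_formats.write_gwas(gwas, out / "gwas.tsv")
    results = association.associate_all(db, gwas, cell_type=sim.cell_type)
    results.to_csv(out / "associations.tsv", sep="\t", index=False)
    threshold = association.bonferroni(config.alpha, max(len(results), 1))
    sig = results[results["pvalue"] < threshold]["gene"].tolist()
    causal = set(study.truth.trait_causal_genes)
    manifest["stages"]["association"] = {
        "n_genes_tested": int(len(results)),
        "bonferroni_threshold": threshold,
        "n_significant": len(sig),
        "n_significant_causal": len(causal & set(sig)),
        "results_sha": _sha(out / "associations.tsv"),
    }
    if len(results) >= 2:
        pi1 = evaluation.estimate_pi1(results["pvalue"].to_numpy(), method="fixed")
        manifest["stages"]["evaluation"] = {"pi1": pi1.pi1, "m1": pi1.m1}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
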