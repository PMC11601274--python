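import numpy as np
import pandas as pd
import pytest

from scptwas import ctpred, linearization, pseudobulk
from scptwas.feature_extraction import SyntheticExtractor
from scptwas.io_formats import GenotypePanel, read_weight_db, write_weight_db
from scptwas.linearization import (
    ElasticNetConfig,
    InSilicoPanel,
    build_insilico_panel,
    fit_elastic_net,
    fit_pen_baseline,
    linearize_all,
    validate_linearization,
    weight_db_from_weights,
)
from scptwas.synthetic_data import (
    SimConfig,
    simulate_all,
    simulate_cis_architecture,
    simulate_features,
    simulate_genotypes,
    gene_annotation,
)


@pytest.fixture(scope="module")
def en_panel():
    cfg = SimConfig(n_genes=1, n_individuals=200, snps_per_gene=30,
                    n_causal_snps_per_gene=1, seed=5)
    panel = simulate_genotypes(cfg)
    truth = simulate_cis_architecture(panel, cfg)
    return cfg, panel, truth


class TestFitElasticNet:
    def test_planted_single_snp_recovered(self, en_panel):
        cfg, panel, truth = en_panel
        gene = truth.gene_ids[0]
        snp = truth.causal_snps[gene][0]
        j = panel.snp_records["snp_id"].tolist().index(snp)
        d = panel.dosages[:, j]
        expr = pd.Series(2 * (d - d.mean()) / d.std(), index=panel.individual_ids)
        rec = gene_annotation(cfg).record(gene)
        pred, _ = fit_elastic_net(gene, expr, panel, rec["chrom"], int(rec["tss"]))
        assert pred.converged
        assert pred.cv_metric > 0.99
        w = pred.weights.set_index("snp_id")["weight"]
        assert w.abs().idxmax() == snp
        # fitted values reproduce the (noise-free) expression
        fitted = pred.predict(panel)
        assert np.corrcoef(fitted, expr)[0, 1] > 0.999

    def test_pure_noise_rarely_converges(self, en_panel):
        cfg, panel, truth = en_panel
        rec = gene_annotation(cfg).record(truth.gene_ids[0])
        rng = np.random.default_rng(0)
        n_conv = 0
        for rep in range(50):
            y = pd.Series(rng.normal(size=panel.n_individuals),
                          index=panel.individual_ids)
            p, _ = fit_elastic_net("noise", y, panel, rec["chrom"], int(rec["tss"]),
                                   ElasticNetConfig(seed=rep))
            n_conv += p.converged
        assert n_conv / 50 <= 0.20

    def test_individual_order_invariance(self, en_panel):
        cfg, panel, truth = en_panel
        gene = truth.gene_ids[0]
        rec = gene_annotation(cfg).record(gene)
        rng = np.random.default_rng(1)
        expr = pd.Series(
            truth.latent_expression.loc[gene].to_numpy() + rng.normal(0, 0.1, panel.n_individuals),
            index=panel.individual_ids,
        )
        pred_a, _ = fit_elastic_net(gene, expr, panel, rec["chrom"], int(rec["tss"]))
        perm = rng.permutation(panel.n_individuals)
        shuffled = GenotypePanel(
            dosages=panel.dosages[perm],
            snp_records=panel.snp_records.copy(),
            individual_ids=[panel.individual_ids[i] for i in perm],
        )
        pred_b, _ = fit_elastic_net(gene, expr, shuffled, rec["chrom"], int(rec["tss"]))
        pd.testing.assert_frame_equal(pred_a.weights, pred_b.weights)

    def test_no_cis_snps_rejected(self, en_panel):
        cfg, panel, truth = en_panel
        y = pd.Series(np.zeros(panel.n_individuals), index=panel.individual_ids)
        with pytest.raises(ValueError, match="no cis SNPs"):
            fit_elastic_net("g", y, panel, "22", 1, ElasticNetConfig())


class TestInSilicoPanel:
    @pytest.fixture(scope="class")
    def trained(self, tiny_config, tiny_study):
        targets = pseudobulk.rank_percentile_crossgene(
            pseudobulk.aggregate(tiny_study.cells, tiny_config.cell_type, min_cells=1)
        )
        split = ctpred.split_by_chromosome(
            tiny_study.annotation, *ctpred.default_split_chroms(tiny_study.annotation)
        )
        model = ctpred.train(
            tiny_study.features.reference, targets.values, split,
            ctpred.CtPredConfig(input_dim=tiny_config.feature_dim,
                                learning_rate=3e-3, max_epochs=30, seed=0),
        )
        extractor = SyntheticExtractor(tiny_config, tiny_study.panel, tiny_study.truth)
        return model, extractor

    def test_shape_and_determinism(self, tiny_study, trained):
        model, extractor = trained
        genes = tiny_study.truth.gene_ids[:2]
        a = build_insilico_panel(model, extractor, tiny_study.panel, genes)
        b = build_insilico_panel(model, extractor, tiny_study.panel, genes)
        assert a.expression.shape == (2, tiny_study.panel.n_individuals)
        pd.testing.assert_frame_equal(a.expression, b.expression)

    def test_identical_genotypes_identical_predictions(self, tiny_config, tiny_study, trained):
        model, _ = trained
        panel = tiny_study.panel
        dup = GenotypePanel(
            dosages=np.vstack([panel.dosages[0], panel.dosages]),
            snp_records=panel.snp_records.copy(),
            individual_ids=["dup"] + panel.individual_ids,
        )
        cfg = SimConfig(**{**tiny_config.__dict__, "feature_noise_sd": 0.0})
        ex = SyntheticExtractor(cfg, dup, tiny_study.truth)
        ip = build_insilico_panel(model, ex, dup, ["gene0"])
        assert ip.expression.loc["gene0", "dup"] == ip.expression.loc["gene0", "ind0"]

    def test_provenance_tracks_model_weights(self, tiny_study, trained):
        model, extractor = trained
        genes = ["gene0"]
        h1 = build_insilico_panel(model, extractor, tiny_study.panel, genes).provenance
        model.weights[0] = model.weights[0] + 0.1
        h2 = build_insilico_panel(model, extractor, tiny_study.panel, genes).provenance
        model.weights[0] = model.weights[0] - 0.1
        assert h1["model_hash"] != h2["model_hash"]


class TestLinearizeAll:
    @pytest.fixture(scope="class")
    def fitted(self):
        cfg = SimConfig(n_genes=10, n_individuals=150, snps_per_gene=15,
                        feature_dim=8, n_causal_snps_per_gene=2, seed=31)
        panel = simulate_genotypes(cfg)
        truth = simulate_cis_architecture(panel, cfg)
        expr = truth.latent_expression.copy()
        for g in truth.gene_ids:
            expr.loc[g] += truth.baselines[g]
        db, summary = linearize_all(
            InSilicoPanel(expression=expr), panel, gene_annotation(cfg)
        )
        return db, summary

    def test_extra_rows_equal_converged_genes(self, fitted):
        db, summary = fitted
        assert len(db.extra) == int(summary["converged"].sum())

    def test_covariances_positive_semidefinite(self, fitted):
        db, _ = fitted
        for gene, (rsids, cov) in db.covariances.items():
            eig = np.linalg.eigvalsh(cov)
            assert eig.min() >= -1e-8

    def test_db_roundtrips_through_files(self, fitted, tmp_path):
        db, _ = fitted
        write_weight_db(db, tmp_path / "w.db", tmp_path / "c.txt.gz")
        back = read_weight_db(tmp_path / "w.db", tmp_path / "c.txt.gz")
        pd.testing.assert_frame_equal(
            back.weights.sort_values(["gene", "rsid"]).reset_index(drop=True),
            db.weights.sort_values(["gene", "rsid"]).reset_index(drop=True),
        )

    def test_converged_count_increases_with_signal_strength(self):
        counts = []
        for effect_sd in (0.02, 0.2, 1.0):
            cfg = SimConfig(n_genes=12, n_individuals=100, snps_per_gene=10,
                            feature_dim=8, effect_sd=effect_sd, seed=37)
            panel = simulate_genotypes(cfg)
            truth = simulate_cis_architecture(panel, cfg)
            rng = np.random.default_rng(37)
            expr = truth.latent_expression + rng.normal(
                0, 0.5, size=truth.latent_expression.shape
            )
            _, summary = linearize_all(
                InSilicoPanel(expression=expr), panel, gene_annotation(cfg)
            )
            counts.append(int(summary["converged"].sum()))
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[0] < counts[2]


class TestValidateLinearization:
    def _expr_from_features(self, cfg):
        panel = simulate_genotypes(cfg)
        truth = simulate_cis_architecture(panel, cfg)
        feats = simulate_features(panel, truth, cfg)
        readout = np.random.default_rng(cfg.seed).standard_normal(cfg.feature_dim)
        expr = pd.DataFrame(
            {ind: 0.0 for ind in panel.individual_ids}, index=truth.gene_ids
        )
        for gene in truth.gene_ids:
            expr.loc[gene] = feats.personalized[gene] @ readout
        return panel, gene_annotation(cfg), expr

    def test_linear_predictions_high_fidelity(self):
        cfg = SimConfig(n_genes=10, n_individuals=150, snps_per_gene=15,
                        n_causal_snps_per_gene=5, feature_dim=8,
                        feature_noise_sd=0.0, nonlinearity_strength=0.0, seed=41)
        panel, ann, expr = self._expr_from_features(cfg)
        rho = validate_linearization(InSilicoPanel(expression=expr), panel, ann)
        assert rho.median() > 0.95

    def test_constant_predictions_flagged(self):
        cfg = SimConfig(n_genes=3, n_individuals=60, snps_per_gene=5,
                        feature_dim=4, seed=2)
        panel = simulate_genotypes(cfg)
        expr = pd.DataFrame(
            np.ones((3, 60)), index=[f"gene{i}" for i in range(3)],
            columns=panel.individual_ids,
        )
        rho = validate_linearization(InSilicoPanel(expression=expr), panel,
                                     gene_annotation(cfg))
        assert rho.isna().all()

    def test_invariant_to_monotone_transform(self):
        cfg = SimConfig(n_genes=4, n_individuals=100, snps_per_gene=10,
                        n_causal_snps_per_gene=3, feature_dim=8,
                        feature_noise_sd=0.0, nonlinearity_strength=0.0, seed=43)
        panel, ann, expr = self._expr_from_features(cfg)
        rho_a = validate_linearization(InSilicoPanel(expression=expr), panel, ann)
        # strictly increasing transform of the predictions
        rho_b = validate_linearization(
            InSilicoPanel(expression=expr * 3 + 7), panel, ann
        )
        sp_a = rho_a.sort_index()
        sp_b = rho_b.sort_index()
        # Spearman is exactly invariant; residual differences come only from
        # the coordinate-descent solver tolerance at the rescaled y
        np.testing.assert_allclose(sp_a.to_numpy(), sp_b.to_numpy(), atol=1e-3)


class TestPENBaseline:
    def test_pen_converges_for_fewer_genes_than_insilico(self):
        cfg = SimConfig(n_genes=20, n_individuals=200, snps_per_gene=20,
                        feature_dim=16, n_causal_snps_per_gene=2, effect_sd=0.3,
                        cells_per_individual=5, library_size_mean=500,
                        nb_dispersion=0.5, seed=9)
        study = simulate_all(cfg)
        expr = study.truth.latent_expression.copy()
        for g in study.truth.gene_ids:
            expr.loc[g] += study.truth.baselines[g]
        _, summary_insilico = linearize_all(
            InSilicoPanel(expression=expr), study.panel, study.annotation
        )
        keep = study.panel.individual_ids[:29]
        cells = study.cells.subset_cells(
            study.cells.cell_meta["individual_id"].isin(keep).to_numpy()
        )
        pb = pseudobulk.aggregate(cells, cfg.cell_type, min_cells=100)
        _, summary_pen = fit_pen_baseline(pb, study.panel, study.annotation)
        assert summary_pen["converged"].mean() < summary_insilico["converged"].mean()

    def test_zero_individuals_rejected(self, tiny_study):
        pb = pseudobulk.aggregate(tiny_study.cells, "synthetic", min_cells=1)
        empty = pseudobulk.PseudobulkMatrix(
            cell_type="synthetic",
            counts=pb.counts.iloc[:, :0],
            n_cells=pb.n_cells.iloc[:0],
        )
        with pytest.raises(ValueError, match="no individuals"):
            fit_pen_baseline(empty, tiny_study.panel, tiny_study.annotation)


def test_weight_db_from_explicit_weights(tiny_study):
    panel = tiny_study.panel
    truth = tiny_study.truth
    gene = truth.gene_ids[0]
    wmap = {snp: float(w) for snp, w in
            zip(truth.causal_snps[gene], truth.causal_effects[gene])}
    db = weight_db_from_weights({gene: wmap}, panel)
    assert db.genes == [gene]
    assert set(db.gene_weights(gene)["rsid"]) == set(wmap)
    rsids, cov = db.covariances[gene]
    assert cov.shape == (len(wmap), len(wmap))
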