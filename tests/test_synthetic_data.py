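import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from scipy.special import ndtri

from scptwas.synthetic_data import (
    SimConfig,
    simulate_all,
    simulate_cis_architecture,
    simulate_features,
    simulate_genotypes,
    simulate_gwas,
    simulate_single_cell,
)


def _adjacent_corrs(panel):
    out = []
    for _, grp in panel.snp_records.groupby("gene"):
        idx = grp.index.to_numpy()
        d = panel.dosages[:, idx]
        for j in range(d.shape[1] - 1):
            out.append(np.corrcoef(d[:, j], d[:, j + 1])[0, 1])
    return np.array(out)


def _tetrachoric_corr_oracle(maf, rho):
    """Brute-force integration of the bivariate-normal orthant probability."""
    t = ndtri(maf)
    density = lambda y, x: np.exp(
        -(x**2 - 2 * rho * x * y + y**2) / (2 * (1 - rho**2))
    ) / (2 * np.pi * np.sqrt(1 - rho**2))
    p11, _ = integrate.dblquad(density, -8, t, -8, lambda _: t)
    return (p11 - maf**2) / (maf * (1 - maf))


class TestGenotypes:
    def test_no_ld_gives_near_zero_adjacent_correlation(self):
        cfg = SimConfig(n_genes=5, n_individuals=2000, snps_per_gene=40,
                        maf_range=(0.3, 0.3), ld_rho=0.0, seed=7)
        corrs = _adjacent_corrs(simulate_genotypes(cfg))
        assert abs(corrs.mean()) < 0.05
        assert np.abs(corrs).max() < 0.1

    def test_strong_ld_matches_thresholded_gaussian_value(self):
        cfg = SimConfig(n_genes=5, n_individuals=2000, snps_per_gene=40,
                        maf_range=(0.3, 0.3), ld_rho=0.9, seed=7)
        corrs = _adjacent_corrs(simulate_genotypes(cfg))
        expected = _tetrachoric_corr_oracle(0.3, 0.9)
        assert corrs.mean() == pytest.approx(expected, abs=0.1)

    def test_maf_half_gives_mean_dosage_one(self):
        cfg = SimConfig(n_genes=2, n_individuals=5000, snps_per_gene=20,
                        maf_range=(0.5, 0.5), seed=1)
        assert simulate_genotypes(cfg).dosages.mean() == pytest.approx(1.0, abs=0.05)

    def test_determinism(self):
        cfg = SimConfig(n_genes=3, n_individuals=50, seed=13)
        a, b = simulate_genotypes(cfg), simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)


class TestCisArchitecture:
    def test_single_causal_snp_perfect_correlation(self):
        cfg = SimConfig(n_genes=4, n_individuals=300, n_causal_snps_per_gene=1, seed=2)
        panel = simulate_genotypes(cfg)
        truth = simulate_cis_architecture(panel, cfg)
        for gene in truth.gene_ids:
            snp = truth.causal_snps[gene][0]
            j = panel.snp_records["snp_id"].tolist().index(snp)
            g = truth.latent_expression.loc[gene].to_numpy()
            r = abs(np.corrcoef(g, panel.dosages[:, j])[0, 1])
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_zero_causal_snps_gives_zero_latent(self):
        cfg = SimConfig(n_genes=3, n_individuals=50, n_causal_snps_per_gene=0, seed=2)
        panel = simulate_genotypes(cfg)
        truth = simulate_cis_architecture(panel, cfg)
        assert (truth.latent_expression.to_numpy() == 0).all()

    def test_equal_effects_split_variance(self):
        """Two equal-effect causal SNPs in LD-free blocks each explain ~1/2 var(g)."""
        cfg = SimConfig(n_genes=6, n_individuals=4000, snps_per_gene=10,
                        n_causal_snps_per_gene=2, ld_rho=0.0, seed=3)
        panel = simulate_genotypes(cfg)
        truth = simulate_cis_architecture(panel, cfg)
        for gene in truth.gene_ids:
            e = np.abs(truth.causal_effects[gene])
            e[:] = 1.0
            truth.causal_effects[gene] = e
        latent = truth.latent_for(panel)
        for gene in truth.gene_ids:
            g = latent.loc[gene].to_numpy()
            snp = truth.causal_snps[gene][0]
            j = panel.snp_records["snp_id"].tolist().index(snp)
            d = panel.dosages[:, j]
            share = np.corrcoef(g, d)[0, 1] ** 2
            assert share == pytest.approx(0.5, abs=0.07)

    def test_trait_effects_have_floored_magnitude(self):
        cfg = SimConfig(n_genes=10, n_individuals=50, n_causal_genes=5,
                        gene_trait_effect_sd=0.4, seed=5)
        truth = simulate_cis_architecture(simulate_genotypes(cfg), cfg)
        assert len(truth.trait_causal_genes) == 5
        for eff in truth.trait_effects.values():
            assert abs(eff) >= 0.5 * 0.4


class TestFeatures:
    def test_noise_free_linear_features_are_rank_one(self):
        cfg = SimConfig(n_genes=3, n_individuals=60, feature_dim=8,
                        feature_noise_sd=0.0, nonlinearity_strength=0.0, seed=4)
        panel = simulate_genotypes(cfg)
        truth = simulate_cis_architecture(panel, cfg)
        feats = simulate_features(panel, truth, cfg)
        for gene in truth.gene_ids:
            mat = feats.personalized[gene]
            sv = np.linalg.svd(mat - mat.mean(axis=0), compute_uv=False)
            assert sv[1] < 1e-8 * max(sv[0], 1)

    def test_same_seed_identical(self):
        cfg = SimConfig(n_genes=2, n_individuals=30, feature_dim=8, seed=9)
        panel = simulate_genotypes(cfg)
        truth = simulate_cis_architecture(panel, cfg)
        a = simulate_features(panel, truth, cfg)
        b = simulate_features(panel, truth, cfg)
        for gene in truth.gene_ids:
            np.testing.assert_array_equal(a.personalized[gene], b.personalized[gene])
            np.testing.assert_array_equal(a.reference[gene], b.reference[gene])

    def test_feature_variance_monotone_in_noise(self):
        variances = []
        for noise in (0.0, 0.5, 2.0):
            cfg = SimConfig(n_genes=2, n_individuals=200, feature_dim=16,
                            feature_noise_sd=noise, seed=11)
            panel = simulate_genotypes(cfg)
            truth = simulate_cis_architecture(panel, cfg)
            feats = simulate_features(panel, truth, cfg)
            variances.append(
                np.mean([feats.personalized[g].var(axis=0).mean() for g in truth.gene_ids])
            )
        assert variances[0] < variances[1] < variances[2]


class TestSingleCell:
    def test_poisson_limit_variance_mean_ratio(self):
        cfg = SimConfig(n_genes=5, n_individuals=4, cells_per_individual=3000,
                        nb_dispersion=np.inf, library_size_mean=1000, seed=6)
        panel = simulate_genotypes(cfg)
        truth = simulate_cis_architecture(panel, cfg)
        cells = simulate_single_cell(truth, cfg)
        counts = np.asarray(cells.counts.todense(), float)
        # condition on one individual; library-size lognormal still inflates
        # variance, so compare against the NB alternative rather than 1.0
        ind_mask = (cells.cell_meta["individual_id"] == "ind0").to_numpy()
        sub = counts[ind_mask]
        ratio = sub.var(axis=0) / np.maximum(sub.mean(axis=0), 1e-9)
        cfg_nb = SimConfig(**{**cfg.__dict__, "nb_dispersion": 0.5})
        cells_nb = simulate_single_cell(truth, cfg_nb)
        sub_nb = np.asarray(cells_nb.counts.todense(), float)[ind_mask]
        ratio_nb = sub_nb.var(axis=0) / np.maximum(sub_nb.mean(axis=0), 1e-9)
        assert ratio.mean() < 0.2 * ratio_nb.mean()

    def test_higher_latent_expression_raises_pseudobulk_share(self):
        cfg = SimConfig(n_genes=6, n_individuals=2, cells_per_individual=2000,
                        library_size_mean=2000, seed=8)
        panel = simulate_genotypes(cfg)
        truth = simulate_cis_architecture(panel, cfg)
        gene = truth.gene_ids[0]
        truth.latent_expression.loc[gene, "ind1"] = (
            truth.latent_expression.loc[gene, "ind0"] + 2.0
        )
        cells = simulate_single_cell(truth, cfg)
        counts = np.asarray(cells.counts.todense(), float)
        meta = cells.cell_meta
        share = {}
        for ind in ("ind0", "ind1"):
            sub = counts[(meta["individual_id"] == ind).to_numpy()]
            share[ind] = sub[:, 0].sum() / sub.sum()
        assert share["ind1"] > share["ind0"]

    def test_all_zero_counts_handled(self):
        cfg = SimConfig(n_genes=2, n_individuals=2, cells_per_individual=3,
                        n_causal_snps_per_gene=0, library_size_mean=1e-6, seed=1)
        panel = simulate_genotypes(cfg)
        truth = simulate_cis_architecture(panel, cfg)
        for g in truth.gene_ids:
            truth.baselines[g] = -40.0
        cells = simulate_single_cell(truth, cfg)
        assert cells.counts.nnz == 0
        assert (cells.cell_meta["n_count_total"] == 0).all()


class TestGWAS:
    def test_null_z_scores_standard_normal(self):
        cfg = SimConfig(n_genes=125, n_individuals=20, snps_per_gene=40,
                        gwas_n=800, seed=17)
        panel = simulate_genotypes(cfg)
        truth = simulate_cis_architecture(panel, cfg)
        gwas, _, _ = simulate_gwas(cfg, truth, null=True)
        z = gwas.table["beta"] / gwas.table["standard_error"]
        assert len(z) == 5000
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_power_grows_with_cohort_size(self):
        zs = {}
        for n in (300, 3000):
            cfg = SimConfig(n_genes=10, n_individuals=20, snps_per_gene=10,
                            gwas_n=n, n_causal_genes=10,
                            gene_trait_effect_sd=0.5, h2_trait=0.3, seed=23)
            panel = simulate_genotypes(cfg)
            truth = simulate_cis_architecture(panel, cfg)
            gwas, _, cohort = simulate_gwas(cfg, truth)
            causal_snps = {s for g in truth.gene_ids for s in truth.causal_snps[g]}
            mask = gwas.table["variant_id"].isin(causal_snps)
            z = (gwas.table["beta"] / gwas.table["standard_error"])[mask]
            zs[n] = np.abs(z).mean()
        assert zs[3000] > zs[300]

    def test_zero_heritability_matches_null(self):
        cfg = SimConfig(n_genes=5, n_individuals=20, gwas_n=300, h2_trait=0.0, seed=3)
        panel = simulate_genotypes(cfg)
        truth = simulate_cis_architecture(panel, cfg)
        g0, _, _ = simulate_gwas(cfg, truth)
        g1, _, _ = simulate_gwas(cfg, truth, null=True)
        pd.testing.assert_frame_equal(g0.table, g1.table)


def test_full_bundle_deterministic(tiny_config):
    a = simulate_all(tiny_config)
    b = simulate_all(tiny_config)
    np.testing.assert_array_equal(a.panel.dosages, b.panel.dosages)
    assert (a.cells.counts != b.cells.counts).nnz == 0
    pd.testing.assert_frame_equal(a.truth.latent_expression, b.truth.latent_expression)
    assert a.truth.trait_effects == b.truth.trait_effects
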