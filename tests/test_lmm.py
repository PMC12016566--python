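"""Mixed-model machinery against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from altadapt.lmm import (
    VariantCounts,
    association_scan,
    bonferroni_threshold,
    clustered_percentage,
    compute_grm,
    conditional_scan,
    fit_null,
    pc_covariates,
)
from altadapt.simulate import (
    GenotypeMatrix,
    SimConfig,
    simulate_altitude_phenotype,
    simulate_deletion_cohort,
    simulate_genotypes,
)


def _geno(dosages, positions=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    positions = positions if positions is not None else np.arange(1, m + 1) * 100
    variants = pd.DataFrame(
        {"chrom": "1", "pos": positions, "ref": "A", "alt": "G", "type": "SNP"}
    )
    return GenotypeMatrix([f"S{i}" for i in range(n)], variants, dosages)


class TestGrm:
    def test_hand_computed_entries(self):
        """3 samples x 2 variants with p = 0.5 each: K = Z Z'/2 by hand."""
        dos = np.array([[0, 2], [1, 1], [2, 0]])
        p = np.array([0.5, 0.5])
        Z = (dos - 2 * p) / np.sqrt(2 * p * (1 - p))
        expected = Z @ Z.T / 2
        K = compute_grm(_geno(dos))
        assert np.allclose(K, expected, atol=1e-12)

    def test_identical_samples_equal_entries(self):
        dos = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]])
        K = compute_grm(_geno(dos))
        assert K[0, 0] == pytest.approx(K[0, 1])
        assert K[0, 1] == pytest.approx(K[1, 1])

    def test_monomorphic_variant_excluded(self):
        dos = np.array([[0, 2], [1, 2], [2, 2]])
        K_with = compute_grm(_geno(dos))
        K_without = compute_grm(_geno(dos[:, :1]))
        assert np.allclose(K_with, K_without)

    def test_symmetric_psd(self):
        g = simulate_genotypes(SimConfig(seed=0, n_samples=30, n_variants=100))
        K = compute_grm(g)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_empty_after_filter_errors(self):
        dos = np.array([[2, 2], [2, 2], [2, 2]])
        with pytest.raises(ValueError):
            compute_grm(_geno(dos))


class TestPcCovariates:
    def test_two_subpops_separated_by_pc1(self):
        g = simulate_genotypes(
            SimConfig(seed=2, n_samples=60, n_variants=400, n_subpops=2, fst=0.2)
        )
        pcs = pc_covariates(g, k=1)
        pc1 = pcs[:, 0]
        grp = g.subpop
        within = sum(pc1[grp == j].var() for j in (0, 1)) / 2
        between = (pc1[grp == 0].mean() - pc1[grp == 1].mean()) ** 2
        assert between > within

    def test_k_zero_is_empty(self):
        g = simulate_genotypes(SimConfig(seed=1, n_samples=10, n_variants=30))
        assert pc_covariates(g, k=0).shape == (10, 0)

    def test_duplicate_samples_equal_coordinates(self):
        g = simulate_genotypes(SimConfig(seed=3, n_samples=10, n_variants=60))
        dos = np.vstack([g.dosages, g.dosages[:1]])
        pcs = pc_covariates(_geno(dos), k=2)
        assert np.allclose(pcs[0], pcs[-1], atol=1e-8)

    def test_k_too_large(self):
        g = simulate_genotypes(SimConfig(seed=1, n_samples=5, n_variants=30))
        with pytest.raises(ValueError):
            pc_covariates(g, k=5)


class TestFitNull:
    def test_identity_kinship_collapses_to_ols(self):
        rng = np.random.default_rng(0)
        n = 80
        y = rng.normal(size=n)
        W = np.ones((n, 1))
        fit = fit_null(y, W, np.eye(n))
        total_var = (fit.lambda_hat + 1) / fit.tau_hat
        ols_resid_var = y.var(ddof=1)  # REML scaling, intercept only
        assert fit.boundary
        assert total_var == pytest.approx(ols_resid_var, rel=1e-6)

    def test_matches_dense_grid_search(self):
        """Brent refinement lands within one step of a 10,001-point grid."""
        cfg = SimConfig(seed=6, n_samples=50, n_variants=200, heritability=0.6,
                        n_subpops=2, fst=0.1)
        g = simulate_genotypes(cfg)
        K = compute_grm(g)
        phen = simulate_altitude_phenotype(g, K, cfg)
        y, W = phen.altitude, np.ones((50, 1))
        fit = fit_null(y, W, K)

        from altadapt.lmm import _reml_criterion

        s, U = np.linalg.eigh((K + K.T) / 2)
        s = np.clip(s, 0, None)
        yr, Wr = U.T @ y, U.T @ W
        grid = np.linspace(-10, 10, 10_001)
        lls = np.array([_reml_criterion(x, s, yr, Wr)[0] for x in grid])
        best = grid[np.argmax(lls)]
        step = grid[1] - grid[0]
        assert abs(np.log(fit.lambda_hat) - best) <= step

    def test_lambda_recovery_over_seeds(self):
        """Median REML lambda over 50 phenotype draws near the true ratio 2."""
        cfg = SimConfig(seed=8, n_samples=300, n_variants=400,
                        heritability=2 / 3, n_subpops=3, fst=0.1)
        g = simulate_genotypes(cfg)
        K = compute_grm(g)
        W = np.ones((300, 1))
        lams = []
        for rep in range(50):
            rep_cfg = SimConfig(**{**cfg.__dict__, "seed": 5000 + rep})
            phen = simulate_altitude_phenotype(g, K, rep_cfg)
            lams.append(fit_null(phen.altitude, W, K).lambda_hat)
        assert 1.5 <= np.median(lams) <= 2.7


class TestScan:
    def test_identity_kinship_equals_ols(self):
        rng = np.random.default_rng(1)
        cfg = SimConfig(seed=3, n_samples=100, n_variants=60, n_subpops=1)
        g = simulate_genotypes(cfg)
        y = rng.normal(size=100)
        res = association_scan(g, y, None, np.eye(100), maf_min=0.0)
        X = g.dosages.astype(float)
        for j in range(g.n_variants):
            if not res.table["testable"][j]:
                continue
            ols = stats.linregress(X[:, j], y)
            assert res.table["p"][j] == pytest.approx(ols.pvalue, abs=1e-8)
            assert res.table["beta"][j] == pytest.approx(ols.slope, abs=1e-8)

    def test_null_type_one_error_and_uniformity(self):
        """Under the global null, p < 0.05 at ~nominal rate and KS-uniform."""
        cfg = SimConfig(seed=10, n_samples=200, n_variants=5000, n_subpops=1)
        g = simulate_genotypes(cfg)
        y = np.random.default_rng(99).normal(size=200)
        K = compute_grm(g)
        res = association_scan(g, y, None, K, maf_min=0.0)
        p = res.table.loc[res.table["testable"], "p"].to_numpy()
        assert abs((p < 0.05).mean() - 0.05) < 0.01
        assert stats.kstest(p, "uniform").pvalue > 0.001

    def test_power_causal_variant_is_top_hit(self):
        hits = 0
        for seed in range(50):
            cfg = SimConfig(seed=seed, n_samples=500, n_variants=200,
                            heritability=0.3, causal_positions=(100,),
                            causal_effects=(2.0,), residual_sd=1.0)
            g = simulate_genotypes(cfg)
            K = compute_grm(g)
            phen = simulate_altitude_phenotype(g, K, cfg)
            res = association_scan(g, phen.altitude, None, K, maf_min=0.0)
            if res.table["p"].idxmin() == 100:
                hits += 1
        assert hits >= 45

    def test_sample_reordering_invariance(self):
        cfg = SimConfig(seed=12, n_samples=60, n_variants=80, n_subpops=2)
        g = simulate_genotypes(cfg)
        K = compute_grm(g)
        y = simulate_altitude_phenotype(g, K, cfg).altitude
        res1 = association_scan(g, y, None, K, maf_min=0.0)
        perm = np.random.default_rng(0).permutation(60)
        g2 = GenotypeMatrix([g.sample_ids[i] for i in perm], g.variants,
                            g.dosages[perm])
        res2 = association_scan(g2, y[perm], None, K[np.ix_(perm, perm)],
                                maf_min=0.0)
        assert np.allclose(res1.table["p"], res2.table["p"], rtol=1e-8)
        assert np.allclose(res1.table["beta"], res2.table["beta"], rtol=1e-8)


class TestConditionalScan:
    def test_conditioning_on_tested_variant_not_testable(self):
        cfg = SimConfig(seed=1, n_samples=50, n_variants=10, n_subpops=1)
        g = simulate_genotypes(cfg)
        K = np.eye(50)
        y = np.random.default_rng(2).normal(size=50)
        cond = g.dosages[:, 3].astype(float)
        res = conditional_scan(g, y, None, cond, K, maf_min=0.0)
        assert not res.table["testable"][3]

    def test_irrelevant_covariate_leaves_scan_unchanged(self):
        cfg = SimConfig(seed=13, n_samples=150, n_variants=200, n_subpops=1)
        g = simulate_genotypes(cfg)
        K = compute_grm(g)
        y = np.random.default_rng(7).normal(size=150)
        res0 = association_scan(g, y, None, K, maf_min=0.0)
        perm_dos = np.random.default_rng(8).permutation(
            g.dosages[:, 0].astype(float)
        )
        res1 = conditional_scan(g, y, None, perm_dos, K, maf_min=0.0)
        both = res0.table["testable"] & res1.table["testable"]
        rho = stats.spearmanr(res0.table.loc[both, "p"],
                              res1.table.loc[both, "p"]).statistic
        assert rho > 0.99

    def test_deletion_signal_removed_by_conditioning(self):
        """Conditioning on haplotype-A dosage removes the locus signal."""
        removed = 0
        for seed in range(20):
            cfg = SimConfig(seed=seed, n_samples=300, n_variants=120,
                            residual_sd=50.0)
            cohort = simulate_deletion_cohort(cfg, beta_sv=800.0)
            g, phen = cohort.genotypes, cohort.phenotype
            # leave-region-out kinship so the tested locus does not sit in K
            K = compute_grm(g.dosages[:, ~cohort.region_mask])
            res_u = association_scan(g, phen.altitude, None, K, maf_min=0.0)
            thr = res_u.bonferroni_p
            region = cohort.region_mask
            p_u = res_u.table.loc[region, "p"].min()
            assert p_u < thr  # unconditional scan must light up the locus
            res_c = conditional_scan(g, phen.altitude, None, cohort.a_dosage,
                                     K, maf_min=0.0)
            ok = res_c.table["testable"] & region
            p_c = res_c.table.loc[ok, "p"].min() if ok.any() else 1.0
            if p_c > res_c.bonferroni_p:
                removed += 1
        assert removed >= 18


def test_bonferroni_threshold_values():
    p, neglog = bonferroni_threshold(0.05, 34_298_967)
    assert p == pytest.approx(1.46e-9, rel=5e-3)
    assert round(neglog, 2) == 8.84
    assert bonferroni_threshold(0.05, 1)[0] == 0.05
    with pytest.raises(ZeroDivisionError):
        bonferroni_threshold(0.05, 0)


def test_variant_bookkeeping_total():
    counts = VariantCounts(n_snps=31_567_131, n_indels=2_731_836)
    assert counts.total == 34_298_967


def test_clustered_percentage():
    assert clustered_percentage([788, 25], 896) == pytest.approx(90.74, abs=0.005)
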