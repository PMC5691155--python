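"""GRM formula, AI-REML maximisation, liability transform, score variance."""

import numpy as np
import pytest
from scipy import special

import pathpgs as pg
from pathpgs.heritability import liability_multiplier, reml_loglik

import oracles
from conftest import toy_panel


class TestGrm:
    def test_toy_matrix_matches_elementwise_formula(self, rng):
        X = rng.integers(0, 3, size=(5, 3)).astype(float)
        while np.any((X.mean(0) == 0) | (X.mean(0) == 2)):
            X = rng.integers(0, 3, size=(5, 3)).astype(float)
        panel = toy_panel(X)
        A = pg.build_grm(panel)
        for j in range(5):
            for k in range(5):
                assert A[j, k] == pytest.approx(oracles.grm_entry(X, j, k), abs=1e-12)
        np.testing.assert_allclose(A, A.T)

    def test_duplicated_individual_is_identical_by_state(self, rng):
        X = rng.integers(0, 3, size=(30, 40)).astype(float)
        X[1] = X[0]
        panel = toy_panel(X)
        A = pg.build_grm(panel)
        assert A[0, 1] == pytest.approx(A[0, 0], abs=1e-12)
        assert A[0, 1] == pytest.approx(A[1, 1], abs=1e-12)

    def test_mean_diagonal_is_one(self):
        cfg = pg.SimulationConfig(
            n_individuals=10_000, n_snps_autosomal=50, n_snps_x=0, n_loci=2,
            h2_x=0.0, seed=12,
        )
        panel = pg.simulate_panel(cfg)
        A = pg.build_grm(panel)
        assert A.diagonal().mean() == pytest.approx(1.0, abs=0.02)

    def test_monomorphic_snps_excluded(self, rng):
        X = rng.integers(0, 3, size=(40, 3)).astype(float)
        X[:, 1] = 2.0  # monomorphic
        panel = toy_panel(X)
        A = pg.build_grm(panel)  # must not produce NaN
        assert np.isfinite(A).all()
        with pytest.raises(ValueError):
            pg.build_grm(toy_panel(np.full((10, 1), 2.0)))


class TestLiabilityTransform:
    def test_zero_maps_to_zero(self):
        for k in (0.01, 0.3, 0.59, 0.9):
            assert pg.liability_transform(0.0, k) == 0.0

    def test_half_prevalence_multiplier_is_pi_over_two(self):
        assert liability_multiplier(0.5) == pytest.approx(np.pi / 2, abs=1e-12)

    def test_study_prevalence_multiplier_against_numerical_oracle(self):
        # independent route: t via erfinv, z via the explicit density formula
        K = 0.59
        t = np.sqrt(2.0) * special.erfinv(2.0 * (1.0 - K) - 1.0)
        z = np.exp(-t * t / 2.0) / np.sqrt(2.0 * np.pi)
        expected = K * (1 - K) / z**2
        assert liability_multiplier(0.59) == pytest.approx(expected, abs=1e-3)
        assert expected == pytest.approx(1.6007, abs=1e-3)

    def test_linear_in_h2_and_continuous_in_k(self):
        assert pg.liability_transform(0.4, 0.3) == pytest.approx(2 * pg.liability_transform(0.2, 0.3))
        # continuity: increments shrink proportionally with the grid step
        coarse = np.array([liability_multiplier(k) for k in np.linspace(0.2, 0.8, 61)])
        fine = np.array([liability_multiplier(k) for k in np.linspace(0.2, 0.8, 601)])
        assert np.abs(np.diff(fine)).max() == pytest.approx(np.abs(np.diff(coarse)).max() / 10, rel=0.05)

    def test_invalid_prevalence_rejected(self):
        for k in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                pg.liability_transform(0.5, k)


def quantitative_cohort(seed, n=2000, m=600, h2=0.5):
    """Panel + fully polygenic quantitative trait with exact in-sample h2."""
    rng = np.random.default_rng(seed)
    cfg = pg.SimulationConfig(
        n_individuals=n, n_snps_autosomal=m, n_snps_x=0, n_loci=2,
        h2_x=0.0, ld_decay=0.0, seed=seed,
    )
    panel = pg.simulate_panel(cfg)
    W = panel.dosages
    W = (W - W.mean(0)) / W.std(0)
    g = W @ rng.standard_normal(m)
    g *= np.sqrt(h2) / g.std()
    e = rng.standard_normal(n)
    e *= np.sqrt(1 - h2) / e.std()
    return panel, g + e, g


class TestAiReml:
    def test_pure_noise_gives_null_genetic_fraction(self):
        rng = np.random.default_rng(5)
        panel, y, _ = quantitative_cohort(seed=5, n=2000, h2=0.5)
        noise = rng.standard_normal(2000)
        vc = pg.fit_aireml(noise, None, [pg.build_grm(panel)])
        assert vc.converged
        assert abs(vc.h2_observed[0]) < 2 * vc.h2_observed_se[0] + 1e-9

    def test_recovers_planted_h2(self):
        panel, y, _ = quantitative_cohort(seed=17, n=2000, h2=0.5)
        vc = pg.fit_aireml(y, None, [pg.build_grm(panel)])
        assert abs(vc.h2_observed[0] - 0.5) < 2 * vc.h2_observed_se[0]

    def test_loglik_nondecreasing_and_matches_grid_oracle(self):
        rng = np.random.default_rng(3)
        n, m = 150, 80
        X = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        panel = toy_panel(X)
        A = pg.build_grm(panel)
        L = np.linalg.cholesky(A + 1e-8 * np.eye(n))
        y = 0.8 * (L @ rng.standard_normal(n)) + 0.7 * rng.standard_normal(n)
        vc = pg.fit_aireml(y, None, [A])
        traj = np.asarray(vc.loglik_trajectory)
        assert np.all(np.diff(traj) >= -1e-8)
        # brute-force grid maximisation of an independently coded REML loglik
        design = np.ones((n, 1))
        grid = np.linspace(0.02, 2.5, 60)
        best, best_ll = None, -np.inf
        for sg in grid:
            for se_ in grid:
                ll = oracles.reml_loglik_direct(np.array([sg, se_]), y, design, [A])
                if ll > best_ll:
                    best, best_ll = (sg, se_), ll
        step = grid[1] - grid[0]
        assert vc.variances[0] == pytest.approx(best[0], abs=step)
        assert vc.variances[1] == pytest.approx(best[1], abs=step)
        assert vc.loglik >= best_ll - 1e-6
        # the package's own loglik helper agrees with the oracle definition
        assert reml_loglik(vc.variances, y, None, [A]) == pytest.approx(
            oracles.reml_loglik_direct(vc.variances, y, design, [A]), abs=1e-6
        )

    def test_two_component_recovery(self):
        cfg = pg.SimulationConfig(
            n_individuals=2000, n_snps_autosomal=500, n_snps_x=100, n_loci=8,
            h2_autosomal=0.6, h2_x=0.2, seed=23,
        )
        panel = pg.simulate_panel(cfg)
        pheno, _ = pg.simulate_traits(panel, cfg)
        meta = panel.snp_meta
        Aa = pg.build_grm(panel, meta.loc[meta["chr"] != "X", "snp"])
        Ax = pg.build_grm(panel, meta.loc[meta["chr"] == "X", "snp"])
        vc = pg.fit_aireml(pheno["liability"].to_numpy(), None, [Aa, Ax], names=["autosomal", "x"])
        assert vc.converged
        assert abs(vc.h2_observed[0] - 0.6) < 2 * vc.h2_observed_se[0]
        assert abs(vc.h2_observed[1] - 0.2) < 2 * vc.h2_observed_se[1]

    def test_identity_grm_reported_degenerate(self):
        rng = np.random.default_rng(9)
        y = rng.standard_normal(300)
        vc = pg.fit_aireml(y, None, [np.eye(300)])
        assert vc.degenerate or vc.boundary

    def test_binary_phenotype_on_liability_scale(self):
        cfg = pg.SimulationConfig(
            n_individuals=2000, n_snps_autosomal=500, n_snps_x=0, n_loci=8,
            h2_autosomal=0.5, h2_x=0.0, prevalence=0.59, seed=29,
        )
        panel = pg.simulate_panel(cfg)
        pheno, _ = pg.simulate_traits(panel, cfg)
        vc = pg.fit_aireml(
            pheno["mpb"].to_numpy(), None, [pg.build_grm(panel)], prevalence=0.59
        )
        assert vc.h2_liability is not None
        assert abs(vc.h2_liability[0] - 0.5) < 2 * vc.h2_liability_se[0]

    def test_zero_variance_phenotype_rejected(self):
        with pytest.raises(ValueError):
            pg.fit_aireml(np.ones(50), None, [np.eye(50)])


class TestScoreVarianceExplained:
    def test_null_true_and_half_scores(self):
        panel, y, g = quantitative_cohort(seed=41, n=1500, m=400, h2=0.5)
        A = pg.build_grm(panel)
        rng = np.random.default_rng(41)

        null = pg.score_variance_explained(y, None, [A], rng.standard_normal(len(y)))
        assert abs(null["observed"]) < 2 * null["without_score"].h2_observed_se[0]

        full = pg.score_variance_explained(y, None, [A], g)
        assert full["observed"] == pytest.approx(
            full["without_score"].total_h2_observed, abs=2 * full["without_score"].h2_observed_se[0]
        )

    def test_constant_score_warns_and_is_zero(self, caplog):
        panel, y, _ = quantitative_cohort(seed=43, n=800, m=200, h2=0.4)
        with caplog.at_level("WARNING"):
            out = pg.score_variance_explained(y, None, [pg.build_grm(panel)], np.ones(800))
        assert out["observed"] == 0.0
        assert any("constant" in r.message for r in caplog.records)
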