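"""Per-SNP residualization: path solve, audit re-fit, effective N."""

import numpy as np
import pytest

import gsubtract as gs
from gsubtract import subtract
from gsubtract.ldsc import genetic_covariance_from_matrices
from gsubtract.factor import fit_common_factor

from conftest import exact_factor_gc


@pytest.fixture(scope="module")
def exact_solution():
    """Exact 3-trait measurement model on a heritability scale, with V at
    reference-panel precision so the measurement model dominates per-SNP
    information (the regime the fixed-measurement solve assumes)."""
    lam_std = np.array([0.6, 0.7, 0.8])
    h2 = np.array([0.2, 0.15, 0.25])
    lam_cov = lam_std * np.sqrt(h2)
    u_cov = (1 - lam_std ** 2) * h2
    gc = exact_factor_gc(lam_cov, u_cov, traits=["a", "b", "c"],
                         v_scale=(5e-3) ** 2)
    return gc, fit_common_factor(gc)


class TestSnpTraitCovariances:
    def test_scaling_arithmetic(self, toy_panel):
        panel, _ = toy_panel
        C, valid = subtract.snp_trait_covariances(panel)
        assert valid.all()
        np.testing.assert_allclose(
            C[0], panel.Z[0] / np.sqrt(panel.N[0]))

    def test_zero_z_gives_zero_covariance(self, toy_panel):
        panel, _ = toy_panel
        Z = panel.Z.copy()
        Z[0] = 0.0
        panel2 = gs.SumstatsPanel(traits=panel.traits, variants=panel.variants,
                                  Z=Z, N=panel.N, ld=panel.ld, M=panel.M)
        C, _ = subtract.snp_trait_covariances(panel2)
        np.testing.assert_array_equal(C[0], 0.0)

    def test_z_two_n_1e4_gives_0p02(self):
        assert 2.0 / np.sqrt(10_000) == pytest.approx(0.02)


class TestFitSnpPaths:
    def test_pure_factor_snp(self, exact_solution):
        """A SNP acting only through g: b_resid ~ 0, b_g recovered."""
        gc, sol = exact_solution
        bg_true = 0.01
        c = sol.loadings_cov * bg_true
        n = np.full(3, 20_000.0)
        bg, se_g, br, se_r = subtract.fit_snp_paths(c, sol, "b", n)
        assert bg == pytest.approx(bg_true, abs=1e-10)
        assert br == pytest.approx(0.0, abs=1e-10)

    def test_pure_residual_snp(self, exact_solution):
        gc, sol = exact_solution
        c = np.array([0.0, 0.02, 0.0])
        n = np.full(3, 20_000.0)
        bg, _, br, _ = subtract.fit_snp_paths(c, sol, "b", n)
        assert br == pytest.approx(0.02 - sol.loadings_cov[1] * bg, abs=1e-10)
        assert abs(bg) < abs(br)  # mostly attributed to the residual

    def test_allele_relabel_invariance(self, exact_solution):
        """Negating the covariance vector (relabelled effect allele) negates
        both paths but changes no magnitude."""
        _, sol = exact_solution
        c = np.array([0.01, -0.005, 0.02])
        n = np.full(3, 20_000.0)
        bg, se_g, br, se_r = subtract.fit_snp_paths(c, sol, "b", n)
        bg2, se_g2, br2, se_r2 = subtract.fit_snp_paths(-c, sol, "b", n)
        assert bg2 == pytest.approx(-bg) and br2 == pytest.approx(-br)
        assert se_g2 == pytest.approx(se_g) and se_r2 == pytest.approx(se_r)

    def test_bulk_solve_matches_scalar_solve(self, toy_panel, toy_solution):
        panel, _ = toy_panel
        _, sol = toy_solution
        tau = 1
        valid, b, se = subtract._bulk_paths(panel, sol, tau)
        C, _ = subtract.snp_trait_covariances(panel)
        n = np.nanmean(panel.N, axis=0)
        for j in (0, 17, 930):
            bg, se_g, br, se_r = subtract.fit_snp_paths(
                C[j], sol, panel.traits[tau], n)
            assert b[j, 0] == pytest.approx(bg, rel=1e-10)
            assert b[j, 1] == pytest.approx(br, rel=1e-10)
            assert se[j, 1] == pytest.approx(se_r, rel=1e-8)


class TestAuditRefit:
    def test_fast_solve_matches_full_refit(self, exact_solution):
        """200-variant audit: the fixed-measurement solve and the exact
        per-SNP re-fit of the full model agree to 1e-3 on b_resid."""
        gc, sol = exact_solution
        n = np.full(3, 20_000.0)
        rng = np.random.default_rng(5)
        m_scale = 20_000
        lam_cov = sol.loadings_cov
        u_cov = sol.resid_cov
        worst = 0.0
        for _ in range(200):
            alpha = rng.normal(0, np.sqrt(3.0 / m_scale))
            delta = rng.normal(0, np.sqrt(3.0 / m_scale), 3)
            c = lam_cov * alpha + np.sqrt(u_cov) * delta \
                + rng.standard_normal(3) / np.sqrt(n)
            _, _, br_fast, _ = subtract.fit_snp_paths(c, sol, "b", n)
            _, br_refit = subtract.fit_snp_paths_refit(gc, c, n, "b",
                                                       start=sol)
            worst = max(worst, abs(br_fast - br_refit))
        assert worst < 1e-3


class TestCorrectTrait:
    def test_zero_loading_target_preserves_sumstats(self):
        """lambda_target = 0: correction leaves the trait's statistics
        essentially unchanged (h2 preserved downstream)."""
        truth = gs.TruthSet(loadings=[0.0, 0.7, 0.8], h2=[0.2, 0.15, 0.25],
                            n=[20_000] * 3, m=5_000, block_size=10,
                            rho=(0.2, 0.8), seed=23)
        panel, _ = gs.simulate_panel(truth)
        gc = gs.build_S_V(panel)
        sol = gs.fit_common_factor(gc)
        corr = gs.correct_trait(panel, sol, "test01")
        r = np.corrcoef(corr.z, panel.Z[:, 0])[0, 1]
        assert r > 0.95

    def test_targets_are_order_independent(self, toy_panel, toy_solution):
        panel, _ = toy_panel
        _, sol = toy_solution
        fwd = {t: gs.correct_trait(panel, sol, t) for t in panel.traits}
        rev = {t: gs.correct_trait(panel, sol, t)
               for t in reversed(panel.traits)}
        for t in panel.traits:
            np.testing.assert_array_equal(fwd[t].beta, rev[t].beta)

    def test_missing_variants_skipped_and_counted(self, toy_panel,
                                                  toy_solution):
        panel, _ = toy_panel
        _, sol = toy_solution
        Z = panel.Z.copy()
        Z[:100, 1] = np.nan
        holey = gs.SumstatsPanel(traits=panel.traits, variants=panel.variants,
                                 Z=Z, N=panel.N, ld=panel.ld, M=panel.M)
        corr = gs.correct_trait(holey, sol, panel.traits[0])
        assert corr.n_skipped == 100
        assert len(corr.beta) == panel.m - 100

    def test_majority_skipped_fatal(self, toy_panel, toy_solution):
        panel, _ = toy_panel
        _, sol = toy_solution
        Z = panel.Z.copy()
        Z[: panel.m // 2 + 1, 2] = np.nan
        holey = gs.SumstatsPanel(traits=panel.traits, variants=panel.variants,
                                 Z=Z, N=panel.N, ld=panel.ld, M=panel.M)
        with pytest.raises(subtract.SubtractionError, match="skipped"):
            gs.correct_trait(holey, sol, panel.traits[0])


class TestEffectiveN:
    def test_recovers_gwas_n_for_plain_trait(self, toy_panel, toy_truth,
                                             toy_solution):
        """Running a trait through the machinery yields N_eff near the true
        GWAS sample size."""
        panel, _ = toy_panel
        _, sol = toy_solution
        corr = gs.correct_trait(panel, sol, "test01")
        # residual solve inflates variance somewhat; same order as true n
        assert 0.5 * toy_truth.n[0] < corr.n_eff <= 1.05 * toy_truth.n[0]

    def test_doubling_se_quarters_n(self):
        se = np.full(50, 0.01)
        freq = np.full(50, 0.25)
        beta = np.full(50, 0.01)
        n1, _ = subtract.estimate_effective_n(beta, se, freq)
        n2, _ = subtract.estimate_effective_n(beta, 2 * se, freq)
        assert n2 == pytest.approx(n1 / 4)

    def test_allele_relabel_invariance(self):
        se = np.linspace(0.01, 0.02, 30)
        freq = np.linspace(0.15, 0.35, 30)
        n1, _ = subtract.estimate_effective_n(se, se, freq)
        n2, _ = subtract.estimate_effective_n(se, se, 1 - freq)
        assert n1 == pytest.approx(n2)

    def test_empty_window_falls_back_to_median(self):
        se = np.full(10, 0.01)
        freq = np.full(10, 0.45)  # outside (0.1, 0.4)
        n, fell_back = subtract.estimate_effective_n(se, se, freq)
        assert fell_back and n > 0


class TestFactorGwas:
    def test_orthogonal_to_corrected_low_loading_trait(self):
        """The factor GWAS is genetically uncorrelated with the corrected
        sumstats of a moderately loading trait."""
        truth = gs.TruthSet(loadings=[0.4, 0.6, 0.7, 0.8],
                            h2=[0.2, 0.15, 0.2, 0.25],
                            n=[20_000] * 4, m=20_000, block_size=10,
                            rho=(0.2, 0.8), seed=29)
        panel, _ = gs.simulate_panel(truth)
        sol = gs.fit_common_factor(gs.build_S_V(panel))
        corr = gs.correct_trait(panel, sol, "test01")
        gfac = gs.factor_gwas(panel, sol)
        sub = gs.SumstatsPanel(
            traits=["g", "resid"], variants=panel.variants,
            Z=np.column_stack([gfac.z, corr.z]),
            N=np.column_stack([np.full(panel.m, gfac.n_eff),
                               np.full(panel.m, corr.n_eff)]),
            ld=panel.ld, M=panel.M)
        rg = gs.rg_matrix(gs.build_S_V(sub))
        assert abs(rg.rg[0, 1]) < 0.15

    def test_factor_gwas_tracks_factor_signal(self, toy_panel, toy_solution):
        """b_g correlates with the LD-convolved factor effects from truth."""
        panel, draws = toy_panel
        _, sol = toy_solution
        gfac = gs.factor_gwas(panel, sol)
        alpha_marg = draws.ld.convolve(draws.alpha[:, None])[:, 0]
        r = np.corrcoef(gfac.z, alpha_marg)[0, 1]
        assert r > 0.5
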