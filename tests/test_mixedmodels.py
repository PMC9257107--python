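"""Mixed-model engines: REML against grid search, Gibbs against closed
forms, heritability/correlation arithmetic, BMORS stacking."""

import numpy as np
import pandas as pd
import pytest

from tracegp.kernels import RelationshipMatrix, additive_grm
from tracegp.mixedmodels import (
    FitResult,
    VarianceComponents,
    blup_closed_form,
    estimate_heritability,
    fit_bmors,
    fit_mt,
    fit_st_gblup,
    genetic_correlation,
    predict_genetic_values,
    reml_single_trait,
)
from tracegp.simulate import make_fixture


def grid_search_reml(y, Kreg, grid):
    """Independent oracle: dense restricted-likelihood evaluation per delta."""
    n = len(y)
    X = np.ones((n, 1))
    best, best_ll = None, -np.inf
    for delta in grid:
        V = Kreg + delta * np.eye(n)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        mu = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ mu
        rss = float(r @ Vi @ r)
        sg2 = rss / (n - 1)
        ll = -0.5 * (
            (n - 1) * (1 + np.log(2 * np.pi * sg2))
            + np.linalg.slogdet(V)[1]
            + np.log(np.linalg.det(XtViX))
        )
        if ll > best_ll:
            best_ll, best = ll, (sg2, sg2 * delta)
    return best


class TestREML:
    def test_identity_kernel_recovers_sample_variance(self):
        # with K = I only the total variance is identified: the REML fit
        # must reproduce the one-way variance partition sigma_g^2 + sigma_e^2
        # = var(y) (the closed form for V = c I)
        rng = np.random.default_rng(0)
        n = 12
        y = rng.standard_normal(n)
        Kreg = np.eye(n) + 1e-6 * np.eye(n)
        sg2, se2, mu, ll, _ = reml_single_trait(y, Kreg)
        assert sg2 + se2 == pytest.approx(np.var(y, ddof=1), rel=1e-4)
        assert mu == pytest.approx(y.mean(), abs=1e-8)

    def test_matches_grid_search_structured_kernel(self, tiny):
        geno, pheno, _ = tiny
        K = additive_grm(geno.dosage_imputed())
        y = pheno.values.iloc[:, 0].to_numpy()
        sg2, se2, *_ = reml_single_trait(y, K.regularized())
        g_sg2, g_se2 = grid_search_reml(
            y, K.regularized(), np.exp(np.linspace(-12, 12, 4001))
        )
        assert sg2 / (sg2 + se2) == pytest.approx(g_sg2 / (g_sg2 + g_se2), abs=1e-3)

    def test_noiseless_eigenvector_gives_boundary_h2(self, tiny):
        geno, _, _ = tiny
        K = additive_grm(geno.dosage_imputed())
        d, U = np.linalg.eigh(K.regularized())
        y = U[:, -1] * 3.0  # exactly genetic signal, zero noise
        fit = fit_st_gblup(y, K, ids=[f"i{i}" for i in range(K.n)])
        assert fit.vc.h2[0] > 0.999
        assert not fit.diagnostics["converged"]  # boundary reported

    def test_masked_individuals_predicted(self, tiny):
        geno, pheno, truth = tiny
        K = additive_grm(geno.dosage_imputed())
        y = pheno.values.iloc[:, 0].copy()
        y.iloc[:6] = np.nan
        fit = fit_st_gblup(y, K)
        g = truth.true_genetic_values.iloc[:, 0]
        r = np.corrcoef(fit.u.iloc[:6, 0], g.iloc[:6])[0, 1]
        assert r > 0.2  # masked individuals get informative BLUPs

    def test_requires_ten_observations(self):
        K = RelationshipMatrix(np.eye(12), "additive")
        y = np.full(12, np.nan)
        y[:5] = 1.0
        with pytest.raises(ValueError, match="observed"):
            fit_st_gblup(y, K)


class TestHeritabilityArithmetic:
    def test_plugin_ratio(self):
        vc = VarianceComponents(np.array([[0.62]]), np.array([0.38]))
        fit = FitResult("ST-REML", ["a"], ["y"], np.zeros(1),
                        pd.DataFrame([[0.0]], index=["a"], columns=["y"]), vc)
        assert estimate_heritability(fit)["y"] == pytest.approx(0.62)

    def test_zero_genetic_variance(self):
        vc = VarianceComponents(np.array([[0.0]]), np.array([1.0]))
        fit = FitResult("ST-REML", ["a"], ["y"], np.zeros(1),
                        pd.DataFrame([[0.0]], index=["a"], columns=["y"]), vc)
        assert estimate_heritability(fit)["y"] == 0.0

    def test_two_estimator_consistency_on_chain(self, tiny):
        geno, pheno, _ = tiny
        K = additive_grm(geno.dosage_imputed())
        fit = fit_st_gblup(pheno.values.iloc[:, 0], K, engine="gibbs",
                           iterations=3000, burn_in=1000, seed=1)
        mean_of_ratio = fit.samples["h2"].mean()
        sg = fit.samples["psi_u"][:, 0, 0].mean()
        se = fit.samples["psi_e"][:, 0].mean()
        ratio_of_means = sg / (sg + se)
        mc_se = fit.samples["h2"].std() / np.sqrt(
            max(fit.diagnostics["ess_h2"][pheno.traits[0]], 4)
        )
        assert abs(mean_of_ratio - ratio_of_means) < max(4 * mc_se, 0.05)


class TestMultiTraitGibbs:
    def test_posterior_mean_u_matches_closed_form_blup(self, tiny):
        geno, pheno, _ = tiny
        idx = np.arange(12)
        K = additive_grm(geno.subset_individuals(idx).dosage_imputed())
        Y = pheno.values.iloc[idx]
        psi_u = np.array([[0.5, 0.3], [0.3, 0.4]])
        psi_e = np.array([0.5, 0.6])
        oracle = blup_closed_form(Y, K, psi_u, psi_e)
        fit = fit_mt(Y, K, structure="un", iterations=22000, burn_in=2000,
                     seed=3, fixed_components=(psi_u, psi_e))
        mc_se = np.sqrt(fit.diagnostics["u_var"] / 2000)  # conservative ESS
        assert np.all(np.abs(fit.u.to_numpy() - oracle.to_numpy()) < 2.5 * mc_se + 1e-3)

    def test_seeded_chain_reproducible(self, tiny):
        geno, pheno, _ = tiny
        K = additive_grm(geno.dosage_imputed())
        a = fit_mt(pheno.values, K, "un", iterations=400, burn_in=200, seed=9)
        b = fit_mt(pheno.values, K, "un", iterations=400, burn_in=200, seed=9)
        assert a.u.equals(b.u)
        assert np.array_equal(a.samples["psi_u"], b.samples["psi_u"])

    def test_label_permutation_equivariance(self, tiny):
        geno, pheno, _ = tiny
        K = additive_grm(geno.dosage_imputed())
        fit = fit_st_gblup(pheno.values.iloc[:, 0], K)
        perm = np.random.default_rng(1).permutation(geno.n)
        Kp = RelationshipMatrix(K.values[np.ix_(perm, perm)], "additive")
        yp = pheno.values.iloc[perm, 0]
        fitp = fit_st_gblup(yp, Kp)
        assert np.allclose(
            fitp.u.to_numpy()[:, 0], fit.u.to_numpy()[perm, 0], atol=1e-8
        )

    def test_all_missing_trait_rejected(self, tiny):
        geno, pheno, _ = tiny
        K = additive_grm(geno.dosage_imputed())
        Y = pheno.values.copy()
        Y.iloc[:, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_mt(Y, K, "un", iterations=200, burn_in=100)

    def test_fa_psiu_psd_every_sweep(self, rice250):
        geno, pheno, _ = rice250
        idx = np.arange(60)
        K = additive_grm(geno.subset_individuals(idx).dosage_imputed())
        fit = fit_mt(pheno.values.iloc[idx], K, "fa", k=2,
                     iterations=600, burn_in=300, seed=2)
        for psi in fit.samples["psi_u"]:
            assert np.linalg.eigvalsh(psi).min() >= -1e-10

    def test_isolated_masked_individual_predicted_at_prior_mean(self):
        rng = np.random.default_rng(0)
        n = 20
        y = rng.standard_normal(n)
        y[0] = np.nan
        K = np.eye(n)  # no relatedness: masked individual is isolated
        fit = fit_st_gblup(y, RelationshipMatrix(K, "additive"))
        assert fit.u.iloc[0, 0] == pytest.approx(0.0, abs=1e-8)


class TestGeneticCorrelation:
    def _fit_with_psi(self, psi, model="MT-UN"):
        t = psi.shape[0]
        traits = [f"t{i}" for i in range(t)]
        vc = VarianceComponents(psi, np.ones(t))
        return FitResult(model, ["a"], traits, np.zeros(t),
                         pd.DataFrame(np.zeros((1, t)), index=["a"], columns=traits),
                         vc)

    def test_identity_psi(self):
        cor = genetic_correlation(self._fit_with_psi(np.eye(2)))
        assert np.allclose(cor, np.eye(2))

    def test_arithmetic(self):
        psi = np.array([[1.0, 0.95], [0.95, 1.0]])
        cor = genetic_correlation(self._fit_with_psi(psi))
        assert cor.iloc[0, 1] == pytest.approx(0.95)

    def test_rank_one_fa_gives_unit_correlation(self):
        lam = np.array([[0.7], [-1.3]])
        psi = lam @ lam.T  # FA(1) with zero uniqueness
        cor = genetic_correlation(self._fit_with_psi(psi, model="MT-FA"))
        assert cor.iloc[0, 1] == pytest.approx(-1.0)

    def test_diag_structure_warns_identity(self, tiny):
        geno, pheno, _ = tiny
        K = additive_grm(geno.dosage_imputed())
        fit = fit_mt(pheno.values, K, "diag", iterations=200, burn_in=100)
        with pytest.warns(UserWarning, match="diagonal"):
            cor = genetic_correlation(fit)
        assert np.allclose(cor, np.eye(2))


class TestPredictGeneticValues:
    def test_unknown_ids_rejected(self, tiny):
        geno, pheno, _ = tiny
        K = additive_grm(geno.dosage_imputed())
        fit = fit_st_gblup(pheno.values.iloc[:, 0], K)
        with pytest.raises(KeyError):
            predict_genetic_values(fit, pheno.traits[0], ["nobody"])
        with pytest.raises(KeyError):
            predict_genetic_values(fit, "unknown-trait")

    def test_observed_own_phenotype_informs_prediction(self, tiny):
        # information monotonicity: with the target observed, the prediction
        # tracks the phenotype more closely than when masked
        geno, pheno, _ = tiny
        K = additive_grm(geno.dosage_imputed())
        y = pheno.values.iloc[:, 0]
        fit_obs = fit_st_gblup(y, K)
        y_masked = y.copy()
        y_masked.iloc[:10] = np.nan
        fit_mask = fit_st_gblup(y_masked, K)
        r_obs = np.corrcoef(fit_obs.u.iloc[:10, 0], y.iloc[:10])[0, 1]
        r_mask = np.corrcoef(fit_mask.u.iloc[:10, 0], y.iloc[:10])[0, 1]
        assert r_obs > r_mask


class TestBMORS:
    def test_identity_stacking_reproduces_stage1(self, tiny):
        geno, pheno, _ = tiny
        K = additive_grm(geno.dosage_imputed())
        Y = pheno.values.copy()
        Y.iloc[:5, 0] = np.nan
        fit = fit_bmors(Y, K, seed=4, stage2="identity")
        assert fit.u.equals(fit.diagnostics["stage1"])
        assert np.allclose(np.diag(fit.diagnostics["stage2_coefficients"]), 1.0)

    def test_needs_two_traits(self, tiny):
        geno, pheno, _ = tiny
        K = additive_grm(geno.dosage_imputed())
        with pytest.raises(ValueError):
            fit_bmors(pheno.values.iloc[:, [0]], K)

    def test_cross_trait_coefficients_shrink_for_uncorrelated_traits(self, tiny):
        geno, _, _ = tiny
        rng = np.random.default_rng(6)
        Y = pd.DataFrame(
            rng.standard_normal((geno.n, 2)), index=geno.ids, columns=["a", "b"]
        )
        Y.iloc[:5, 0] = np.nan
        K = additive_grm(geno.dosage_imputed())
        fit = fit_bmors(Y, K, seed=0)
        B = fit.diagnostics["stage2_coefficients"]
        assert abs(B[0, 1]) < 1.0  # no runaway cross-trait loading
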