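"""Paired t-test, gamma mixed model, marginal means and contrasts."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.integrate
import scipy.stats

from sepkit.stats import (
    BAND_NAMES,
    COEF_NAMES,
    adjust_max_abs_z,
    aicc,
    all_cells,
    contrasts,
    design_row,
    estimated_marginal_means,
    fit_gamma_lmm,
    paired_t_test,
    simulate_from_model,
)

TABLE2_BETA = np.array(
    [1.11, 0.01, -0.21, 0.01, -0.35, 0.04, 0.02, 0.03, 0.00, 0.07, -0.00, -0.04]
)


class TestPairedT:
    def test_equal_vectors(self):
        r = paired_t_test(np.arange(5.0), np.arange(5.0))
        assert r.t == 0.0 and r.p == 1.0

    def test_hand_computed_example(self):
        # d = (1, 2, 3): mean 2, sd 1, t = 2/(1/sqrt 3) = 2 sqrt 3
        r = paired_t_test(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert r.t == pytest.approx(2 * math.sqrt(3))
        assert r.df == 2
        assert r.p == pytest.approx(2 * scipy.stats.t.sf(2 * math.sqrt(3), 2))
        assert r.effect_r == pytest.approx(math.sqrt(12 / 14))
        crit = scipy.stats.t.ppf(0.975, 2)
        assert r.ci_low == pytest.approx(2 - crit / math.sqrt(3))
        assert r.ci_high == pytest.approx(2 + crit / math.sqrt(3))

    def test_df_convention(self, rng):
        x = rng.standard_normal(34)
        r = paired_t_test(x, x + rng.standard_normal(34))
        assert r.df == 33

    def test_zero_variance_nonzero_mean(self):
        r = paired_t_test(np.array([2.0, 2.0]), np.array([1.0, 1.0]))
        assert math.isinf(r.t) and r.p == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test(np.array([1.0]), np.array([2.0]))


class TestDesignCoding:
    def test_reference_cell(self):
        np.testing.assert_array_equal(
            design_row("FIR", "0.5-1000", "no"), np.eye(12)[0]
        )

    def test_full_grid_rank(self):
        X = np.vstack([design_row(*cell) for cell in all_cells()])
        assert np.linalg.matrix_rank(X) == 12


class TestGammaLMM:
    def test_constant_response_intercept_only(self):
        rows = [
            dict(subject_id=f"S{i}", dataset_id=f"D{i}", filter=f, band=b, ica=a,
                 n30_amplitude_uv=3.0)
            for i in range(4)
            for f, b, a in all_cells()
        ]
        fit = fit_gamma_lmm(pd.DataFrame(rows), compute_vcov=False)
        assert fit.beta[0] == pytest.approx(math.log(3.0), abs=1e-4)
        np.testing.assert_allclose(fit.beta[1:], 0.0, atol=1e-4)
        assert fit.sigma_subject < 1e-3

    def test_loglik_matches_brute_force_integration(self):
        """AGQ marginal likelihood vs dense numerical integration of
        ∫ Π Gamma(y; k, exp(xβ+z)k⁻¹…) N(z; 0, σ²) dz on a tiny instance."""
        data = simulate_from_model(TABLE2_BETA, 0.4, 6.0, n_subjects=2, n_datasets=1, seed=3)
        fit = fit_gamma_lmm(data, compute_vcov=False)
        X = np.vstack([design_row(r["filter"], r["band"], r["ica"]) for _, r in data.iterrows()])
        y = data["n30_amplitude_uv"].to_numpy()
        eta = X @ fit.beta
        total = 0.0
        for sid in data["subject_id"].unique():
            sel = (data["subject_id"] == sid).to_numpy()

            def integrand(z, sel=sel):
                mu = np.exp(eta[sel] + z)
                dens = scipy.stats.gamma.pdf(y[sel], a=fit.shape, scale=mu / fit.shape)
                return np.prod(dens) * scipy.stats.norm.pdf(z, scale=fit.sigma_subject)

            val, _ = scipy.integrate.quad(integrand, -8 * fit.sigma_subject,
                                          8 * fit.sigma_subject, limit=200)
            total += math.log(val)
        assert fit.loglik == pytest.approx(total, abs=1e-4)

    def test_sigma_zero_limit_equals_glm(self):
        import statsmodels.api as sm

        data = simulate_from_model(TABLE2_BETA, 0.0, 8.0, n_subjects=10, n_datasets=2, seed=5)
        fit = fit_gamma_lmm(data, compute_vcov=False)
        X = np.vstack([design_row(r["filter"], r["band"], r["ica"]) for _, r in data.iterrows()])
        glm = sm.GLM(
            data["n30_amplitude_uv"].to_numpy(), X,
            family=sm.families.Gamma(link=sm.families.links.Log()),
        ).fit()
        np.testing.assert_allclose(fit.beta, glm.params, atol=1e-3)

    def test_scaling_invariance(self):
        data = simulate_from_model(TABLE2_BETA, 0.3, 8.0, n_subjects=6, n_datasets=1, seed=9)
        fit1 = fit_gamma_lmm(data, compute_vcov=False)
        data2 = data.copy()
        data2["n30_amplitude_uv"] *= 10.0
        fit2 = fit_gamma_lmm(data2, compute_vcov=False)
        assert fit2.beta[0] - fit1.beta[0] == pytest.approx(math.log(10.0), abs=1e-3)
        np.testing.assert_allclose(fit2.beta[1:], fit1.beta[1:], atol=1e-3)

    def test_nonpositive_response_rejected(self):
        data = simulate_from_model(TABLE2_BETA, 0.3, 8.0, n_subjects=2, seed=1)
        data.loc[0, "n30_amplitude_uv"] = -1.0
        with pytest.raises(ValueError):
            fit_gamma_lmm(data)

    def test_identity_link_fits(self):
        data = simulate_from_model(TABLE2_BETA, 0.2, 8.0, n_subjects=6, seed=2)
        fit_log = fit_gamma_lmm(data, link="log", compute_vcov=False)
        fit_id = fit_gamma_lmm(data, link="identity", compute_vcov=False)
        assert np.isfinite(fit_id.loglik)
        # data generated under the log link: AICc must prefer it
        assert fit_log.aicc < fit_id.aicc


class TestAICc:
    def test_formula(self):
        data = simulate_from_model(TABLE2_BETA, 0.3, 8.0, n_subjects=4, seed=7)
        fit = fit_gamma_lmm(data, compute_vcov=False)
        n, p = fit.n_obs, fit.n_params
        expected = 2 * p - 2 * fit.loglik + 2 * p * (p + 1) / (n - p - 1)
        assert fit.aicc == pytest.approx(expected)
        assert fit.aicc > 2 * p - 2 * fit.loglik  # AICc > AIC

    def test_divergence_guarded(self):
        data = simulate_from_model(TABLE2_BETA, 0.3, 8.0, n_subjects=4, seed=7)
        fit = fit_gamma_lmm(data, compute_vcov=False)
        with pytest.raises(ValueError):
            aicc(fit, n_obs=fit.n_params + 1)


@pytest.fixture(scope="module")
def fitted():
    data = simulate_from_model(TABLE2_BETA, 0.3, 8.0, n_subjects=17, n_datasets=2, seed=42)
    return fit_gamma_lmm(data)


class TestEMMsAndContrasts:

    def test_reference_cell_emm_is_exp_beta0(self, fitted):
        emm = estimated_marginal_means(fitted)
        ref = emm[(emm["filter"] == "FIR") & (emm["band"] == "0.5-1000") & (emm.ica == "no")]
        assert ref["mean"].iloc[0] == pytest.approx(math.exp(fitted.beta[0]))

    def test_emms_recover_true_cell_means(self, fitted):
        emm = estimated_marginal_means(fitted)
        for _, row in emm.iterrows():
            truth = math.exp(design_row(row["filter"], row["band"], row["ica"]) @ TABLE2_BETA)
            assert abs(row["mean"] - truth) < 3 * row["se"]

    def test_all_equal_responses_identical_emms(self):
        rows = [
            dict(subject_id=f"S{i}", dataset_id=f"D{i}", filter=f, band=b, ica=a,
                 n30_amplitude_uv=2.5)
            for i in range(3)
            for f, b, a in all_cells()
        ]
        fit = fit_gamma_lmm(pd.DataFrame(rows))
        emm = estimated_marginal_means(fit)
        np.testing.assert_allclose(emm["mean"], 2.5, rtol=1e-3)

    def test_ica_contrast_is_minus_beta2_at_reference(self, fitted):
        table = contrasts(fitted, "ica_within", seed=0)
        ref = table[(table["filter"] == "FIR") & (table["band"] == "0.5-1000")]
        assert math.log(ref["ratio"].iloc[0]) == pytest.approx(-fitted.beta[2], abs=1e-10)

    def test_self_ratio_is_one(self, fitted):
        L = design_row("FIR", "3-1000", "yes") - design_row("FIR", "3-1000", "yes")
        assert math.exp(L @ fitted.beta) == 1.0

    def test_contrast_family_shapes(self, fitted):
        assert len(contrasts(fitted, "filter_within", seed=0)) == 6
        assert len(contrasts(fitted, "band_within", seed=0)) == 12
        assert len(contrasts(fitted, "ica_within", seed=0)) == 6

    def test_adjusted_p_never_below_raw(self, fitted):
        for family in ("filter_within", "band_within", "ica_within"):
            table = contrasts(fitted, family, seed=0)
            assert (table["p_adj"] >= table["p_raw"] - 0.01).all()

    def test_adjustment_controls_familywise_error(self):
        """Null z-vectors drawn from the contrast correlation: the single-step
        max-|z| adjustment keeps the family-wise error near nominal."""
        rng = np.random.default_rng(123)
        q = 6
        corr = 0.5 * np.eye(q) + 0.5  # exchangeable family
        chol = np.linalg.cholesky(corr)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            z = chol @ rng.standard_normal(q)
            p_adj = adjust_max_abs_z(z, corr, n_draws=20_000, seed=7)
            rejections += bool((p_adj < 0.05).any())
        assert rejections / n_rep <= 0.06

    def test_identity_link_has_no_ratio_contrasts(self):
        data = simulate_from_model(TABLE2_BETA, 0.2, 8.0, n_subjects=4, seed=2)
        fit = fit_gamma_lmm(data, link="identity", compute_vcov=False)
        with pytest.raises(ValueError):
            contrasts(fit, "ica_within", seed=0)


def test_simulated_dataset_shape():
    data = simulate_from_model(TABLE2_BETA, 0.3, 8.0, n_subjects=17, n_datasets=2, seed=0)
    assert len(data) == 17 * 2 * 12
    assert (data["n30_amplitude_uv"] > 0).all()
    assert data.groupby(["subject_id", "dataset_id"]).size().eq(12).all()
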