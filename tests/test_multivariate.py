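"""Multivariate ACE models and the correlation decomposition."""

import numpy as np
import pytest

from twinpk.config import VarianceSpec, default_variance_spec
from twinpk.multivariate import (
    MultivariateFit, fit_multivariate, multivariate_pairs,
    correlation_decomposition,
)
from twinpk.simulate import draw_latent_traits
from twinpk.univariate import TwinModelError, fit_variance_model
from conftest import quick_cohort


def make_table(spec, n_mz, n_dz, seed):
    coh = quick_cohort(n_mz, n_dz, seed)
    lat = draw_latent_traits(coh, spec, None, np.random.default_rng(seed))
    df = coh.merge(lat, on="subject_id")
    for t in spec.traits:
        df[t] = np.exp(df[t])
    return df


def manual_fit(A, C, E, traits=("a", "b")) -> MultivariateFit:
    p = len(traits)
    return MultivariateFit(
        model="ACE", traits=traits, beta=np.zeros((p, 1)),
        beta_names=("intercept",), A=np.asarray(A, float),
        C=np.asarray(C, float), E=np.asarray(E, float), loglik=0.0,
        n_params=0, n_pairs=0, n_obs=0, converged=True)


class TestDecomposition:
    def test_hand_computed_genetic_correlation(self):
        fit = manual_fit([[1.0, 0.5], [0.5, 4.0]], np.zeros((2, 2)), np.eye(2))
        dec = correlation_decomposition(fit)
        assert dec.r_g[0, 1] == pytest.approx(0.25)

    def test_diagonal_A_gives_zero_genetic_correlation(self):
        fit = manual_fit(np.diag([1.0, 2.0]), np.eye(2) * 0.5,
                         [[1.0, 0.3], [0.3, 1.0]])
        assert correlation_decomposition(fit).r_g[0, 1] == pytest.approx(0.0)

    def test_pure_genetic_covariance_gives_unit_bivariate_h2(self):
        A = np.array([[1.0, 0.6], [0.6, 2.0]])
        fit = manual_fit(A, np.zeros((2, 2)), np.zeros((2, 2)))
        dec = correlation_decomposition(fit)
        assert np.allclose(dec.bivariate_h2, 1.0)

    def test_phenotypic_correlation_identity(self):
        A = np.array([[1.0, 0.2], [0.2, 1.5]])
        C = np.array([[0.5, -0.1], [-0.1, 0.4]])
        E = np.array([[0.8, 0.15], [0.15, 0.9]])
        dec = correlation_decomposition(manual_fit(A, C, E))
        P = A + C + E
        direct = P / np.sqrt(np.outer(np.diag(P), np.diag(P)))
        assert np.allclose(dec.r_ph, direct, atol=1e-12)

    def test_bivariate_h2_sign_identity(self):
        A = np.array([[0.7, -0.3], [-0.3, 1.1]])
        C = np.eye(2) * 0.2
        E = np.eye(2) * 0.5
        fit = manual_fit(A, C, E)
        dec = correlation_decomposition(fit)
        assert np.allclose(dec.bivariate_h2 * fit.phenotypic, A, atol=1e-12)


class TestFitting:
    def test_null_recovery(self):
        spec = VarianceSpec(np.zeros((2, 2)), np.zeros((2, 2)), np.eye(2), ("a", "b"))
        df = make_table(spec, 1000, 1000, 1)
        fit = fit_multivariate(df, ("a", "b"), polish=False)
        assert np.linalg.norm(fit.A) < 0.06
        assert np.linalg.norm(fit.C) < 0.06
        assert np.allclose(fit.E, np.eye(2), atol=0.08)

    def test_p1_matches_univariate(self):
        spec = VarianceSpec.from_proportions(0.5, 0.25, 0.4, "a")
        df = make_table(spec, 40, 15, 2)
        uni = fit_variance_model(df, "a", model="ACE", compute_se=False)
        mv = fit_multivariate(df, ("a",), model="ACE")
        assert mv.loglik == pytest.approx(uni.loglik, abs=1e-6)
        assert mv.h2[0] == pytest.approx(uni.h2, abs=1e-4)

    def test_trait_permutation_consistency(self):
        spec = default_variance_spec().subset(["midazolam_auc", "ohmidazolam_auc"])
        df = make_table(spec, 40, 15, 3)
        f_ab = fit_multivariate(df, spec.traits)
        f_ba = fit_multivariate(df, spec.traits[::-1])
        assert f_ab.loglik == pytest.approx(f_ba.loglik, abs=1e-6)
        d_ab = correlation_decomposition(f_ab)
        d_ba = correlation_decomposition(f_ba)
        assert d_ab.r_g[0, 1] == pytest.approx(d_ba.r_g[1, 0], abs=1e-4)

    def test_optimum_beats_random_probe(self):
        """Random parameter probes around the optimum never improve the
        likelihood on a tiny 8-pair instance."""
        spec = VarianceSpec.from_proportions(0.4, 0.3, 0.5, "a")
        spec = VarianceSpec(
            np.array([[0.2, 0.05], [0.05, 0.3]]),
            np.array([[0.1, 0.02], [0.02, 0.1]]),
            np.array([[0.2, 0.0], [0.0, 0.2]]), ("a", "b"))
        df = make_table(spec, 5, 3, 4)
        data = multivariate_pairs(df, ("a", "b"), covariates=())
        fit = fit_multivariate(data)
        # rebuild the objective exactly as the fitter sees it
        from twinpk.multivariate import _vech_indices
        rng = np.random.default_rng(0)
        tril = _vech_indices(2)
        theta_opt = np.concatenate([
            fit.beta.reshape(-1),
            np.linalg.cholesky(fit.A + 1e-12 * np.eye(2))[tril],
            np.linalg.cholesky(fit.C + 1e-12 * np.eye(2))[tril],
            np.linalg.cholesky(fit.E + 1e-12 * np.eye(2))[tril]])

        def loglik(theta):
            beta = theta[:2].reshape(2, 1)
            Ls = [np.zeros((2, 2)) for _ in range(3)]
            for i, L in enumerate(Ls):
                L[tril] = theta[2 + 3 * i: 5 + 3 * i]
            A, C, E = (L @ L.T for L in Ls)
            P = A + C + E
            resid = data.y - np.einsum("nik,jk->nij", data.X, beta)
            r2p = resid.reshape(len(data.y), 4)
            ll = 0.0
            for mask, W in ((data.is_mz, A + C), (~data.is_mz, 0.5 * A + C)):
                sigma = np.block([[P, W], [W, P]])
                sign, logdet = np.linalg.slogdet(sigma)
                if sign <= 0:
                    return -np.inf
                sol = np.linalg.solve(sigma, r2p[mask].T)
                ll += -0.5 * (mask.sum() * (4 * np.log(2 * np.pi) + logdet)
                              + float(np.sum(r2p[mask].T * sol)))
            return ll

        base = loglik(theta_opt)
        assert base == pytest.approx(fit.loglik, abs=1e-6)
        for _ in range(500):
            probe = theta_opt + rng.normal(0, 0.05, theta_opt.shape)
            assert loglik(probe) <= fit.loglik + 1e-6

    def test_overparameterized_model_rejected(self):
        spec = default_variance_spec()
        df = make_table(spec, 3, 2, 5)
        with pytest.raises(TwinModelError, match="parameters"):
            fit_multivariate(df, spec.traits)

    def test_missing_trait_rows_dropped_with_count(self):
        spec = default_variance_spec().subset(["midazolam_auc", "ohmidazolam_auc"])
        df = make_table(spec, 20, 8, 6)
        df.loc[df.index[:3], "midazolam_auc"] = np.nan
        data = multivariate_pairs(df, spec.traits)
        assert data.n_dropped_subjects >= 3
        assert data.n_pairs < 28
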