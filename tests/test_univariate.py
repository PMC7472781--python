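"""Univariate twin models: unstructured correlations, ACE/AE/CE ML fits,
likelihood properties against a grid-search oracle, information criteria."""

import numpy as np
import pandas as pd
import pytest

from twinpk.config import VarianceSpec
from twinpk.simulate import draw_latent_traits
from twinpk.univariate import (
    TwinModelError, twin_pairs, fit_unstructured, fit_variance_model,
    model_comparison, falconer_estimates, aic, bic,
)
from conftest import quick_cohort


def make_table(spec: VarianceSpec, n_mz: int, n_dz: int, seed: int,
               trait: str = "y") -> pd.DataFrame:
    coh = quick_cohort(n_mz, n_dz, seed)
    lat = draw_latent_traits(coh, spec, None, np.random.default_rng(seed))
    df = coh.merge(lat, on="subject_id")
    df[trait] = np.exp(df[trait])
    return df


class TestUnstructured:
    def test_degenerate_construction(self):
        rng = np.random.default_rng(0)
        coh = quick_cohort(60, 200, 0)
        mz = coh.zygosity == "MZ"
        y = np.empty(len(coh))
        shared = rng.normal(0, 1, mz.sum() // 2)
        y[mz.to_numpy()] = np.repeat(shared, 2)          # MZ co-twins identical
        y[~mz.to_numpy()] = rng.normal(0, 1, (~mz).sum())  # DZ independent
        df = coh.assign(y=np.exp(y))
        fit = fit_unstructured(df, "y", compute_se=False)
        assert fit.r_mz > 0.99
        assert abs(fit.r_dz) < 0.12

    def test_invariant_to_twin_order(self):
        spec = VarianceSpec.from_proportions(0.5, 0.3, 0.4, "y")
        df = make_table(spec, 30, 12, 3)
        flipped = df.iloc[::-1].reset_index(drop=True)
        a = fit_unstructured(df, "y", compute_se=False)
        b = fit_unstructured(flipped, "y", compute_se=False)
        assert a.r_mz == pytest.approx(b.r_mz, abs=1e-6)
        assert a.r_dz == pytest.approx(b.r_dz, abs=1e-6)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-8)

    def test_single_zygosity_reports_absent_correlation(self):
        spec = VarianceSpec.from_proportions(0.4, 0.2, 0.3, "y")
        df = make_table(spec, 20, 0, 5)
        fit = fit_unstructured(df, "y", compute_se=False)
        assert fit.r_mz is not None
        assert fit.r_dz is None

    def test_recovers_generating_correlations_at_study_size(self):
        # 1-OH-midazolam generating values across replicate studies
        spec = VarianceSpec.from_proportions(0.73, 0.21, 0.31, "y")
        r_mz, r_dz = [], []
        for rep in range(60):
            df = make_table(spec, 43, 14, 100 + rep)
            fit = fit_unstructured(df, "y", compute_se=False)
            r_mz.append(fit.r_mz)
            r_dz.append(fit.r_dz)
        assert np.mean(r_mz) == pytest.approx(0.94, abs=0.02)
        assert np.mean(r_dz) == pytest.approx(0.575, abs=0.06)


class TestVarianceModels:
    def test_large_sample_heritability_recovery(self):
        # mean over replicates keeps the Monte-Carlo error well inside
        # the +/-0.03 band (single-replicate SE at 2000 pairs is ~0.025)
        spec = VarianceSpec.from_proportions(0.73, 0.21, 0.3, "y")
        h2s, c2s = [], []
        for rep in range(5):
            df = make_table(spec, 1000, 1000, 40 + rep)
            fit = fit_variance_model(df, "y", model="ACE", compute_se=False)
            h2s.append(fit.h2)
            c2s.append(fit.c2_prop)
        assert np.mean(h2s) == pytest.approx(0.73, abs=0.03)
        assert np.mean(c2s) == pytest.approx(0.21, abs=0.03)

    def test_proportions_sum_to_one(self):
        spec = VarianceSpec.from_proportions(0.3, 0.3, 1.0, "y")
        for model in ("ACE", "AE", "CE"):
            fit = fit_variance_model(make_table(spec, 40, 15, 9), "y",
                                     model=model, compute_se=False)
            assert fit.h2 + fit.c2_prop + fit.e2_prop == pytest.approx(1.0, abs=1e-9)

    def test_e_only_data_hits_boundary(self):
        spec = VarianceSpec(np.zeros((1, 1)), np.zeros((1, 1)),
                            np.array([[0.4]]), ("y",))
        df = make_table(spec, 400, 400, 17)
        fit = fit_variance_model(df, "y", model="ACE", compute_se=False)
        assert fit.h2 < 0.05 and fit.c2_prop < 0.05
        assert fit.e2_prop > 0.9

    def test_falconer_closed_form(self):
        a2, c2, e2 = falconer_estimates(0.94, 0.59)
        assert a2 == pytest.approx(0.70, abs=1e-12)
        assert c2 == pytest.approx(0.24, abs=1e-12)
        assert e2 == pytest.approx(0.06, abs=1e-12)

    def test_likelihood_nesting(self):
        spec = VarianceSpec.from_proportions(0.4, 0.3, 0.5, "y")
        for rep in range(5):
            df = make_table(spec, 30, 10, 200 + rep)
            fits = {m: fit_variance_model(df, "y", model=m, compute_se=False)
                    for m in ("ACE", "AE", "CE")}
            assert fits["ACE"].loglik >= fits["AE"].loglik - 1e-6
            assert fits["ACE"].loglik >= fits["CE"].loglik - 1e-6

    def test_optimizer_beats_grid_oracle(self):
        """Coarse grid over variance shares and total variance never beats
        the optimizer's likelihood on tiny instances."""
        from twinpk.univariate import _pair_loglik, _residuals
        spec = VarianceSpec.from_proportions(0.5, 0.2, 0.6, "y")
        for rep in range(3):
            df = make_table(spec, 6, 4, 300 + rep)
            data = twin_pairs(df, "y", covariates=())
            fit = fit_variance_model(data, model="ACE", compute_se=False)
            resid = _residuals(data, fit.beta)
            mz, dz = data.is_mz, ~data.is_mz
            tot_hat = fit.a2 + fit.c2 + fit.e2
            best_grid = -np.inf
            shares = np.linspace(0, 1, 20)
            for tot in tot_hat * np.linspace(0.5, 2.0, 20):
                for h2 in shares:
                    for c2 in shares:
                        if h2 + c2 > 1:
                            continue
                        a, c = h2 * tot, c2 * tot
                        v = tot
                        ll = (_pair_loglik(resid[mz], v, a + c)
                              + _pair_loglik(resid[dz], v, a / 2 + c))
                        best_grid = max(best_grid, ll)
            assert fit.loglik >= best_grid - 1e-6

    def test_unconstrained_variant_allows_negative_components(self):
        spec = VarianceSpec(np.zeros((1, 1)), np.zeros((1, 1)),
                            np.array([[0.3]]), ("y",))
        res = []
        for rep in range(20):
            df = make_table(spec, 20, 10, 400 + rep)
            fit = fit_variance_model(df, "y", compute_se=False, constrain="none")
            res.append(fit.a2)
        assert min(res) < 0  # sampling noise must be able to go negative

    def test_delta_method_ses_track_replicate_spread(self):
        # interior generating values where asymptotic SEs are meaningful
        spec = VarianceSpec.from_proportions(0.4, 0.3, 0.5, "y")
        h2s, ses = [], []
        for rep in range(80):
            df = make_table(spec, 43, 14, 500 + rep)
            fit = fit_variance_model(df, "y", compute_se=True, constrain="none")
            h2s.append(fit.h2)
            ses.append(fit.se["h2"])
        assert np.mean(ses) == pytest.approx(np.std(h2s), rel=0.25)


class TestInformationCriteria:
    def test_aic_from_published_loglik(self):
        assert aic(-2274.6, 32) == pytest.approx(4613.2, abs=0.05)

    def test_bic_with_456_observations(self):
        # 114 subjects x 4 traits
        assert bic(-2274.6, 32, 456) == pytest.approx(4745.1, abs=0.05)

    def test_comparison_flags_best_and_rejects_mixed_data(self):
        spec = VarianceSpec.from_proportions(0.5, 0.2, 0.4, "y")
        df = make_table(spec, 25, 10, 31)
        fits = [fit_variance_model(df, "y", model=m, compute_se=False)
                for m in ("ACE", "AE", "CE")]
        table = model_comparison(fits)
        assert table.best_aic.sum() == 1
        other = make_table(spec, 25, 10, 32)
        bad = fit_variance_model(other, "y", model="ACE", compute_se=False)
        with pytest.raises(TwinModelError, match="same data"):
            model_comparison([fits[0], bad])
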