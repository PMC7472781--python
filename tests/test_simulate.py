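"""Synthetic twin-study generator: cohort structure, ACE covariance
structure of the latent traits, PK and endogenous measurement models."""

import numpy as np
import pandas as pd
import pytest

from twinpk.config import StudyConfig, VarianceSpec, ConfigError, default_variance_spec
from twinpk.simulate import (
    SimulationError, generate_cohort, draw_latent_traits, simulate_endogenous,
    simulate_study, infusion_profile,
)
from twinpk.nca import nca_table
from conftest import quick_cohort


def pair_corr(values: np.ndarray) -> float:
    """Within-pair correlation, symmetrized over twin order."""
    both = np.concatenate([values, values[:, ::-1]])
    return float(np.corrcoef(both[:, 0], both[:, 1])[0, 1])


class TestCohort:
    def test_analysis_cohort_size(self):
        df = generate_cohort(StudyConfig(n_mz_pairs=43, n_dz_pairs=14))
        assert len(df) == 114
        assert (df.zygosity == "MZ").sum() == 86
        assert (df.zygosity == "DZ").sum() == 28

    def test_enrolled_cohort_size(self):
        df = generate_cohort(StudyConfig(n_mz_pairs=44, n_dz_pairs=14))
        assert len(df) == 116

    def test_deterministic_for_fixed_seed(self, small_config):
        a = simulate_study(small_config, seed=99)
        b = simulate_study(small_config, seed=99)
        pd.testing.assert_frame_equal(a.subjects, b.subjects)
        pd.testing.assert_frame_equal(a.concentrations, b.concentrations)
        pd.testing.assert_frame_equal(a.endogenous, b.endogenous)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigError, match="empty cohort"):
            StudyConfig(n_mz_pairs=0, n_dz_pairs=0)

    def test_covariates_within_ranges(self, paper_design_config):
        df = generate_cohort(paper_design_config)
        cd = paper_design_config.covariate_distributions
        assert df.age.between(*cd.age_range).all()
        assert df.weight.between(*cd.weight_range).all()
        # twins share age and sex
        for _, g in df.groupby("pair_id"):
            assert g.age.nunique() == 1 and g.sex.nunique() == 1

    def test_mz_genotypes_identical_dz_sibling_correlated(self):
        cfg = StudyConfig(n_mz_pairs=1500, n_dz_pairs=1500, seed=4)
        cfg.genotype_frequencies.cyp3a5_1 = 0.3  # common allele for power
        df = generate_cohort(cfg)
        g = df.cyp3a5_1.to_numpy().reshape(-1, 2)
        mz = (df.zygosity.to_numpy()[::2] == "MZ")
        assert np.all(g[mz, 0] == g[mz, 1])
        r_dz = pair_corr(g[~mz].astype(float))
        assert r_dz == pytest.approx(0.5, abs=0.06)


class TestLatentTraits:
    def test_pure_noise_limit(self):
        spec = VarianceSpec(np.zeros((1, 1)), np.zeros((1, 1)), np.eye(1), ("y",))
        coh = quick_cohort(5000, 5000)
        lat = draw_latent_traits(coh, spec, None, np.random.default_rng(0))
        y = lat.y.to_numpy().reshape(-1, 2)
        mz = coh.zygosity.to_numpy()[::2] == "MZ"
        assert abs(pair_corr(y[mz])) < 0.05
        assert abs(pair_corr(y[~mz])) < 0.05

    def test_pure_additive_limit(self):
        spec = VarianceSpec(np.eye(1), np.zeros((1, 1)), np.zeros((1, 1)), ("y",))
        coh = quick_cohort(5000, 5000)
        lat = draw_latent_traits(coh, spec, None, np.random.default_rng(1))
        y = lat.y.to_numpy().reshape(-1, 2)
        mz = coh.zygosity.to_numpy()[::2] == "MZ"
        assert np.allclose(y[mz, 0], y[mz, 1])
        assert pair_corr(y[~mz]) == pytest.approx(0.5, abs=0.04)

    def test_table_generating_values_give_expected_twin_correlations(self):
        # h2=0.73, c2=0.21, e2=0.06 -> r_mz = 0.94, r_dz = 0.575
        spec = VarianceSpec.from_proportions(0.73, 0.21, 1.0, "y")
        coh = quick_cohort(5000, 5000)
        lat = draw_latent_traits(coh, spec, None, np.random.default_rng(2))
        y = lat.y.to_numpy().reshape(-1, 2)
        mz = coh.zygosity.to_numpy()[::2] == "MZ"
        assert pair_corr(y[mz]) == pytest.approx(0.94, abs=0.02)
        assert pair_corr(y[~mz]) == pytest.approx(0.575, abs=0.03)

    def test_total_covariance_converges_to_A_plus_C_plus_E(self):
        spec = default_variance_spec()
        coh = quick_cohort(5000, 5000)
        lat = draw_latent_traits(coh, spec, None, np.random.default_rng(3))
        vals = lat[list(spec.traits)].to_numpy()
        emp = np.cov(vals.T)
        target = spec.phenotypic
        n = len(vals)
        # elementwise Monte-Carlo 3*SE band for a covariance entry
        se = np.sqrt((np.outer(np.diag(target), np.diag(target)) + target ** 2) / n)
        assert np.all(np.abs(emp - target) < 3.5 * se)

    def test_cross_twin_covariance_structure(self):
        spec = default_variance_spec()
        coh = quick_cohort(8000, 8000)
        lat = draw_latent_traits(coh, spec, None, np.random.default_rng(4))
        vals = lat[list(spec.traits)].to_numpy()
        p = len(spec.traits)
        pairs = vals.reshape(-1, 2, p)
        mz = coh.zygosity.to_numpy()[::2] == "MZ"

        def cross_cov(block):
            r1, r2 = block[:, 0, :], block[:, 1, :]
            r1 = r1 - r1.mean(0)
            r2 = r2 - r2.mean(0)
            c = (r1.T @ r2) / (len(block) - 1)
            return 0.5 * (c + c.T)

        assert np.allclose(cross_cov(pairs[mz]), spec.A + spec.C, atol=0.02)
        assert np.allclose(cross_cov(pairs[~mz]), 0.5 * spec.A + spec.C, atol=0.02)

    def test_non_psd_component_identified(self):
        spec = VarianceSpec(np.eye(2), np.eye(2), np.eye(2), ("a", "b"))
        spec.A = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(SimulationError, match="A"):
            draw_latent_traits(quick_cohort(5, 5), spec, None, 0)

    def test_incomplete_pair_rejected(self):
        coh = quick_cohort(3, 0).iloc[:-1]
        spec = VarianceSpec.from_proportions(0.5, 0.2, 1.0, "y")
        with pytest.raises(SimulationError, match="2 subjects"):
            draw_latent_traits(coh, spec, None, 0)


class TestPKSimulation:
    def test_noise_free_clearance_recovery_within_2pct(self):
        cfg = StudyConfig(n_mz_pairs=15, n_dz_pairs=5, n_occasions=1,
                          occasion_cv=0.0, metabolite_occasion_cv=0.0,
                          assay_cv=0.0, seed=11)
        study = simulate_study(cfg)
        pk = nca_table(study.concentrations, cfg.dose_ug)
        truth = np.exp(study.latent.set_index("subject_id")["midazolam_auc"])
        cl_true = cfg.dose_ug / truth
        cl_rec = pk.query("analyte == 'midazolam'").set_index("subject_id")["cl"]
        assert np.max(np.abs(cl_rec / cl_true - 1.0)) < 0.02

    def test_doubling_clearance_halves_auc(self):
        t = np.array(StudyConfig().sampling_times_min)
        c1 = infusion_profile(t, 200.0, 0.4, 163.0, 2.0)
        c2 = infusion_profile(t, 200.0, 0.8, 163.0, 2.0)
        assert np.allclose(c2, c1 / 2.0)

    def test_nonpositive_clearance_rejected(self):
        with pytest.raises(SimulationError):
            infusion_profile(np.array([0.0, 10.0]), 200.0, 0.0, 163.0, 2.0)

    def test_within_subject_auc_cv_matches_occasion_cv(self):
        cfg = StudyConfig(n_mz_pairs=50, n_dz_pairs=16, seed=21)
        study = simulate_study(cfg)
        pk = nca_table(study.concentrations, cfg.dose_ug)
        parent = pk.query("analyte == 'midazolam'")
        cv = parent.groupby("subject_id")["auc_inf"].apply(
            lambda x: x.std(ddof=1) / x.mean())
        assert cv.mean() == pytest.approx(0.113, abs=0.02)


class TestEndogenous:
    def test_zero_occasion_noise_gives_identical_values(self):
        cfg = StudyConfig(n_mz_pairs=4, n_dz_pairs=2, seed=5)
        cfg.endogenous_occasion_cv = {"ohcholesterol": 0.0, "ohcortisol": 0.0}
        study = simulate_study(cfg)
        spread = study.endogenous.groupby(["subject_id", "trait"])["value"].nunique()
        assert (spread == 1).all()

    def test_median_matches_configured_location(self):
        cfg = StudyConfig(n_mz_pairs=1500, n_dz_pairs=500, seed=6)
        coh = generate_cohort(cfg)
        from twinpk.simulate import mean_coeffs_from_config
        lat = draw_latent_traits(coh, cfg.ace_spec, mean_coeffs_from_config(cfg),
                                 np.random.default_rng(6))
        med = np.median(np.exp(lat["ohcholesterol"]))
        assert med == pytest.approx(24.56, rel=0.05)

    def test_autocorrelation_reduces_within_subject_variation(self):
        from twinpk.repeatability import repeatability_table
        cfg = StudyConfig(n_mz_pairs=100, n_dz_pairs=30, seed=8)
        cfg.endogenous_occasion_cv = {"ohcholesterol": 0.2, "ohcortisol": 0.2}
        cfg.endogenous_autocorr = {"ohcholesterol": 1.0, "ohcortisol": 0.0}
        study = simulate_study(cfg)
        rep = repeatability_table(study.endogenous).set_index("trait")
        assert rep.loc["ohcholesterol", "r_gc"] > rep.loc["ohcortisol", "r_gc"]

    def test_negative_noise_cv_rejected(self):
        cfg = StudyConfig(n_mz_pairs=2, n_dz_pairs=1)
        cfg.endogenous_occasion_cv["ohcortisol"] = -0.1
        with pytest.raises((ConfigError, SimulationError)):
            cfg.validate()


class TestConfigRoundTrip:
    def test_yaml_round_trip(self, tmp_path, small_config):
        path = tmp_path / "cfg.yaml"
        small_config.to_yaml(path)
        loaded = StudyConfig.from_yaml(path)
        assert loaded.n_mz_pairs == small_config.n_mz_pairs
        assert np.allclose(loaded.ace_spec.A, small_config.ace_spec.A)
        a = simulate_study(small_config, seed=3).subjects
        b = simulate_study(loaded, seed=3).subjects
        pd.testing.assert_frame_equal(a, b)
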