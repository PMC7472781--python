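"""Synthetic twin-cohort generator with known ACE ground truth.

Generates (i) a cohort of MZ/DZ twin pairs with demographics and CYP3A
genotypes, (ii) per-subject latent log-scale trait values with an exact
ACE cross-twin covariance structure, (iii) per-occasion midazolam /
1-OH-midazolam concentration-time profiles from a one-compartment
zero-order-infusion model, and (iv) per-occasion endogenous biomarker
measurements.  Every stage is a pure function of the configuration and a
seed, so downstream estimators can be validated against the generating
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import StudyConfig, VarianceSpec, ConfigError, TRAITS, TRAIT_UNITS

LN2 = float(np.log(2.0))


class SimulationError(ValueError):
    pass


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent named substreams derived from one master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(s) for s in children]


def _lognormal_multiplier(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size))


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _draw_pair_genotypes(rng: np.random.Generator, q: float, zygosity: str) -> tuple[int, int]:
    """Variant-allele copy numbers for both co-twins.

    MZ twins share their genotype; DZ twins are full siblings, so each
    inherits one allele from each of two simulated parents.
    """
    if zygosity == "MZ":
        g = int(rng.random() < q) + int(rng.random() < q)
        return g, g
    father = rng.random(2) < q
    mother = rng.random(2) < q
    g1 = int(father[rng.integers(2)]) + int(mother[rng.integers(2)])
    g2 = int(father[rng.integers(2)]) + int(mother[rng.integers(2)])
    return g1, g2


def generate_cohort(config: StudyConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate the twin cohort: demographics, zygosity and genotypes.

    Returns one row per subject with columns ``subject_id, pair_id,
    zygosity, sex, age, weight, height, smoker, contraceptive,
    cyp3a4_22, cyp3a5_1``.  Ages and sex are shared within a pair
    (same-sex pairs only); weight derives from a BMI draw and height.
    """
    if config.n_mz_pairs + config.n_dz_pairs == 0:
        raise ConfigError("empty cohort")
    if rng is None:
        rng = _substreams(config.seed, 4)[0]
    cd = config.covariate_distributions
    gf = config.genotype_frequencies
    rows = []
    pair_idx = 0
    for zyg, n_pairs in (("MZ", config.n_mz_pairs), ("DZ", config.n_dz_pairs)):
        for _ in range(n_pairs):
            pair_idx += 1
            pair_id = f"{zyg}{pair_idx:03d}"
            age = float(np.round(rng.uniform(*cd.age_range), 1))
            female = rng.random() < cd.prop_female
            sex = "F" if female else "M"
            smoker = int(rng.random() < cd.prop_smoker_pairs)
            g4 = _draw_pair_genotypes(rng, gf.cyp3a4_22, zyg)
            g5 = _draw_pair_genotypes(rng, gf.cyp3a5_1, zyg)
            for twin in (1, 2):
                h_mean = cd.height_mean_by_sex[1] if female else cd.height_mean_by_sex[0]
                height = float(rng.normal(h_mean, cd.height_sd))
                bmi = float(rng.normal(cd.bmi_mean, cd.bmi_sd))
                weight = float(np.clip(bmi * height ** 2, *cd.weight_range))
                contraceptive = int(female and rng.random() < cd.prop_contraceptive)
                rows.append({
                    "subject_id": f"{pair_id}_{twin}",
                    "pair_id": pair_id,
                    "zygosity": zyg,
                    "sex": sex,
                    "age": age,
                    "weight": round(weight, 1),
                    "height": round(height, 2),
                    "smoker": smoker,
                    "contraceptive": contraceptive,
                    "cyp3a4_22": g4[twin - 1],
                    "cyp3a5_1": g5[twin - 1],
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# latent ACE traits
# ---------------------------------------------------------------------------

def mean_coeffs_from_config(config: StudyConfig) -> dict:
    """Per-trait linear-predictor coefficients on the log scale."""
    coeffs = {}
    for t in config.ace_spec.traits:
        g = config.genotype_effects.get(t, {})
        coeffs[t] = {
            "intercept": config.trait_means.get(t, 0.0),
            "age": config.age_coeffs.get(t, 0.0),
            "sex_male": config.sex_coeffs.get(t, 0.0),
            "cyp3a4_22": g.get("cyp3a4_22", 0.0),
            "cyp3a5_1": g.get("cyp3a5_1", 0.0),
        }
    return coeffs


def _chol_psd(m: np.ndarray, name: str) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    if w.min() < -1e-8:
        raise SimulationError(f"component matrix {name} is not positive semidefinite")
    return v * np.sqrt(np.clip(w, 0.0, None))


def draw_latent_traits(
    cohort: pd.DataFrame,
    ace_spec: VarianceSpec,
    mean_coeffs: dict | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw per-subject latent log-scale trait vectors with ACE structure.

    The latent value is ``X @ beta + a + c + e`` where the additive
    genetic draw ``a`` correlates 1.0 within MZ and 0.5 within DZ pairs,
    the common-environment draw ``c`` is shared within a pair, and ``e``
    is subject-specific.  Cross-twin covariance is therefore ``A + C``
    (MZ) or ``0.5*A + C`` (DZ) and the total covariance ``A + C + E``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    elif rng is None:
        rng = np.random.default_rng(0)
    traits = ace_spec.traits
    p = len(traits)
    La = _chol_psd(ace_spec.A, "A")
    Lc = _chol_psd(ace_spec.C, "C")
    Le = _chol_psd(ace_spec.E, "E")

    codes, uniques = pd.factorize(cohort["pair_id"], sort=False)
    counts = np.bincount(codes)
    if np.any(counts != 2):
        bad = uniques[np.argmax(counts != 2)]
        raise SimulationError(f"pair {bad} does not have 2 subjects")
    order = np.argsort(codes, kind="stable")  # pairs contiguous, twins adjacent
    n_pairs = len(uniques)
    zyg = cohort["zygosity"].to_numpy()[order][::2]
    is_mz = (zyg == "MZ")[:, None]

    z_shared = rng.standard_normal((n_pairs, p))
    z1 = rng.standard_normal((n_pairs, p))
    z2 = rng.standard_normal((n_pairs, p))
    sq2 = np.sqrt(2.0)
    a1 = np.where(is_mz, z_shared, (z_shared + z1) / sq2) @ La.T
    a2 = np.where(is_mz, z_shared, (z_shared + z2) / sq2) @ La.T
    c = rng.standard_normal((n_pairs, p)) @ Lc.T
    e = rng.standard_normal((2 * n_pairs, p)) @ Le.T

    values = np.empty((len(cohort), p))
    values[order[0::2]] = a1 + c + e[0::2]
    values[order[1::2]] = a2 + c + e[1::2]

    if mean_coeffs is not None:
        age = cohort["age"].to_numpy(dtype=float)
        age_c = age - age.mean()
        male = (cohort["sex"].to_numpy() == "M").astype(float)
        g4 = cohort["cyp3a4_22"].to_numpy(dtype=float) if "cyp3a4_22" in cohort else 0.0
        g5 = cohort["cyp3a5_1"].to_numpy(dtype=float) if "cyp3a5_1" in cohort else 0.0
        for j, t in enumerate(traits):
            b = mean_coeffs[t]
            values[:, j] += (b.get("intercept", 0.0)
                             + b.get("age", 0.0) * age_c
                             + b.get("sex_male", 0.0) * male
                             + b.get("cyp3a4_22", 0.0) * g4
                             + b.get("cyp3a5_1", 0.0) * g5)

    latent = pd.DataFrame({"subject_id": cohort["subject_id"].to_numpy()})
    for j, t in enumerate(traits):
        latent[t] = values[:, j]
    return latent


# ---------------------------------------------------------------------------
# concentration-time profiles
# ---------------------------------------------------------------------------

def infusion_profile(times_min: np.ndarray, dose_ug: float, cl_l_per_min: float,
                     half_life_min: float, infusion_min: float) -> np.ndarray:
    """Parent drug concentration (ug/L) for a one-compartment model with a
    zero-order infusion of duration ``infusion_min``.

    During infusion ``C(t) = (R0/CL) * (1 - exp(-k t))``; afterwards the
    concentration declines mono-exponentially with ``k = CL/V`` fixed by
    the configured half-life.
    """
    if cl_l_per_min <= 0:
        raise SimulationError("clearance must be positive")
    t = np.asarray(times_min, dtype=float)
    k = LN2 / half_life_min
    r0 = dose_ug / infusion_min
    c_end = (r0 / cl_l_per_min) * -np.expm1(-k * infusion_min)
    during = (r0 / cl_l_per_min) * -np.expm1(-k * np.minimum(t, infusion_min))
    after = c_end * np.exp(-k * np.clip(t - infusion_min, 0.0, None))
    return np.where(t <= infusion_min, during, after)


def metabolite_profile(times_min: np.ndarray, dose_ug: float, cl_parent: float,
                       parent_half_life_min: float, infusion_min: float,
                       formation_fraction: float, cl_met: float,
                       met_half_life_min: float) -> np.ndarray:
    """Metabolite concentration (ug/L) formed from the parent drug.

    The metabolite compartment receives input ``f_m * k * A_parent(t)``
    and eliminates with ``k_m = ln2 / met_half_life``; its volume is
    ``CL_m / k_m`` so that AUC_inf = f_m * dose / CL_m.  Closed-form
    solution of the linear ODE for both infusion and decay phases.
    """
    t = np.asarray(times_min, dtype=float)
    k = LN2 / parent_half_life_min
    km = LN2 / met_half_life_min
    if abs(km - k) < 1e-12:  # resolve the Bateman degeneracy
        km *= 1.0 + 1e-9
    r0 = dose_ug / infusion_min
    fm = formation_fraction
    vm = cl_met / km
    tau_inf = np.minimum(t, infusion_min)
    # amount during infusion
    am_inf = fm * r0 * ((-np.expm1(-km * tau_inf)) / km
                        - (np.exp(-k * tau_inf) - np.exp(-km * tau_inf)) / (km - k))
    a_parent_end = (r0 / k) * -np.expm1(-k * infusion_min)
    am_end = fm * r0 * ((-np.expm1(-km * infusion_min)) / km
                        - (np.exp(-k * infusion_min) - np.exp(-km * infusion_min)) / (km - k))
    tau = np.clip(t - infusion_min, 0.0, None)
    am_post = (am_end * np.exp(-km * tau)
               + fm * k * a_parent_end * (np.exp(-k * tau) - np.exp(-km * tau)) / (km - k))
    am = np.where(t <= infusion_min, am_inf, am_post)
    return am / vm


def simulate_pk_occasions(
    subject_id: str,
    latent_parent_log_auc: float,
    latent_met_log_auc: float,
    config: StudyConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-occasion parent and metabolite profiles for one subject.

    The occasion effect is a mean-one lognormal multiplier on clearance
    (so the subject's AUC varies across occasions with the configured
    CV); assay noise is multiplicative per sample.
    """
    auc_parent = float(np.exp(latent_parent_log_auc))
    auc_met = float(np.exp(latent_met_log_auc))
    cl = config.dose_ug / auc_parent
    if cl <= 0:
        raise SimulationError("non-positive clearance")
    fm = config.metabolite_params.formation_fraction
    cl_met = fm * config.dose_ug / auc_met
    times = np.asarray(config.sampling_times_min, dtype=float)
    rows = []
    for occ in range(1, config.n_occasions + 1):
        m_p = float(_lognormal_multiplier(rng, config.occasion_cv, ()))
        m_m = float(_lognormal_multiplier(rng, config.metabolite_occasion_cv, ()))
        cp = infusion_profile(times, config.dose_ug, cl * m_p,
                              config.parent_half_life_min,
                              config.infusion_duration_min)
        cm = metabolite_profile(times, config.dose_ug, cl * m_p,
                                config.parent_half_life_min,
                                config.infusion_duration_min,
                                fm, cl_met * m_m,
                                config.metabolite_params.half_life_min)
        cp = cp * _lognormal_multiplier(rng, config.assay_cv, cp.shape)
        cm = cm * _lognormal_multiplier(rng, config.assay_cv, cm.shape)
        for analyte, conc in (("midazolam", cp), ("1-OH-midazolam", cm)):
            for ti, ci in zip(times, conc):
                rows.append({
                    "subject_id": subject_id, "occasion": occ, "analyte": analyte,
                    "time_min": ti, "conc_ug_per_L": max(float(ci), 0.0),
                })
    return pd.DataFrame(rows)


def simulate_concentrations(latent: pd.DataFrame, config: StudyConfig,
                            rng: np.random.Generator) -> pd.DataFrame:
    frames = [
        simulate_pk_occasions(row["subject_id"], row["midazolam_auc"],
                              row["ohmidazolam_auc"], config, rng)
        for _, row in latent.iterrows()
    ]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# endogenous biomarkers
# ---------------------------------------------------------------------------

def simulate_endogenous(latent: pd.DataFrame, config: StudyConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Per-occasion 4ß-OH-cholesterol and 6ß-OH-cortisol measurements.

    ``measurement = exp(latent) * lognormal occasion noise``.  The
    autocorrelation parameter rho splits the occasion deviation into a
    subject-constant and an occasion-specific part; rho -> 1 makes the
    three occasions identical (the long-half-life biomarker limit).
    """
    traits = [t for t in ("ohcholesterol", "ohcortisol") if t in latent.columns]
    if not traits:
        raise SimulationError("latent table lacks endogenous traits")
    rows = []
    for t in traits:
        cv = config.endogenous_occasion_cv.get(t, 0.0)
        if cv < 0:
            raise SimulationError("negative endogenous occasion CV")
        rho = float(config.endogenous_autocorr.get(t, 0.0))
        sigma = np.sqrt(np.log1p(cv ** 2))
        for _, row in latent.iterrows():
            z_subj = rng.standard_normal()
            for occ in range(1, config.n_occasions + 1):
                z = (np.sqrt(rho) * z_subj
                     + np.sqrt(1.0 - rho) * rng.standard_normal())
                value = float(np.exp(row[t] + sigma * z - 0.5 * sigma ** 2))
                rows.append({
                    "subject_id": row["subject_id"], "occasion": occ,
                    "trait": t, "value": value, "unit": TRAIT_UNITS.get(t, ""),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole study
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: StudyConfig
    subjects: pd.DataFrame
    latent: pd.DataFrame
    concentrations: pd.DataFrame
    endogenous: pd.DataFrame

    @property
    def truth(self) -> dict:
        """Generating parameters, for estimate-vs-truth reports."""
        spec = self.config.ace_spec
        tot = np.diag(spec.phenotypic)
        return {
            "traits": list(spec.traits),
            "A": spec.A.tolist(), "C": spec.C.tolist(), "E": spec.E.tolist(),
            "h2": (np.diag(spec.A) / tot).tolist(),
            "c2": (np.diag(spec.C) / tot).tolist(),
            "e2": (np.diag(spec.E) / tot).tolist(),
            "config": self.config.to_dict(),
        }


def simulate_study(config: StudyConfig, seed: int | None = None) -> SimulatedStudy:
    """Run every simulation stage with named substreams from one seed."""
    seed = config.seed if seed is None else seed
    rng_cohort, rng_latent, rng_pk, rng_endo = _substreams(seed, 4)
    cohort = generate_cohort(config, rng_cohort)
    latent = draw_latent_traits(cohort, config.ace_spec,
                                mean_coeffs_from_config(config), rng_latent)
    conc = simulate_concentrations(latent, config, rng_pk)
    endo = simulate_endogenous(latent, config, rng_endo)
    return SimulatedStudy(config, cohort, latent, conc, endo)
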