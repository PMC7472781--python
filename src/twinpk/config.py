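"""Study configuration for twin CYP3A phenotyping simulations.

The default :class:`StudyConfig` encodes the design of a repeated-dose
intravenous midazolam twin study: 43 monozygotic (MZ) and 14 same-sex
dizygotic (DZ) twin pairs, a 0.2 mg midazolam dose infused over 2 minutes,
15 blood samples over 24 h, and three phenotyping occasions per subject.
Four CYP3A activity biomarkers are simulated jointly: midazolam AUC,
1-OH-midazolam AUC, plasma 4ß-OH-cholesterol, and 24-h urinary
6ß-OH-cortisol.

Between-subject variation is generated from an ACE structure (additive
genetic A, common-environment C, unique-environment E) on the natural-log
trait scale; the default component matrices are assembled from published
univariate variance shares and cross-trait genetic/non-shared correlations
(see :func:`default_variance_spec`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

TRAITS: tuple[str, ...] = (
    "midazolam_auc",
    "ohmidazolam_auc",
    "ohcholesterol",
    "ohcortisol",
)

TRAIT_UNITS: dict[str, str] = {
    "midazolam_auc": "ug*min/L",
    "ohmidazolam_auc": "ug*min/L",
    "ohcholesterol": "ng/ml",
    "ohcortisol": "ug/24h",
}

#: Blood sampling schedule in minutes after start of infusion:
#: 0 (pre-dose), 0.25, 0.5, 0.75, 1, 1.5, 2, 2.5, 3, 4, 5, 6, 7, 8 and 24 h.
SAMPLING_TIMES_MIN: tuple[float, ...] = (
    0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0, 150.0,
    180.0, 240.0, 300.0, 360.0, 420.0, 480.0, 1440.0,
)


class ConfigError(ValueError):
    """Raised when a study configuration violates its invariants."""


def _as_matrix(m, p: int, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (p, p):
        raise ConfigError(f"{name} must be {p}x{p}, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ConfigError(f"{name} must be symmetric")
    return 0.5 * (m + m.T)


def nearest_psd(m: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the nearest positive semidefinite
    matrix by clipping negative eigenvalues at zero."""
    w, v = np.linalg.eigh(0.5 * (m + m.T))
    if w.min() >= 0:
        return 0.5 * (m + m.T)
    w = np.clip(w, 0.0, None)
    out = (v * w) @ v.T
    return 0.5 * (out + out.T)


@dataclass
class VarianceSpec:
    """A, C and E covariance matrices on the log-trait scale.

    Cross-twin trait covariance is ``A + C`` within MZ pairs and
    ``0.5*A + C`` within DZ pairs; the phenotypic covariance is
    ``A + C + E``.
    """

    A: np.ndarray
    C: np.ndarray
    E: np.ndarray
    traits: tuple[str, ...] = TRAITS

    def __post_init__(self) -> None:
        p = len(self.traits)
        self.A = _as_matrix(self.A, p, "A")
        self.C = _as_matrix(self.C, p, "C")
        self.E = _as_matrix(self.E, p, "E")
        for name in ("A", "C", "E"):
            m = getattr(self, name)
            if np.linalg.eigvalsh(m).min() < -1e-8:
                raise ConfigError(f"component matrix {name} is not positive semidefinite")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def phenotypic(self) -> np.ndarray:
        return self.A + self.C + self.E

    def subset(self, traits) -> "VarianceSpec":
        idx = [self.traits.index(t) for t in traits]
        ix = np.ix_(idx, idx)
        return VarianceSpec(self.A[ix], self.C[ix], self.E[ix], tuple(traits))

    @classmethod
    def from_proportions(cls, h2, c2, total_var=1.0, trait="trait") -> "VarianceSpec":
        """Single-trait spec from variance shares (h2 + c2 <= 1)."""
        e2 = 1.0 - h2 - c2
        if e2 < -1e-12:
            raise ConfigError("h2 + c2 must not exceed 1")
        t = float(total_var)
        return cls(
            A=np.array([[h2 * t]]),
            C=np.array([[c2 * t]]),
            E=np.array([[max(e2, 0.0) * t]]),
            traits=(trait,),
        )


# Univariate ACE variance shares (h2, c2, e2) per trait and total
# between-subject log-scale variances.  Totals derive from the observed
# between-subject coefficients of variation of the four biomarkers
# (CV^2 = Var_b / mean^2; log-variance = ln(1 + CV^2)).
ACE_SHARES: dict[str, tuple[float, float, float]] = {
    "midazolam_auc": (0.15, 0.48, 0.37),
    "ohmidazolam_auc": (0.73, 0.21, 0.06),
    "ohcholesterol": (0.56, 0.22, 0.22),
    "ohcortisol": (0.31, 0.36, 0.33),
}

LOG_TOTAL_VAR: dict[str, float] = {
    "midazolam_auc": 0.051,   # Var_b 11233, mean 464
    "ohmidazolam_auc": 0.313, # Var_b 2726, mean 86.2
    "ohcholesterol": 0.121,   # Var_b 86.5, mean 25.9
    "ohcortisol": 0.152,      # Var_b 8141, mean 222
}

# Cross-trait correlations (upper triangles, trait order as TRAITS):
# genetic (r_g), non-shared environmental (r_e) and phenotypic (r_ph).
_R_G = [[1.0, 0.37, -0.18, -0.42],
        [0.37, 1.0, 0.04, -0.15],
        [-0.18, 0.04, 1.0, 0.11],
        [-0.42, -0.15, 0.11, 1.0]]
_R_E = [[1.0, 0.54, -0.43, -0.38],
        [0.54, 1.0, -0.23, -0.07],
        [-0.43, -0.23, 1.0, 0.69],
        [-0.38, -0.07, 0.69, 1.0]]
_R_PH = [[1.0, 0.37, -0.24, -0.41],
         [0.37, 1.0, 0.01, -0.13],
         [-0.24, 0.01, 1.0, 0.26],
         [-0.41, -0.13, 0.26, 1.0]]

#: Log-scale trait means: natural logs of the observed MZ medians
#: (450.3 ug*min/L, 66.88 ug*min/L, 24.56 ng/ml, 209.0 ug/24 h).
DEFAULT_TRAIT_MEANS: dict[str, float] = {
    "midazolam_auc": float(np.log(450.3)),
    "ohmidazolam_auc": float(np.log(66.88)),
    "ohcholesterol": float(np.log(24.56)),
    "ohcortisol": float(np.log(209.0)),
}


def default_variance_spec() -> VarianceSpec:
    """Default 4-trait A, C, E matrices on the log scale.

    Diagonals come from the univariate variance shares scaled by the
    total log-variances; A and E off-diagonals from the genetic and
    non-shared correlations; C off-diagonals are set so that
    A + C + E reproduces the phenotypic correlations.  Each matrix is
    projected to the nearest PSD matrix (eigenvalue clipping at zero).
    """
    p = len(TRAITS)
    shares = np.array([ACE_SHARES[t] for t in TRAITS])
    tot = np.array([LOG_TOTAL_VAR[t] for t in TRAITS])
    a2, c2, e2 = shares[:, 0] * tot, shares[:, 1] * tot, shares[:, 2] * tot
    rg, re_, rph = np.array(_R_G), np.array(_R_E), np.array(_R_PH)
    A = rg * np.sqrt(np.outer(a2, a2))
    E = re_ * np.sqrt(np.outer(e2, e2))
    P = rph * np.sqrt(np.outer(tot, tot))
    C = P - A - E
    np.fill_diagonal(C, c2)
    A, C, E = nearest_psd(A), nearest_psd(C), nearest_psd(E)
    return VarianceSpec(A=A, C=C, E=E, traits=TRAITS)


@dataclass
class CovariateDistributions:
    """Ranges/proportions for the demographic covariates.

    Ages are shared within a twin pair, as is sex (all pairs are
    same-sex, matching the DZ recruitment criterion and MZ biology).
    """

    age_range: tuple[float, float] = (18.0, 40.0)
    prop_female: float = 0.64
    height_mean_by_sex: tuple[float, float] = (1.76, 1.67)  # (male, female), m
    height_sd: float = 0.06
    bmi_mean: float = 22.5
    bmi_sd: float = 2.5
    weight_range: tuple[float, float] = (45.0, 100.0)
    prop_smoker_pairs: float = 0.2
    prop_contraceptive: float = 0.4  # among women


@dataclass
class GenotypeFrequencies:
    """Variant-allele frequencies (CYP3A4*22 and active CYP3A5*1)."""

    cyp3a4_22: float = 0.018
    cyp3a5_1: float = 0.07


@dataclass
class MetaboliteParams:
    """Parent-to-metabolite kinetics for 1-OH-midazolam.

    ``formation_fraction`` is the fraction of the midazolam dose converted
    to the metabolite (about three quarters of elimination proceeds via
    1-hydroxylation); ``half_life_min`` is the metabolite's nominal
    elimination half-life.
    """

    formation_fraction: float = 0.75
    half_life_min: float = 60.0


@dataclass
class StudyConfig:
    """Full specification of a simulated twin phenotyping study."""

    n_mz_pairs: int = 43
    n_dz_pairs: int = 14
    dose_ug: float = 200.0
    infusion_duration_min: float = 2.0
    sampling_times_min: tuple[float, ...] = SAMPLING_TIMES_MIN
    n_occasions: int = 3
    parent_half_life_min: float = 163.0
    occasion_cv: float = 0.113
    metabolite_occasion_cv: float = 0.123
    assay_cv: float = 0.05
    # occasion-to-occasion CVs of the endogenous biomarkers and the share
    # of that variation carried by a subject-constant component (high for
    # 4ß-OH-cholesterol would reflect its long elimination half-life)
    endogenous_occasion_cv: dict = field(
        default_factory=lambda: {"ohcholesterol": 0.146, "ohcortisol": 0.294})
    endogenous_autocorr: dict = field(
        default_factory=lambda: {"ohcholesterol": 0.0, "ohcortisol": 0.0})
    trait_means: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    age_coeffs: dict = field(default_factory=lambda: {t: 0.0 for t in TRAITS})
    sex_coeffs: dict = field(default_factory=lambda: {t: 0.0 for t in TRAITS})
    # per-variant-allele additive effects on the log trait scale
    genotype_effects: dict = field(default_factory=lambda: {
        "midazolam_auc": {"cyp3a4_22": float(np.log(595.1 / 439.1))},
        "ohcholesterol": {"cyp3a5_1": float(np.log(30.69 / 23.01))},
    })
    ace_spec: VarianceSpec = field(default_factory=default_variance_spec)
    covariate_distributions: CovariateDistributions = field(
        default_factory=CovariateDistributions)
    genotype_frequencies: GenotypeFrequencies = field(
        default_factory=GenotypeFrequencies)
    metabolite_params: MetaboliteParams = field(default_factory=MetaboliteParams)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0:
            raise ConfigError("pair counts must be non-negative")
        if self.n_mz_pairs + self.n_dz_pairs == 0:
            raise ConfigError("empty cohort")
        if self.dose_ug <= 0:
            raise ConfigError("dose must be positive")
        t = np.asarray(self.sampling_times_min, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ConfigError("sampling times must start at 0 and strictly increase")
        if self.occasion_cv < 0 or self.assay_cv < 0 or self.metabolite_occasion_cv < 0:
            raise ConfigError("coefficients of variation must be non-negative")
        for cv in self.endogenous_occasion_cv.values():
            if cv < 0:
                raise ConfigError("negative endogenous occasion CV")
        gf = self.genotype_frequencies
        for name, q in (("cyp3a4_22", gf.cyp3a4_22), ("cyp3a5_1", gf.cyp3a5_1)):
            if not 0.0 <= q <= 1.0:
                raise ConfigError(f"allele frequency {name} outside [0, 1]")
        fm = self.metabolite_params.formation_fraction
        if not 0.0 < fm <= 1.0:
            raise ConfigError("formation fraction must be in (0, 1]")
        if self.n_occasions < 1:
            raise ConfigError("need at least one occasion")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ace_spec"] = {
            "A": self.ace_spec.A.tolist(),
            "C": self.ace_spec.C.tolist(),
            "E": self.ace_spec.E.tolist(),
            "traits": list(self.ace_spec.traits),
        }
        d["sampling_times_min"] = list(self.sampling_times_min)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "ace_spec" in d and isinstance(d["ace_spec"], dict):
            s = d["ace_spec"]
            d["ace_spec"] = VarianceSpec(
                np.array(s["A"]), np.array(s["C"]), np.array(s["E"]),
                tuple(s.get("traits", TRAITS)))
        for key, klass in (("covariate_distributions", CovariateDistributions),
                           ("genotype_frequencies", GenotypeFrequencies),
                           ("metabolite_params", MetaboliteParams)):
            if key in d and isinstance(d[key], dict):
                sub = d[key]
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                d[key] = klass(**sub)
        if "sampling_times_min" in d:
            d["sampling_times_min"] = tuple(d["sampling_times_min"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
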