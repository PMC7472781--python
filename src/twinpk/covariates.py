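"""Covariate and genotype association analyses for the CYP3A biomarkers.

Multiple linear regression of each (log) biomarker on demographic,
lifestyle and genotype factors with pair-clustered robust inference
(twins are not independent observations), plus nonparametric genotype
contrasts of group medians and an exploratory ordinal trend test.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class CovariateError(ValueError):
    pass


#: Sex-specific lean-body-weight coefficients (Hume-type linear formula):
#: LBW [kg] = w * weight[kg] + h * height[cm] + const.
DEFAULT_LBW_COEFFICIENTS: dict[str, dict[str, float]] = {
    "M": {"weight": 0.32810, "height_cm": 0.33929, "const": -29.5336},
    "F": {"weight": 0.29569, "height_cm": 0.41813, "const": -43.2933},
}


def lean_body_weight(weight_kg, height_m, sex, coefficients: dict | None = None):
    """Lean body weight from total weight, height and sex.

    A sex-specific linear combination; the default coefficients give
    51.1 kg for a 70 kg, 1.70 m male.  Pass ``coefficients`` (same
    structure as :data:`DEFAULT_LBW_COEFFICIENTS`) to override.
    Accepts scalars or aligned array-likes.
    """
    coeffs = coefficients if coefficients is not None else DEFAULT_LBW_COEFFICIENTS

    def one(w, h, s):
        if w <= 0 or h <= 0:
            raise CovariateError("weight and height must be positive")
        key = s.upper()[:1] if isinstance(s, str) else ("M" if s else "F")
        if key not in coeffs:
            raise CovariateError(f"unknown sex code {s!r}")
        c = coeffs[key]
        return c["weight"] * w + c["height_cm"] * h * 100.0 + c["const"]

    if np.isscalar(weight_kg) or isinstance(weight_kg, (int, float)):
        return one(float(weight_kg), float(height_m), sex)
    return np.array([one(float(w), float(h), s)
                     for w, h, s in zip(weight_kg, height_m, sex)])


@dataclass
class CovariateResult:
    trait: str
    factor: str
    coefficient: float
    partial_r2: float
    p_value: float
    overall_r2: float
    n: int


DEFAULT_FACTORS = ("sex", "age", "lean_body_weight", "smoker",
                   "contraceptive", "cyp3a4_22", "cyp3a5_1")


def covariate_regression(table: pd.DataFrame, trait: str,
                         factors: tuple[str, ...] = DEFAULT_FACTORS,
                         log_scale: bool = False,
                         cluster_by_pair: bool = True) -> pd.DataFrame:
    """Joint multiple regression of one trait on all factors.

    Returns one row per factor (plus an ``(all)`` row carrying the
    overall R-squared and model F-test p-value).  ``partial_r2`` is the
    squared semi-partial correlation: the drop in R-squared when the
    factor is removed from the full model.  With ``cluster_by_pair``
    (default) p-values use cluster-robust covariance grouped by twin
    pair; set ``log_scale`` to analyze the natural log of the trait.
    Collinear factors are dropped with a printed warning.
    """
    df = table.dropna(subset=[trait]).copy()
    y = df[trait].astype(float).to_numpy()
    if log_scale:
        if (y <= 0).any():
            raise CovariateError("log scale requested but trait has non-positive values")
        y = np.log(y)
    if "lean_body_weight" in factors and "lean_body_weight" not in df.columns:
        df["lean_body_weight"] = lean_body_weight(df["weight"], df["height"], df["sex"])
    cols = {}
    for f in factors:
        v = df[f]
        if f == "sex":
            v = v.map(lambda s: 1.0 if str(s).upper().startswith("M") else 0.0)
        cols[f] = v.astype(float).to_numpy()
    X = pd.DataFrame(cols)
    # drop collinear columns
    keep = []
    for f in X.columns:
        trial = X[keep + [f]].to_numpy()
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), trial])) == len(keep) + 2:
            keep.append(f)
        else:
            print(f"covariate_regression: dropping collinear factor {f!r}")
    X = X[keep]
    if len(df) <= len(keep) + 2:
        raise CovariateError("too few observations for the number of factors")
    exog = sm.add_constant(X)
    if cluster_by_pair:
        fit = sm.OLS(y, exog).fit(cov_type="cluster",
                                  cov_kwds={"groups": df["pair_id"].to_numpy()})
    else:
        fit = sm.OLS(y, exog).fit()
    overall_r2 = float(fit.rsquared)
    rows = [asdict(CovariateResult(
        trait=trait, factor="(all)", coefficient=np.nan,
        partial_r2=np.nan, p_value=float(fit.f_pvalue),
        overall_r2=overall_r2, n=int(fit.nobs)))]
    for f in keep:
        reduced = sm.OLS(y, sm.add_constant(X.drop(columns=f))).fit()
        rows.append(asdict(CovariateResult(
            trait=trait, factor=f, coefficient=float(fit.params[f]),
            partial_r2=max(overall_r2 - float(reduced.rsquared), 0.0),
            p_value=float(fit.pvalues[f]), overall_r2=overall_r2,
            n=int(fit.nobs))))
    return pd.DataFrame(rows)


@dataclass
class GenotypeContrast:
    trait: str
    locus: str
    group0: str
    group1: str
    n0: int
    n1: int
    median0: float
    median1: float
    percent_difference: float
    p_value: float


def genotype_contrast(values: pd.DataFrame, trait: str, locus: str,
                      carrier_def=lambda copies: copies > 0,
                      group_labels: tuple[str, str] = ("non-carrier", "carrier")
                      ) -> GenotypeContrast:
    """Median contrast between genotype groups with a rank-based test.

    ``percent_difference = 100 * (median1 - median0) / median0`` where
    group 1 contains carriers per ``carrier_def`` applied to the
    variant-allele copy number in column ``locus``.
    """
    df = values.dropna(subset=[trait, locus])
    is_carrier = carrier_def(df[locus])
    g0 = df.loc[~is_carrier, trait].to_numpy()
    g1 = df.loc[is_carrier, trait].to_numpy()
    for arr, label in ((g0, group_labels[0]), (g1, group_labels[1])):
        if len(arr) == 0:
            raise CovariateError(f"empty genotype group: {label}")
    m0, m1 = float(np.median(g0)), float(np.median(g1))
    if len(g0) and len(g1):
        p = float(stats.mannwhitneyu(g0, g1, alternative="two-sided").pvalue)
    else:
        p = np.nan
    return GenotypeContrast(
        trait=trait, locus=locus, group0=group_labels[0], group1=group_labels[1],
        n0=len(g0), n1=len(g1), median0=m0, median1=m1,
        percent_difference=100.0 * (m1 - m0) / m0, p_value=p)


def percent_difference(median0: float, median1: float) -> float:
    """100 * (median1 - median0) / median0."""
    if median0 == 0:
        raise CovariateError("reference median is zero")
    return 100.0 * (median1 - median0) / median0


def ordinal_trend_test(values: pd.DataFrame, trait: str, category_col: str,
                       category_order: list | None = None) -> dict:
    """Exploratory ordinal trend (Spearman) of a trait across ordered
    categories such as food-frequency classes."""
    df = values.dropna(subset=[trait, category_col])
    if category_order is not None:
        codes = df[category_col].map({c: i for i, c in enumerate(category_order)})
        if codes.isna().any():
            raise CovariateError("category outside the declared order")
    else:
        codes = df[category_col].astype(float)
    rho, p = stats.spearmanr(codes, df[trait])
    medians = df.groupby(category_col)[trait].median()
    return {"rho": float(rho), "p_value": float(p),
            "medians": medians.to_dict(), "n": len(df)}
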