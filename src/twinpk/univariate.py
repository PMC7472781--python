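"""Univariate twin models by maximum likelihood.

Each twin pair contributes a bivariate normal observation.  The mean is
a linear function of covariates (age, sex by default), identical for MZ
and DZ twins.  Two covariance structures are supported:

* **unstructured** — common variance across zygosities with separate
  within-pair correlations ``r_mz`` and ``r_dz``;
* **ACE / AE / CE** — biometric variance decomposition where the
  within-pair covariance is ``a2 + c2`` for MZ and ``a2/2 + c2`` for DZ
  pairs and the total variance is ``a2 + c2 + e2``.  AE fixes ``c2 = 0``
  and CE fixes ``a2 = 0``.

Components are parameterized as squares, so estimates are non-negative;
estimates at the zero boundary are flagged.  Standard errors come from
the observed information with the delta method for derived proportions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools.numdiff import approx_hess

_LOG2PI = float(np.log(2.0 * np.pi))

MODELS = ("ACE", "AE", "CE")


class TwinModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

@dataclass
class PairData:
    """Complete twin pairs ready for likelihood evaluation."""

    y: np.ndarray          # (n_pairs, 2)
    X: np.ndarray          # (n_pairs, 2, k) design incl. intercept
    is_mz: np.ndarray      # (n_pairs,) bool
    pair_ids: np.ndarray
    trait: str
    covariate_names: tuple[str, ...]
    n_dropped: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.y)

    @property
    def n_obs(self) -> int:
        return 2 * len(self.y)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(self.y.tobytes())
        h.update(self.X.tobytes())
        h.update(self.trait.encode())
        return h.hexdigest()[:16]


def _sex_to_male(s) -> float:
    if isinstance(s, str):
        if s.upper() in ("M", "MALE"):
            return 1.0
        if s.upper() in ("F", "FEMALE"):
            return 0.0
        raise TwinModelError(f"unknown sex code {s!r}")
    return float(s)


def twin_pairs(trait_table: pd.DataFrame, trait: str,
               covariates: tuple[str, ...] = ("age", "sex"),
               log_scale: bool = True) -> PairData:
    """Assemble complete pairs for one trait from a subject-level table.

    Requires columns ``subject_id, pair_id, zygosity`` plus the trait and
    covariates.  Pairs with a missing co-twin or missing trait value are
    dropped (count recorded).  Covariates are centered; sex is coded
    male = 1.  The trait is natural-log transformed by default.
    """
    df = trait_table.copy()
    if trait not in df.columns:
        raise TwinModelError(f"trait {trait!r} not in table")
    df = df.dropna(subset=[trait])
    if log_scale:
        if (df[trait] <= 0).any():
            raise TwinModelError("log scale requested but trait has non-positive values")
        df[trait] = np.log(df[trait])
    cov_cols = []
    for cv in covariates:
        col = df[cv].map(_sex_to_male) if cv == "sex" else df[cv].astype(float)
        cov_cols.append(np.asarray(col, dtype=float))
    cov = np.column_stack(cov_cols) if cov_cols else np.empty((len(df), 0))
    cov = cov - cov.mean(axis=0, keepdims=True)
    df = df.assign(**{f"_c{i}": cov[:, i] for i in range(cov.shape[1])})

    ys, Xs, mzs, pids = [], [], [], []
    n_dropped = 0
    for pid, grp in df.groupby("pair_id", sort=False):
        if len(grp) != 2:
            n_dropped += 1
            continue
        ys.append(grp[trait].to_numpy())
        Xs.append(np.column_stack(
            [np.ones(2)] + [grp[f"_c{i}"].to_numpy() for i in range(cov.shape[1])]))
        mzs.append(grp["zygosity"].iloc[0] == "MZ")
        pids.append(pid)
    if not ys:
        raise TwinModelError("no complete pairs")
    return PairData(
        y=np.asarray(ys), X=np.asarray(Xs), is_mz=np.asarray(mzs, dtype=bool),
        pair_ids=np.asarray(pids), trait=trait,
        covariate_names=("intercept",) + tuple(covariates), n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

@dataclass
class UnivariateFit:
    model: str
    trait: str
    beta: np.ndarray
    beta_names: tuple[str, ...]
    a2: float
    c2: float
    e2: float
    h2: float
    c2_prop: float
    e2_prop: float
    loglik: float
    n_params: int
    n_pairs: int
    n_obs: int
    converged: bool
    se: dict = field(default_factory=dict)
    r_mz: float | None = None
    r_dz: float | None = None
    boundary: tuple[str, ...] = ()
    data_fingerprint: str = ""

    @property
    def aic(self) -> float:
        return aic(self.loglik, self.n_params)

    @property
    def bic(self) -> float:
        return bic(self.loglik, self.n_params, self.n_obs)

    def summary(self) -> str:
        lines = [f"{self.model} fit of {self.trait}  "
                 f"(n_pairs={self.n_pairs}, LL={self.loglik:.2f}, df={self.n_params})"]
        if self.model == "unstructured":
            lines.append(f"  r_mz = {self.r_mz:.3f}  r_dz = {self.r_dz:.3f}")
        else:
            lines.append(
                f"  H2 = {self.h2:.3f}  C2 = {self.c2_prop:.3f}  E2 = {self.e2_prop:.3f}")
        if self.boundary:
            lines.append(f"  boundary estimates: {', '.join(self.boundary)}")
        return "\n".join(lines)


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion, -2*LL + 2*df."""
    return -2.0 * loglik + 2.0 * n_params


def bic(loglik: float, n_params: int, n_obs: int) -> float:
    """Bayesian information criterion, -2*LL + df*ln(N)."""
    return -2.0 * loglik + n_params * np.log(n_obs)


def falconer_estimates(r_mz: float, r_dz: float) -> tuple[float, float, float]:
    """Falconer moment estimates of the variance shares from twin
    correlations: a2 = 2(r_mz - r_dz), c2 = 2 r_dz - r_mz, e2 = 1 - r_mz.
    Useful as optimizer starting values; may fall outside [0, 1]."""
    a2 = 2.0 * (r_mz - r_dz)
    c2 = 2.0 * r_dz - r_mz
    return a2, c2, 1.0 - a2 - c2


def _pair_loglik(resid: np.ndarray, v: float, w: float) -> float:
    """Sum of bivariate normal log-densities with covariance [[v, w], [w, v]]."""
    det = v * v - w * w
    if det <= 0 or v <= 0:
        return -np.inf
    r1, r2 = resid[:, 0], resid[:, 1]
    quad = (v * (r1 ** 2 + r2 ** 2) - 2.0 * w * r1 * r2) / det
    return float(-0.5 * np.sum(2.0 * _LOG2PI + np.log(det) + quad))


def _residuals(data: PairData, beta: np.ndarray) -> np.ndarray:
    return data.y - data.X @ beta


def _falconer_start(data: PairData) -> tuple[np.ndarray, float, float, float]:
    """OLS mean + Falconer moment estimates as optimizer starting values."""
    Xf = data.X.reshape(-1, data.X.shape[2])
    yf = data.y.reshape(-1)
    beta, *_ = np.linalg.lstsq(Xf, yf, rcond=None)
    resid = _residuals(data, beta)
    tot = max(float(np.var(resid)), 1e-12)

    def _corr(mask):
        r = resid[mask]
        if len(r) < 2:
            return 0.0
        rr = np.concatenate([r, r[:, ::-1]])  # symmetrize twin order
        return float(np.corrcoef(rr[:, 0], rr[:, 1])[0, 1])

    r_mz, r_dz = _corr(data.is_mz), _corr(~data.is_mz)
    a2 = np.clip(2.0 * (r_mz - r_dz), 0.02, 0.95) * tot
    c2 = np.clip(2.0 * r_dz - r_mz, 0.02, 0.95) * tot
    e2 = max(tot - a2 - c2, 0.02 * tot)
    return beta, a2, c2, e2


def fit_variance_model(data: PairData | pd.DataFrame, trait: str | None = None,
                       covariates: tuple[str, ...] = ("age", "sex"),
                       model: str = "ACE", log_scale: bool = True,
                       compute_se: bool = True,
                       constrain: str = "nonneg") -> UnivariateFit:
    """ML fit of the ACE, AE or CE model for one trait.

    Accepts either a prepared :class:`PairData` or a subject-level trait
    table (with ``trait`` naming the column to analyze).

    ``constrain="nonneg"`` (default) parameterizes each component as a
    square, so estimates cannot go negative and small-sample estimates
    pile up at the zero boundary (flagged).  ``constrain="none"`` lets
    components go negative, as covariance-GLM estimators do; the
    resulting variance-share estimates are mean-unbiased in replicate
    studies, at the cost of occasionally inadmissible values.
    """
    if model not in MODELS:
        raise TwinModelError(f"model must be one of {MODELS}")
    if constrain not in ("nonneg", "none"):
        raise TwinModelError("constrain must be 'nonneg' or 'none'")
    if isinstance(data, pd.DataFrame):
        data = twin_pairs(data, trait, covariates, log_scale)
    k = data.X.shape[2]
    beta0, a2, c2, e2 = _falconer_start(data)
    comp0 = {"ACE": [a2, c2, e2], "AE": [a2 + c2, e2], "CE": [a2 + c2, e2]}[model]
    if constrain == "nonneg":
        theta0 = np.concatenate([beta0, np.sqrt(comp0)])
    else:
        theta0 = np.concatenate([beta0, comp0])
    mz, dz = data.is_mz, ~data.is_mz

    def unpack(theta):
        beta = theta[:k]
        s2 = theta[k:] ** 2 if constrain == "nonneg" else theta[k:]
        if model == "ACE":
            return beta, s2[0], s2[1], s2[2]
        if model == "AE":
            return beta, s2[0], 0.0, s2[1]
        return beta, 0.0, s2[0], s2[1]

    def negloglik(theta):
        beta, a, c, e = unpack(theta)
        resid = _residuals(data, beta)
        v = a + c + e
        ll = _pair_loglik(resid[mz], v, a + c) + _pair_loglik(resid[dz], v, 0.5 * a + c)
        return -ll if np.isfinite(ll) else 1e10

    res = optimize.minimize(negloglik, theta0, method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": 1e-13, "gtol": 1e-10})
    polish = optimize.minimize(negloglik, res.x, method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-12,
                                        "maxiter": 20000, "maxfev": 20000})
    if polish.fun <= res.fun:
        res = polish
    beta, a, c, e = unpack(res.x)
    tot = a + c + e
    n_params = k + {"ACE": 3, "AE": 2, "CE": 2}[model]
    free = [nm for nm, skip in (("a2", model == "CE"), ("c2", model == "AE"),
                                ("e2", False)) if not skip]
    vals = {"a2": a, "c2": c, "e2": e}
    if constrain == "nonneg":
        boundary = tuple(nm for nm in free if vals[nm] / tot < 1e-3)
    else:
        boundary = tuple(f"{nm}<0" for nm in free if vals[nm] < 0)
    fit = UnivariateFit(
        model=model, trait=data.trait, beta=beta, beta_names=data.covariate_names,
        a2=a, c2=c, e2=e, h2=a / tot, c2_prop=c / tot, e2_prop=e / tot,
        loglik=-res.fun, n_params=n_params, n_pairs=data.n_pairs, n_obs=data.n_obs,
        converged=bool(np.isfinite(res.fun)), boundary=boundary,
        data_fingerprint=data.fingerprint())
    if compute_se:
        fit.se = _variance_model_se(res.x, negloglik, k, model, constrain)
    return fit


def _variance_model_se(theta: np.ndarray, negloglik, k: int, model: str,
                       constrain: str = "nonneg") -> dict:
    """Observed-information SEs with the delta method for components and
    proportions.  Near-boundary or singular information yields NaN."""
    try:
        H = approx_hess(theta, negloglik)
        cov = np.linalg.pinv(H)
    except Exception:
        return {}
    se = {}
    for i in range(k):
        se[f"beta_{i}"] = float(np.sqrt(max(cov[i, i], 0.0)))
    s = theta[k:]
    m = len(s)
    comps = s ** 2 if constrain == "nonneg" else s
    comp_names = {"ACE": ["a2", "c2", "e2"], "AE": ["a2", "e2"], "CE": ["c2", "e2"]}[model]
    # jacobian d components / d raw params
    J = np.diag(2.0 * s) if constrain == "nonneg" else np.eye(m)
    for i, nm in enumerate(comp_names):
        g = np.zeros_like(theta)
        g[k:] = J[:, i]
        se[nm] = float(np.sqrt(max(g @ cov @ g, 0.0)))
    # proportions p_i = comps_i / sum_j comps_j
    tot = float(np.sum(comps))
    prop_names = {"ACE": ["h2", "c2_prop", "e2_prop"],
                  "AE": ["h2", "e2_prop"], "CE": ["c2_prop", "e2_prop"]}[model]
    for i, nm in enumerate(prop_names):
        dp = np.array([((1.0 if j == i else 0.0) * tot - comps[i]) / tot ** 2
                       for j in range(m)])
        g = np.zeros_like(theta)
        g[k:] = J @ dp
        se[nm] = float(np.sqrt(max(g @ cov @ g, 0.0)))
    return se


def fit_unstructured(data: PairData | pd.DataFrame, trait: str | None = None,
                     covariates: tuple[str, ...] = ("age", "sex"),
                     log_scale: bool = True, compute_se: bool = True) -> UnivariateFit:
    """ML fit with equal mean and variance across zygosities and free
    within-pair correlations r_mz and r_dz (Fisher-z parameterized)."""
    if isinstance(data, pd.DataFrame):
        data = twin_pairs(data, trait, covariates, log_scale)
    k = data.X.shape[2]
    mz, dz = data.is_mz, ~data.is_mz
    has_mz, has_dz = bool(mz.any()), bool(dz.any())
    beta0, a2, c2, e2 = _falconer_start(data)
    tot0 = a2 + c2 + e2
    theta0 = np.concatenate([beta0, [np.log(tot0)],
                             [0.5] if has_mz else [], [0.3] if has_dz else []])

    def unpack(theta):
        beta = theta[:k]
        v = np.exp(theta[k])
        i = k + 1
        r_mz = r_dz = None
        if has_mz:
            r_mz = np.tanh(theta[i]); i += 1
        if has_dz:
            r_dz = np.tanh(theta[i])
        return beta, v, r_mz, r_dz

    def negloglik(theta):
        beta, v, r_mz, r_dz = unpack(theta)
        resid = _residuals(data, beta)
        ll = 0.0
        if has_mz:
            ll += _pair_loglik(resid[mz], v, r_mz * v)
        if has_dz:
            ll += _pair_loglik(resid[dz], v, r_dz * v)
        return -ll if np.isfinite(ll) else 1e10

    res = optimize.minimize(negloglik, theta0, method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": 1e-13, "gtol": 1e-10})
    polish = optimize.minimize(negloglik, res.x, method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-12,
                                        "maxiter": 20000, "maxfev": 20000})
    if polish.fun <= res.fun:
        res = polish
    beta, v, r_mz, r_dz = unpack(res.x)
    n_params = k + 1 + int(has_mz) + int(has_dz)
    fit = UnivariateFit(
        model="unstructured", trait=data.trait, beta=beta,
        beta_names=data.covariate_names, a2=np.nan, c2=np.nan, e2=np.nan,
        h2=np.nan, c2_prop=np.nan, e2_prop=np.nan, loglik=-res.fun,
        n_params=n_params, n_pairs=data.n_pairs, n_obs=data.n_obs,
        converged=bool(np.isfinite(res.fun)), r_mz=r_mz, r_dz=r_dz,
        data_fingerprint=data.fingerprint())
    if compute_se:
        try:
            H = approx_hess(res.x, negloglik)
            cov = np.linalg.pinv(H)
            i = k + 1
            if has_mz:
                fit.se["r_mz"] = float(np.sqrt(max(cov[i, i], 0.0)) * (1 - r_mz ** 2))
                i += 1
            if has_dz:
                fit.se["r_dz"] = float(np.sqrt(max(cov[i, i], 0.0)) * (1 - r_dz ** 2))
        except Exception:
            pass
    return fit


def model_comparison(fits: list[UnivariateFit]) -> pd.DataFrame:
    """AIC/BIC comparison table for fits of the same data.

    Raises if the fits were produced from different underlying pair data.
    """
    if len(fits) < 2:
        raise TwinModelError("need at least 2 fits to compare")
    fps = {f.data_fingerprint for f in fits}
    if len(fps) > 1:
        raise TwinModelError("fits are not on the same data")
    rows = []
    for f in fits:
        rows.append({"model": f.model, "loglik": f.loglik, "df": f.n_params,
                     "n_obs": f.n_obs, "AIC": f.aic, "BIC": f.bic})
    df = pd.DataFrame(rows)
    df["best_aic"] = df["AIC"] == df["AIC"].min()
    df["best_bic"] = df["BIC"] == df["BIC"].min()
    return df


def pair_bootstrap(trait_table: pd.DataFrame, trait: str, model: str = "ACE",
                   covariates: tuple[str, ...] = ("age", "sex"),
                   log_scale: bool = True, n_boot: int = 200,
                   seed: int = 0) -> pd.DataFrame:
    """Zygosity-stratified pair-resampling bootstrap of the variance model;
    useful for SEs when components sit near the zero boundary."""
    rng = np.random.default_rng(seed)
    pairs = trait_table.groupby("pair_id")
    mz_ids = [p for p, g in pairs if g["zygosity"].iloc[0] == "MZ"]
    dz_ids = [p for p, g in pairs if g["zygosity"].iloc[0] == "DZ"]
    groups = {p: g for p, g in pairs}
    rows = []
    for b in range(n_boot):
        pick = list(rng.choice(mz_ids, len(mz_ids))) + list(rng.choice(dz_ids, len(dz_ids)))
        frames = []
        for i, p in enumerate(pick):
            g = groups[p].copy()
            g["pair_id"] = f"bs{i}"
            frames.append(g)
        fit = fit_variance_model(pd.concat(frames, ignore_index=True), trait,
                                 covariates, model, log_scale, compute_se=False)
        rows.append({"replicate": b, "h2": fit.h2, "c2_prop": fit.c2_prop,
                     "e2_prop": fit.e2_prop})
    return pd.DataFrame(rows)
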