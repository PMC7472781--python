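"""Multivariate ACE/AE/CE twin models and correlation decomposition.

Each pair contributes a 2p-dimensional normal observation (p traits per
twin).  The within-twin covariance block is ``P = A + C + E`` and the
cross-twin block ``A + C`` (MZ) or ``0.5*A + C`` (DZ).  A, C and E are
parameterized by Cholesky factors, which keeps them positive
semidefinite throughout optimization.

The fitted component matrices decompose the phenotypic correlation into
genetic (``r_g``), non-shared environmental (``r_e``) and shared
environmental channels; the bivariate heritability ``A_jk / P_jk`` is
the fraction of a phenotypic covariance attributable to additive
genetics (unbounded when the covariance is small).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .univariate import TwinModelError, _sex_to_male, MODELS

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class MultivariatePairData:
    y: np.ndarray            # (n_pairs, 2, p)
    X: np.ndarray            # (n_pairs, 2, k)
    is_mz: np.ndarray
    pair_ids: np.ndarray
    traits: tuple[str, ...]
    covariate_names: tuple[str, ...]
    n_dropped_subjects: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.y)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(self.y.tobytes())
        h.update("|".join(self.traits).encode())
        return h.hexdigest()[:16]


def multivariate_pairs(trait_table: pd.DataFrame, traits,
                       covariates: tuple[str, ...] = ("age", "sex"),
                       log_scale: bool = True) -> MultivariatePairData:
    """Complete pairs with complete trait vectors (row-wise deletion,
    dropped-subject count recorded)."""
    traits = tuple(traits)
    if len(traits) < 1:
        raise TwinModelError("need at least one trait")
    df = trait_table.copy()
    n_before = len(df)
    df = df.dropna(subset=list(traits))
    n_dropped = n_before - len(df)
    if log_scale:
        for t in traits:
            if (df[t] <= 0).any():
                raise TwinModelError(f"log scale requested but {t} has non-positive values")
            df[t] = np.log(df[t])
    cov_cols = []
    for cv in covariates:
        col = df[cv].map(_sex_to_male) if cv == "sex" else df[cv].astype(float)
        cov_cols.append(np.asarray(col, dtype=float))
    cov = np.column_stack(cov_cols) if cov_cols else np.empty((len(df), 0))
    cov = cov - cov.mean(axis=0, keepdims=True)
    df = df.assign(**{f"_c{i}": cov[:, i] for i in range(cov.shape[1])})
    ys, Xs, mzs, pids = [], [], [], []
    for pid, grp in df.groupby("pair_id", sort=False):
        if len(grp) != 2:
            n_dropped += len(grp)
            continue
        ys.append(grp[list(traits)].to_numpy())
        Xs.append(np.column_stack(
            [np.ones(2)] + [grp[f"_c{i}"].to_numpy() for i in range(cov.shape[1])]))
        mzs.append(grp["zygosity"].iloc[0] == "MZ")
        pids.append(pid)
    if not ys:
        raise TwinModelError("no complete pairs")
    return MultivariatePairData(
        y=np.asarray(ys), X=np.asarray(Xs), is_mz=np.asarray(mzs, dtype=bool),
        pair_ids=np.asarray(pids), traits=traits,
        covariate_names=("intercept",) + tuple(covariates),
        n_dropped_subjects=n_dropped)


@dataclass
class MultivariateFit:
    model: str
    traits: tuple[str, ...]
    beta: np.ndarray            # (p, k)
    beta_names: tuple[str, ...]
    A: np.ndarray
    C: np.ndarray
    E: np.ndarray
    loglik: float
    n_params: int
    n_pairs: int
    n_obs: int
    converged: bool
    boundary_rank_deficient: tuple[str, ...] = ()
    data_fingerprint: str = ""

    @property
    def phenotypic(self) -> np.ndarray:
        return self.A + self.C + self.E

    @property
    def h2(self) -> np.ndarray:
        """Per-trait heritability from the matrix diagonals."""
        return np.diag(self.A) / np.diag(self.phenotypic)


def _vech_indices(p: int):
    return np.tril_indices(p)


def _build_lower(vals: np.ndarray, p: int) -> np.ndarray:
    L = np.zeros((p, p))
    L[_vech_indices(p)] = vals
    return L


def _chol_start(m: np.ndarray, p: int, floor: float) -> np.ndarray:
    """Cholesky factor of a PSD-projected moment estimate, with eigenvalues
    floored away from zero: a Cholesky factor of exactly zero is a
    stationary point of L @ L.T, so starts must sit in the interior."""
    w, v = np.linalg.eigh(0.5 * (m + m.T))
    w = np.clip(w, floor, None)
    m = (v * w) @ v.T
    return np.linalg.cholesky(0.5 * (m + m.T))


def _moment_components(data: MultivariatePairData):
    """DeFries-Fulker style moment estimates of A, C, E for starting values."""
    k = data.X.shape[2]
    p = len(data.traits)
    Xf = data.X.reshape(-1, k)
    beta = np.empty((p, k))
    resid = np.empty((data.n_pairs, 2, p))
    for j in range(p):
        yf = data.y[:, :, j].reshape(-1)
        b, *_ = np.linalg.lstsq(Xf, yf, rcond=None)
        beta[j] = b
        resid[:, :, j] = data.y[:, :, j] - data.X @ b

    def _cross_cov(mask):
        r = resid[mask]
        if mask.sum() < 2:
            return np.zeros((p, p))
        r1, r2 = r[:, 0, :], r[:, 1, :]
        both = np.concatenate([np.stack([r1, r2], 1), np.stack([r2, r1], 1)])
        c = np.einsum("ni,nj->ij", both[:, 0, :], both[:, 1, :]) / len(both)
        return 0.5 * (c + c.T)

    flat = resid.reshape(-1, p)
    S = np.cov(flat.T).reshape(p, p)
    cmz, cdz = _cross_cov(data.is_mz), _cross_cov(~data.is_mz)
    A0 = 2.0 * (cmz - cdz)
    C0 = 2.0 * cdz - cmz
    E0 = S - cmz
    return beta, A0, C0, E0, S


def fit_multivariate(data: MultivariatePairData | pd.DataFrame, traits=None,
                     covariates: tuple[str, ...] = ("age", "sex"),
                     model: str = "ACE", log_scale: bool = True,
                     rank_tol: float = 1e-8,
                     polish: bool | None = None) -> MultivariateFit:
    """ML fit of the multivariate ACE/AE/CE model.

    For small parameter spaces (p <= 2) the quasi-Newton solution is
    polished with a derivative-free pass so that the p = 1 case agrees
    with the univariate fit to optimizer precision.
    """
    if model not in MODELS:
        raise TwinModelError(f"model must be one of {MODELS}")
    if isinstance(data, pd.DataFrame):
        if traits is None:
            raise TwinModelError("traits required when passing a table")
        data = multivariate_pairs(data, traits, covariates, log_scale)
    p = len(data.traits)
    k = data.X.shape[2]
    nv = p * (p + 1) // 2
    n_mat = 3 if model == "ACE" else 2
    if p * k + n_mat * nv >= data.n_pairs * 2 * p:
        raise TwinModelError(
            f"{p * k + n_mat * nv} parameters cannot be supported by "
            f"{data.n_pairs * 2 * p} observations; reduce traits or model")
    tril = _vech_indices(p)

    beta0, A0, C0, E0, S = _moment_components(data)
    floor = 0.05 * float(np.trace(S)) / p
    mats0 = {"ACE": (A0, C0, E0), "AE": (A0 + np.clip(C0, 0, None), E0),
             "CE": (C0 + np.clip(A0, 0, None), E0)}[model]
    starts = [
        np.concatenate([beta0.reshape(-1)]
                       + [_chol_start(m, p, floor)[tril] for m in mats0]),
        # equal split of the phenotypic covariance across components
        np.concatenate([beta0.reshape(-1)]
                       + [_chol_start(S / n_mat, p, floor)[tril]] * n_mat),
    ]

    mz, dz = data.is_mz, ~data.is_mz

    def unpack(theta):
        beta = theta[:p * k].reshape(p, k)
        rest = theta[p * k:]
        Ls = [_build_lower(rest[i * nv:(i + 1) * nv], p) for i in range(n_mat)]
        mats = [L @ L.T for L in Ls]
        if model == "ACE":
            A, C, E = mats
        elif model == "AE":
            A, E = mats
            C = np.zeros((p, p))
        else:
            C, E = mats
            A = np.zeros((p, p))
        return beta, A, C, E, Ls

    def group_ll(resid2p, sigma):
        n = len(resid2p)
        if n == 0:
            return 0.0
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return -np.inf
        sol = np.linalg.solve(sigma, resid2p.T)
        quad = float(np.sum(resid2p.T * sol))
        return -0.5 * (n * (2 * p * _LOG2PI + logdet) + quad)

    def negloglik(theta):
        beta, A, C, E, _ = unpack(theta)
        P = A + C + E
        resid = data.y - np.einsum("nik,jk->nij", data.X, beta)
        r2p = resid.reshape(data.n_pairs, 2 * p)
        ll = 0.0
        for mask, W in ((mz, A + C), (dz, 0.5 * A + C)):
            sigma = np.block([[P, W], [W, P]])
            ll += group_ll(r2p[mask], sigma)
        return -ll if np.isfinite(ll) else 1e10

    res = None
    for theta0 in starts:
        cand = optimize.minimize(negloglik, theta0, method="L-BFGS-B",
                                 options={"maxiter": 5000, "maxfun": 200000,
                                          "ftol": 1e-13, "gtol": 1e-9})
        if res is None or cand.fun < res.fun:
            res = cand
    if polish is None:
        polish = p <= 2
    if polish:
        fine = optimize.minimize(negloglik, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-12,
                                          "maxiter": 50000, "maxfev": 50000})
        if fine.fun <= res.fun:
            res = fine
    beta, A, C, E, Ls = unpack(res.x)
    mat_names = {"ACE": ("A", "C", "E"), "AE": ("A", "E"), "CE": ("C", "E")}[model]
    scale = np.sqrt(np.diag(A + C + E))
    rank_def = tuple(nm for nm, L in zip(mat_names, Ls)
                     if np.any(np.abs(np.diag(L)) < rank_tol * max(scale.max(), 1e-12)))
    return MultivariateFit(
        model=model, traits=data.traits, beta=beta,
        beta_names=data.covariate_names, A=A, C=C, E=E, loglik=-res.fun,
        n_params=p * k + n_mat * nv, n_pairs=data.n_pairs,
        n_obs=2 * data.n_pairs * p, converged=bool(res.success or np.isfinite(res.fun)),
        boundary_rank_deficient=rank_def, data_fingerprint=data.fingerprint())


@dataclass
class CorrelationDecomposition:
    traits: tuple[str, ...]
    r_ph: np.ndarray
    r_g: np.ndarray
    r_e: np.ndarray
    bivariate_h2: np.ndarray
    unstable_bivariate: np.ndarray    # bool mask where P_jk ~ 0
    se: dict = field(default_factory=dict)

    def tidy(self) -> pd.DataFrame:
        rows = []
        p = len(self.traits)
        for j in range(p):
            for kk in range(j + 1, p):
                rows.append({
                    "trait_j": self.traits[j], "trait_k": self.traits[kk],
                    "r_ph": self.r_ph[j, kk], "r_g": self.r_g[j, kk],
                    "r_e": self.r_e[j, kk], "biv_h2": self.bivariate_h2[j, kk],
                    "biv_h2_unstable": bool(self.unstable_bivariate[j, kk]),
                })
        return pd.DataFrame(rows)


def _corr_from_cov(m: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(m))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = m / np.outer(d, d)
    r[np.outer(d, d) == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    return r


def correlation_decomposition(fit: MultivariateFit,
                              unstable_tol: float = 0.05) -> CorrelationDecomposition:
    """Genetic, non-shared and phenotypic correlations plus bivariate
    heritability from a fitted multivariate model.

    ``r_g(j,k) = A_jk / sqrt(A_jj A_kk)`` and analogously for ``r_e``;
    ``bivariate_h2(j,k) = A_jk / P_jk`` is flagged unstable when the
    phenotypic correlation magnitude falls below ``unstable_tol``.
    Entries whose defining diagonal is zero are NaN.
    """
    P = fit.phenotypic
    r_ph = _corr_from_cov(P)
    r_g = _corr_from_cov(fit.A)
    r_e = _corr_from_cov(fit.E)
    with np.errstate(divide="ignore", invalid="ignore"):
        biv = fit.A / P
    np.fill_diagonal(biv, np.diag(fit.A) / np.diag(P))
    unstable = np.abs(r_ph) < unstable_tol
    np.fill_diagonal(unstable, False)
    return CorrelationDecomposition(
        traits=fit.traits, r_ph=r_ph, r_g=r_g, r_e=r_e,
        bivariate_h2=biv, unstable_bivariate=unstable)


def bootstrap_decomposition(trait_table: pd.DataFrame, traits,
                            covariates: tuple[str, ...] = ("age", "sex"),
                            model: str = "ACE", log_scale: bool = True,
                            n_boot: int = 100, seed: int = 0) -> dict:
    """Pair-resampling bootstrap SEs for the correlation decomposition.

    Returns elementwise SE matrices keyed by quantity; refits the whole
    multivariate model per resample, so cost scales with ``n_boot``.
    """
    rng = np.random.default_rng(seed)
    pairs = trait_table.groupby("pair_id")
    mz_ids = [pid for pid, g in pairs if g["zygosity"].iloc[0] == "MZ"]
    dz_ids = [pid for pid, g in pairs if g["zygosity"].iloc[0] == "DZ"]
    groups = {pid: g for pid, g in pairs}
    acc = {"r_ph": [], "r_g": [], "r_e": [], "bivariate_h2": []}
    for _ in range(n_boot):
        pick = list(rng.choice(mz_ids, len(mz_ids))) + list(rng.choice(dz_ids, len(dz_ids)))
        frames = []
        for i, pid in enumerate(pick):
            g = groups[pid].copy()
            g["pair_id"] = f"bs{i}"
            frames.append(g)
        fit = fit_multivariate(pd.concat(frames, ignore_index=True), traits,
                               covariates, model, log_scale)
        dec = correlation_decomposition(fit)
        for key in acc:
            acc[key].append(getattr(dec, key))
    return {key: np.nanstd(np.stack(v), axis=0) for key, v in acc.items()}
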