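"""Non-compartmental pharmacokinetic analysis.

AUC by the linear-up/log-down trapezoidal rule, terminal slope
(lambda-z) by best-adjusted-R-squared log-linear regression over
candidate tails, extrapolation to infinity, and the derived parameters
clearance, half-life, Cmax/tmax and the metabolite/parent AUC ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd


class NCAError(ValueError):
    pass


@dataclass
class LambdaZFit:
    lambda_z: float          # 1/min
    n_points: int
    adj_r2: float
    intercept: float         # log-concentration intercept of the regression


@dataclass
class PKResult:
    subject_id: str | None
    occasion: int | None
    analyte: str | None
    auc_last: float
    auc_inf: float
    auc_420: float
    lambda_z: float
    lambda_z_n_points: int
    lambda_z_adj_r2: float
    t_half: float
    cl: float | None
    cl_per_kg: float | None
    cmax: float
    tmax: float
    metabolite_parent_auc_ratio: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _validate_profile(times, conc) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise NCAError("times and concentrations must be 1-d arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise NCAError("times must be strictly increasing")
    if np.any(c < 0):
        raise NCAError("negative concentration")
    return t, c


def estimate_lambda_z(times, conc, blq=None) -> LambdaZFit:
    """Terminal elimination rate constant by log-linear regression.

    All candidate tails of >= 3 positive samples strictly after Cmax
    (the Cmax sample itself excluded) are fitted; the tail with the best
    adjusted R-squared wins, ties broken toward more points.  Samples
    flagged below the limit of quantification are excluded.
    """
    t, c = _validate_profile(times, conc)
    usable = c > 0
    if blq is not None:
        usable &= ~np.asarray(blq, dtype=bool)
    i_cmax = int(np.argmax(c))
    usable &= np.arange(len(c)) > i_cmax
    idx = np.flatnonzero(usable)
    if len(idx) < 3:
        raise NCAError("lambda_z not estimable: fewer than 3 usable terminal points")
    logc = np.log(c[idx])
    tt = t[idx]
    best: tuple[float, int, float, float] | None = None  # adj_r2, n, slope, intercept
    for start in range(len(idx) - 2):
        x, y = tt[start:], logc[start:]
        n = len(x)
        slope, intercept = np.polyfit(x, y, 1)
        yhat = intercept + slope * x
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if np.ptp(y) <= 1e-10 * (1.0 + abs(float(y.mean()))):
            continue  # flat tail carries no slope information
        r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if slope >= 0:
            continue
        if best is None or adj > best[0] + 1e-9 or (abs(adj - best[0]) <= 1e-9 and n > best[1]):
            best = (adj, n, slope, intercept)
    if best is None:
        raise NCAError("no terminal decline")
    adj, n, slope, intercept = best
    return LambdaZFit(lambda_z=-slope, n_points=n, adj_r2=adj, intercept=intercept)


def _interp_conc(t0, c0, t1, c1, t):
    """Concentration at t in (t0, t1): log-down on declining positive
    segments, linear otherwise."""
    if c1 < c0 and c0 > 0 and c1 > 0:
        return c0 * (c1 / c0) ** ((t - t0) / (t1 - t0))
    return c0 + (c1 - c0) * (t - t0) / (t1 - t0)


def _segment_auc(t0, c0, t1, c1) -> float:
    dt = t1 - t0
    if c1 < c0 and c0 > 0 and c1 > 0:
        return dt * (c0 - c1) / np.log(c0 / c1)
    return dt * 0.5 * (c0 + c1)


def auc_trapezoid(times, conc, t_end=None, t_start=0.0) -> float:
    """Linear-up/log-down trapezoidal AUC from ``t_start`` to ``t_end``.

    Rising or flat segments use the linear rule; strictly declining
    segments with both endpoints positive use the logarithmic rule;
    segments touching zero fall back to linear.  Endpoints falling
    between samples are interpolated consistently with the segment rule.
    """
    t, c = _validate_profile(times, conc)
    if t_end is None:
        t_end = t[-1]
    if t_end > t[-1] + 1e-9:
        raise NCAError("t_end beyond last sampling time")
    if t_end < t[0]:
        raise NCAError("t_end before first sample")
    if t_start < t[0]:
        raise NCAError("t_start before first sample")
    # clip the grid to [t_start, t_end] with interpolated boundary points
    pts_t, pts_c = [], []
    for i in range(len(t)):
        if t_start <= t[i] <= t_end:
            pts_t.append(t[i]); pts_c.append(c[i])
    if not pts_t or pts_t[0] > t_start:
        j = int(np.searchsorted(t, t_start, side="right")) - 1
        ci = _interp_conc(t[j], c[j], t[j + 1], c[j + 1], t_start)
        pts_t.insert(0, t_start); pts_c.insert(0, ci)
    if pts_t[-1] < t_end:
        j = int(np.searchsorted(t, t_end, side="right")) - 1
        ci = _interp_conc(t[j], c[j], t[j + 1], c[j + 1], t_end)
        pts_t.append(t_end); pts_c.append(ci)
    total = 0.0
    for i in range(len(pts_t) - 1):
        total += _segment_auc(pts_t[i], pts_c[i], pts_t[i + 1], pts_c[i + 1])
    return float(total)


def with_infusion_anchor(times, conc, infusion_end_min: float):
    """Insert a virtual sample at the end of a zero-order infusion.

    Blood sampling schedules often skip the infusion-end peak (first
    draw at 15 min after a 2-min infusion), so the linear-up segment
    from 0 to the first sample clips the peak and biases AUC low.  The
    anchor concentration is log-linearly back-extrapolated from the
    first two positive samples when they decline (the post-infusion
    phase); otherwise the profile is returned unchanged.
    """
    t, c = _validate_profile(times, conc)
    if infusion_end_min <= t[0] or infusion_end_min >= t[-1]:
        return t, c
    if np.any((t > t[0]) & (t <= infusion_end_min)):
        return t, c  # schedule already covers the infusion
    pos = np.flatnonzero(c > 0)
    if len(pos) < 2:
        return t, c
    i, j = pos[0], pos[1]
    if not (c[j] < c[i]):
        return t, c
    k = np.log(c[i] / c[j]) / (t[j] - t[i])
    c_end = c[i] * np.exp(k * (t[i] - infusion_end_min))
    ins = int(np.searchsorted(t, infusion_end_min))
    return np.insert(t, ins, infusion_end_min), np.insert(c, ins, c_end)


def auc_infinity(times, conc, lz: LambdaZFit | None = None) -> float:
    """AUC extrapolated to infinity.

    ``AUC_last + C_hat(t_last)/lambda_z`` with the last concentration
    predicted from the lambda-z regression (less sensitive to assay
    noise in the final sample than the observed value).
    """
    t, c = _validate_profile(times, conc)
    if lz is None:
        lz = estimate_lambda_z(t, c)
    auc_last = auc_trapezoid(t, c)
    c_last_pred = float(np.exp(lz.intercept - lz.lambda_z * t[-1]))
    return auc_last + c_last_pred / lz.lambda_z


def pk_summary(parent_times, parent_conc, dose_ug: float,
               metabolite_times=None, metabolite_conc=None,
               weight_kg: float | None = None,
               subject_id=None, occasion=None,
               infusion_end_min: float | None = None) -> PKResult:
    """Full NCA parameter set for a parent (+ optional metabolite) profile.

    Cmax and tmax are read directly from the observed samples; clearance
    is dose over AUC_inf; the metabolite/parent ratio compares AUC_inf
    values and is absent when no metabolite profile is given.  When
    ``infusion_end_min`` is given the parent AUCs use a back-extrapolated
    infusion-end anchor (see :func:`with_infusion_anchor`); Cmax/tmax and
    lambda-z remain based on observed samples only.
    """
    if dose_ug <= 0:
        raise NCAError("dose must be positive")
    t, c = _validate_profile(parent_times, parent_conc)
    lz = estimate_lambda_z(t, c)
    ta, ca = (t, c) if infusion_end_min is None else with_infusion_anchor(t, c, infusion_end_min)
    auc_last = auc_trapezoid(ta, ca)
    aucinf = auc_infinity(ta, ca, lz)
    t420 = min(420.0, t[-1])
    auc420 = auc_trapezoid(ta, ca, t_end=t420)
    i_cmax = int(np.argmax(c))
    cl = dose_ug / aucinf  # ug / (ug*min/L) = L/min
    ratio = None
    if metabolite_conc is not None:
        mt, mc = _validate_profile(metabolite_times, metabolite_conc)
        ratio = auc_infinity(mt, mc) / aucinf
    return PKResult(
        subject_id=subject_id, occasion=occasion, analyte="midazolam",
        auc_last=auc_last, auc_inf=aucinf, auc_420=auc420,
        lambda_z=lz.lambda_z, lambda_z_n_points=lz.n_points,
        lambda_z_adj_r2=lz.adj_r2, t_half=np.log(2.0) / lz.lambda_z,
        cl=cl, cl_per_kg=None if weight_kg is None else cl * 1000.0 / weight_kg,
        cmax=float(c[i_cmax]), tmax=float(t[i_cmax]),
        metabolite_parent_auc_ratio=ratio,
    )


def nca_table(concentrations: pd.DataFrame, dose_ug: float,
              weights: pd.Series | dict | None = None,
              parent_analyte: str = "midazolam",
              metabolite_analyte: str = "1-OH-midazolam",
              infusion_end_min: float | None = 2.0) -> pd.DataFrame:
    """NCA for every subject x occasion x analyte in a long table.

    Expects columns ``subject_id, occasion, analyte, time_min,
    conc_ug_per_L`` (the simulator's output schema).  Returns one row
    per subject x occasion x analyte with the PKResult fields; profiles
    where lambda-z is not estimable are skipped with a ``note``.
    """
    rows = []
    for (sid, occ), grp in concentrations.groupby(["subject_id", "occasion"], sort=False):
        w = None
        if weights is not None:
            w = weights.get(sid) if hasattr(weights, "get") else weights[sid]
        profiles = {a: g.sort_values("time_min") for a, g in grp.groupby("analyte")}
        parent = profiles.get(parent_analyte)
        met = profiles.get(metabolite_analyte)
        for analyte, prof in profiles.items():
            t = prof["time_min"].to_numpy()
            c = prof["conc_ug_per_L"].to_numpy()
            try:
                if analyte == parent_analyte and met is not None:
                    res = pk_summary(t, c, dose_ug,
                                     met["time_min"].to_numpy(),
                                     met["conc_ug_per_L"].to_numpy(),
                                     weight_kg=w, subject_id=sid, occasion=occ,
                                     infusion_end_min=infusion_end_min)
                else:
                    anchor = infusion_end_min if analyte == parent_analyte else None
                    res = pk_summary(t, c, dose_ug, weight_kg=w,
                                     subject_id=sid, occasion=occ,
                                     infusion_end_min=anchor)
                    res.analyte = analyte
                    if analyte != parent_analyte:
                        # dose-based clearance is meaningful for the parent only
                        res.cl = None
                        res.cl_per_kg = None
                d = res.to_dict()
                d["analyte"] = analyte
                rows.append(d)
            except NCAError as exc:
                rows.append({"subject_id": sid, "occasion": occ,
                             "analyte": analyte, "note": str(exc)})
    return pd.DataFrame(rows)
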