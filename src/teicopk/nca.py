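"""Noncompartmental analysis of single-dose concentration–time profiles.

Estimators follow standard NCA conventions: Cmax/Tlast/Clast are read
directly from the observations; AUC and AUMC use the linear-up/log-down
trapezoidal rule; the terminal rate constant lambda_z comes from an
ordinary least-squares fit of ln(C) against time over the last 3–6
measurable concentrations; extrapolation to infinity and the derived
clearance/volume parameters use the usual closed forms:

    AUC_inf  = AUC_last  + Clast / lz
    AUMC_inf = AUMC_last + Tlast * Clast / lz + Clast / lz**2
    MRT_inf  = AUMC_inf / AUC_inf - infusion_time / 2
    CL       = dose / AUC_inf,  Vz = CL / lz,  Vss = MRT_inf * CL
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .model import LN2

__all__ = [
    "NCAResult",
    "LambdaZFit",
    "NCAError",
    "fit_lambda_z",
    "auc_linear_up_log_down",
    "extrapolate_and_derive",
    "run_nca",
    "summarize_nca",
]


class NCAError(ValueError):
    """Raised when an NCA estimator cannot be computed for a profile."""


@dataclass(frozen=True)
class LambdaZFit:
    lambda_z: float  # 1/h
    intercept: float  # ln(mg/L) at t=0 of the terminal line
    n_points: int
    r2_adj: float


@dataclass(frozen=True)
class NCAResult:
    """All NCA exposure parameters for one subject/profile."""

    cmax: float  # mg/L
    tlast: float  # h
    clast: float  # mg/L
    auc_last: float  # mg·h/L
    auc_inf: float
    aumc_last: float  # mg·h²/L
    aumc_inf: float
    mrt_inf: float  # h
    cl_nca: float  # L/h
    vz: float  # L
    vss: float  # L
    t_half_lambda_z: float  # h
    lambda_z: float  # 1/h
    n_lambda_points: int

    def per_kg(self, weight: float) -> dict[str, float]:
        """Weight-normalized clearance and volumes (L/h/kg, L/kg)."""
        if weight <= 0:
            raise ValueError("weight must be positive")
        return {
            "cl_nca_per_kg": self.cl_nca / weight,
            "vz_per_kg": self.vz / weight,
            "vss_per_kg": self.vss / weight,
        }


def fit_lambda_z(
    times: np.ndarray,
    conc: np.ndarray,
    n_points: int = 4,
    auto: bool = False,
) -> LambdaZFit:
    """Terminal-slope fit: OLS of ln(C) vs t over the last measurable points.

    ``n_points`` (3–6) fixes the window counted back from the last positive
    concentration. With ``auto=True`` the window in 3..6 maximizing adjusted
    R² is chosen instead (off by default).
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if not 3 <= n_points <= 6:
        raise NCAError("terminal fit requires between 3 and 6 points")
    pos = conc > 0
    t_pos, c_pos = times[pos], conc[pos]
    if auto:
        candidates = [n for n in range(3, 7) if n <= t_pos.size]
        if not candidates:
            raise NCAError("fewer than 3 positive concentrations for terminal fit")
        fits = [_ols_terminal(t_pos, c_pos, n) for n in candidates]
        fits = [f for f in fits if f is not None]
        if not fits:
            raise NCAError("no terminal window with a negative slope")
        return max(fits, key=lambda f: f.r2_adj)
    if t_pos.size < n_points:
        raise NCAError(
            f"need {n_points} positive terminal concentrations, have {t_pos.size}"
        )
    fit = _ols_terminal(t_pos, c_pos, n_points)
    if fit is None:
        raise NCAError("terminal slope is non-negative; lambda_z undefined")
    return fit


def _ols_terminal(t: np.ndarray, c: np.ndarray, n: int) -> LambdaZFit | None:
    tt, yy = t[-n:], np.log(c[-n:])
    slope, intercept = np.polyfit(tt, yy, 1)
    if slope >= 0:
        return None
    resid = yy - (slope * tt + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((yy - yy.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return LambdaZFit(
        lambda_z=float(-slope), intercept=float(intercept), n_points=n, r2_adj=r2_adj
    )


def auc_linear_up_log_down(
    times: np.ndarray,
    conc: np.ndarray,
    t_end: float | None = None,
) -> tuple[float, float]:
    """(AUC, AUMC) over [t0, t_end] by the linear-up/log-down trapezoid rule.

    Rising or flat segments (and any segment touching zero) use the linear
    trapezoid; strictly falling positive segments use the logarithmic
    trapezoid. ``t_end`` must coincide with an observation time (default:
    the last time).
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if np.any(np.diff(times) < 0):
        raise NCAError("profile times must be sorted")
    if t_end is None:
        t_end = float(times[-1])
    mask = times <= t_end + 1e-12
    t, c = times[mask], conc[mask]
    if t.size < 2:
        return 0.0, 0.0
    auc = aumc = 0.0
    for (t1, c1), (t2, c2) in zip(zip(t[:-1], c[:-1]), zip(t[1:], c[1:])):
        dt = t2 - t1
        if dt == 0:
            continue
        if c2 < c1 and c1 > 0 and c2 > 0:
            k = np.log(c1 / c2) / dt
            auc += (c1 - c2) / k
            aumc += (t1 * c1 - t2 * c2) / k + (c1 - c2) / k**2
        else:
            auc += dt * (c1 + c2) / 2.0
            aumc += dt * (t1 * c1 + t2 * c2) / 2.0
    return float(auc), float(aumc)


def extrapolate_and_derive(
    dose: float,
    infusion_time: float,
    cmax: float,
    tlast: float,
    clast: float,
    auc_last: float,
    aumc_last: float,
    lambda_fit: LambdaZFit,
) -> NCAResult:
    """Extrapolate the observed AUC/AUMC to infinity and derive CL, Vz, Vss."""
    lz = lambda_fit.lambda_z
    if lz <= 0:
        raise NCAError("lambda_z must be positive")
    auc_inf = auc_last + clast / lz
    aumc_inf = aumc_last + tlast * clast / lz + clast / lz**2
    mrt_inf = aumc_inf / auc_inf - infusion_time / 2.0
    cl = dose / auc_inf
    return NCAResult(
        cmax=cmax,
        tlast=tlast,
        clast=clast,
        auc_last=auc_last,
        auc_inf=auc_inf,
        aumc_last=aumc_last,
        aumc_inf=aumc_inf,
        mrt_inf=mrt_inf,
        cl_nca=cl,
        vz=cl / lz,
        vss=mrt_inf * cl,
        t_half_lambda_z=LN2 / lz,
        lambda_z=lz,
        n_lambda_points=lambda_fit.n_points,
    )


def _nca_one(
    times: np.ndarray,
    conc: np.ndarray,
    dose: float,
    infusion_time: float,
    n_lambda_points: int,
    auto: bool,
) -> NCAResult:
    pos = conc > 0
    if not pos.any():
        raise NCAError("no measurable concentrations")
    tlast = float(times[pos][-1])
    clast = float(conc[pos][-1])
    cmax = float(conc.max())
    auc_last, aumc_last = auc_linear_up_log_down(times, conc, t_end=tlast)
    fit = fit_lambda_z(times, conc, n_points=n_lambda_points, auto=auto)
    return extrapolate_and_derive(
        dose, infusion_time, cmax, tlast, clast, auc_last, aumc_last, fit
    )


def run_nca(
    dataset: pd.DataFrame | str,
    n_lambda_points: int = 4,
    auto_lambda: bool = False,
) -> pd.DataFrame:
    """Per-subject NCA over a NONMEM-style single-dose dataset.

    The dataset needs columns ID, TIME, AMT, DV, EVID (RATE/MDV optional);
    exactly one dose event per subject. Observation times are taken
    relative to the dose time. When a WT column is present, /kg-normalized
    clearance and volumes are added. Subjects whose terminal fit fails are
    reported with ``status`` set to the failure reason, never dropped.
    """
    from .io import read_nonmem

    df = read_nonmem(dataset) if isinstance(dataset, str) else dataset
    rows = []
    for sid, grp in df.groupby("ID", sort=True):
        doses = grp[grp["EVID"] == 1]
        if len(doses) != 1:
            raise NCAError(f"subject {sid}: expected exactly one dose event")
        dose_row = doses.iloc[0]
        dose = float(dose_row["AMT"])
        rate = float(dose_row.get("RATE", 0.0) or 0.0)
        infusion_time = dose / rate if rate > 0 else 0.0
        obs = grp[grp["EVID"] == 0]
        if "MDV" in obs:
            obs = obs[obs["MDV"] == 0]
        t = obs["TIME"].to_numpy(float) - float(dose_row["TIME"])
        c = obs["DV"].to_numpy(float)
        order = np.argsort(t)
        t, c = t[order], c[order]
        record: dict[str, object] = {"ID": sid, "status": "ok"}
        try:
            res = _nca_one(t, c, dose, infusion_time, n_lambda_points, auto_lambda)
            record.update({f.name: getattr(res, f.name) for f in fields(NCAResult)})
            if "WT" in grp.columns:
                record.update(res.per_kg(float(grp["WT"].iloc[0])))
        except NCAError as err:
            record["status"] = str(err)
        rows.append(record)
    return pd.DataFrame(rows)


def summarize_nca(results: pd.DataFrame) -> pd.DataFrame:
    """Mean (CV%) and median (IQR) summary of the per-subject NCA table."""
    numeric = results.select_dtypes("number").drop(columns=["ID"], errors="ignore")
    out = []
    for col in numeric.columns:
        vals = numeric[col].dropna().to_numpy(float)
        if vals.size == 0:
            continue
        mean = vals.mean()
        cv = 100.0 * vals.std(ddof=1) / mean if vals.size > 1 and mean != 0 else np.nan
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out.append(
            {
                "parameter": col,
                "mean": mean,
                "cv_pct": cv,
                "median": med,
                "iqr_low": q1,
                "iqr_high": q3,
            }
        )
    return pd.DataFrame(out)
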