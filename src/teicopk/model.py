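"""Three-compartment mammillary model for teicoplanin IV infusion.

The disposition model is the standard linear mammillary system with a
central compartment (V1) exchanging with two peripheral compartments
(Q2/V2, Q3/V3) and first-order elimination from the central compartment
(CL). After a bolus, the central concentration is a sum of three
exponentials; infusion responses follow by integrating the bolus response
over the zero-order input.

Covariate sub-models follow the published population estimates: clearance
scales with BSA-adjusted eGFR through a power model centred at the study
reference (105.27 mL/min), and the deep peripheral volume V3 scales with
body weight centred at 67.85 kg:

    CL = theta1 * (eGFR / 105.27) ** theta2
    V3 = theta7 * (WT   /  67.85) ** theta8

All other structural parameters equal their typical values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .regimen import DoseEvent, Regimen

__all__ = [
    "PopPKModel",
    "IndividualParams",
    "Disposition",
    "ConcentrationProfile",
    "DegenerateDispositionError",
    "apply_covariates",
    "disposition_of",
    "half_lives",
    "simulate_profile",
    "steady_state_volume",
    "auc_interval",
    "load_model",
]

LN2 = float(np.log(2.0))

#: relative eigenvalue gap below which the disposition is treated as degenerate
DEGENERACY_RTOL = 1e-10


class DegenerateDispositionError(ValueError):
    """Raised when two disposition rate constants coincide within tolerance.

    Physiological parameter sets never trigger this; it guards synthetic
    edge cases where the tri-exponential form is ill-conditioned.
    """


_DEFAULT_IIV = {
    "CL": 0.0883,
    "V1": 0.238,
    "Q2": 0.327,
    "V2": 0.239,
    "Q3": 0.310,
    "V3": 0.0754,
}


@dataclass(frozen=True)
class PopPKModel:
    """Population parameters: fixed effects, IIV magnitudes, residual error.

    Defaults are the published estimates for healthy adults; they are also
    shipped as ``data/teicoplanin_model.json`` and loadable from any
    JSON/YAML file with the same keys (see :func:`load_model`).
    """

    theta1_CL: float = 0.693  # L/h at reference eGFR
    theta2_CL_exp: float = 0.785  # eGFR power on CL
    theta3_V1: float = 3.96  # L
    theta4_Q2: float = 4.45  # L/h
    theta5_V2: float = 8.24  # L
    theta6_Q3: float = 1.76  # L/h
    theta7_V3: float = 69.8  # L at reference weight
    theta8_V3_exp: float = 1.73  # weight power on V3
    egfr_ref: float = 105.27  # mL/min
    wt_ref: float = 67.85  # kg
    iiv_cv: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_IIV))
    prop_error_cv: float = 0.0633

    def __post_init__(self) -> None:
        for name in ("theta1_CL", "theta3_V1", "theta4_Q2", "theta5_V2",
                     "theta6_Q3", "theta7_V3", "egfr_ref", "wt_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(cv < 0 for cv in self.iiv_cv.values()):
            raise ValueError("IIV CVs must be nonnegative")
        if self.prop_error_cv < 0:
            raise ValueError("proportional error CV must be nonnegative")

    @classmethod
    def default(cls) -> "PopPKModel":
        """The packaged published parameter set."""
        with resources.files("teicopk.data").joinpath(
            "teicoplanin_model.json"
        ).open() as fh:
            return cls(**json.load(fh))

    def with_no_iiv(self) -> "PopPKModel":
        return replace(self, iiv_cv={k: 0.0 for k in self.iiv_cv})

    def typical_params(
        self, egfr: float | None = None, weight: float | None = None
    ) -> "IndividualParams":
        """Typical-value parameters at the given (default: reference) covariates."""
        return apply_covariates(
            self,
            self.egfr_ref if egfr is None else egfr,
            self.wt_ref if weight is None else weight,
        )


@dataclass(frozen=True)
class IndividualParams:
    """One subject's realized macro parameters (after covariates and IIV)."""

    CL: float  # L/h
    V1: float  # L
    Q2: float  # L/h
    V2: float  # L
    Q3: float  # L/h
    V3: float  # L

    def __post_init__(self) -> None:
        for name in ("CL", "V1", "V2", "V3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.Q2 < 0 or self.Q3 < 0:
            raise ValueError("intercompartmental clearances must be nonnegative")


@dataclass(frozen=True)
class Disposition:
    """Bolus-response decomposition: C(t) = sum_i coeffs[i] * exp(-lambdas[i] t).

    ``lambdas`` are the positive disposition rate constants (1/h), sorted
    descending; ``coeffs`` are the matching unit-bolus coefficients
    (mg/L per mg dose). The coefficients sum to 1/V1 because a bolus
    initially occupies only the central compartment.
    """

    lambdas: np.ndarray
    coeffs: np.ndarray


@dataclass
class ConcentrationProfile:
    """Times (h) and central-compartment concentrations (mg/L) for one subject."""

    times: np.ndarray
    conc: np.ndarray
    dose_record: Regimen | Sequence[DoseEvent] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.shape != self.conc.shape:
            raise ValueError("times and conc must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be nondecreasing")
        if not np.all(np.isfinite(self.conc)):
            raise ValueError("concentrations must be finite")


def apply_covariates(model: PopPKModel, egfr: float, weight: float) -> IndividualParams:
    """Typical-value parameters for a subject's eGFR (mL/min) and weight (kg).

    No interindividual variability is applied here; see
    :func:`teicopk.cohort.sample_cohort` for the stochastic layer.
    """
    if egfr <= 0:
        raise ValueError("eGFR must be positive")
    if weight <= 0:
        raise ValueError("weight must be positive")
    return IndividualParams(
        CL=model.theta1_CL * (egfr / model.egfr_ref) ** model.theta2_CL_exp,
        V1=model.theta3_V1,
        Q2=model.theta4_Q2,
        V2=model.theta5_V2,
        Q3=model.theta6_Q3,
        V3=model.theta7_V3 * (weight / model.wt_ref) ** model.theta8_V3_exp,
    )


def rate_matrix(p: IndividualParams) -> np.ndarray:
    """Micro-constant rate matrix for amounts (central, peripheral 2, peripheral 3)."""
    k10 = p.CL / p.V1
    k12 = p.Q2 / p.V1
    k21 = p.Q2 / p.V2
    k13 = p.Q3 / p.V1
    k31 = p.Q3 / p.V3
    return np.array(
        [
            [-(k10 + k12 + k13), k21, k31],
            [k12, -k21, 0.0],
            [k13, 0.0, -k31],
        ]
    )


def _check_distinct(lambdas: np.ndarray, rtol: float = DEGENERACY_RTOL) -> None:
    lam = np.sort(lambdas)
    scale = lam[-1]
    if np.any(np.diff(lam) < rtol * scale):
        raise DegenerateDispositionError(
            f"disposition rates {lambdas} coincide within relative tolerance {rtol}"
        )


def disposition_of(p: IndividualParams) -> Disposition:
    """Eigen-decompose the mammillary system into exponential rates/coefficients.

    Peripheral compartments with zero intercompartmental clearance are
    dropped, so the decomposition degrades gracefully to the two- and
    one-compartment closed forms.
    """
    active = [q > 0 for q in (p.Q2, p.Q3)]
    if not any(active):
        return Disposition(
            lambdas=np.array([p.CL / p.V1]), coeffs=np.array([1.0 / p.V1])
        )
    full = rate_matrix(p)
    idx = [0] + [i + 1 for i, a in enumerate(active) if a]
    m = full[np.ix_(idx, idx)]
    mu, vec = np.linalg.eig(m)
    if np.max(np.abs(mu.imag)) > 1e-9 * np.max(np.abs(mu.real)):
        raise DegenerateDispositionError("complex disposition rates encountered")
    lam = -mu.real
    _check_distinct(lam)
    vinv = np.linalg.inv(vec)
    coeffs = (vec[0, :] * vinv[:, 0]).real / p.V1
    order = np.argsort(lam)[::-1]
    return Disposition(lambdas=lam[order], coeffs=coeffs[order])


def half_lives(p: IndividualParams) -> np.ndarray:
    """Disposition half-lives ln(2)/lambda in hours, sorted ascending."""
    disp = disposition_of(p)
    return np.sort(LN2 / disp.lambdas)


def steady_state_volume(p: IndividualParams) -> float:
    """Steady-state volume of distribution Vss = V1 + V2 + V3 (L)."""
    return p.V1 + p.V2 + p.V3


# ---------------------------------------------------------------------------
# vectorized infusion-response kernels, shared with the cohort engine
# ---------------------------------------------------------------------------


def infusion_conc(
    lam: np.ndarray,
    coef: np.ndarray,
    starts: np.ndarray,
    durations: np.ndarray,
    rates: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Central concentration under superposed zero-order infusions.

    Parameters are broadcast as: ``lam``/``coef`` (n, k) exponential terms
    per subject; ``starts``/``durations`` (e,) shared event schedule;
    ``rates`` (n, e) per-subject infusion rates (mg/h); ``times`` (m,).
    Returns concentrations with shape (n, m).
    """
    lam = np.atleast_2d(lam)[:, None, :, None]  # (n,1,k,1)
    coef = np.atleast_2d(coef)[:, None, :, None]
    tau = times[None, :] - starts[:, None]  # (e,m)
    tau = tau[None, :, None, :]  # (1,e,1,m)
    dur = durations[None, :, None, None]
    with np.errstate(over="ignore"):
        during = 1.0 - np.exp(-lam * np.clip(tau, 0.0, None))
        post = (1.0 - np.exp(-lam * dur)) * np.exp(-lam * np.clip(tau - dur, 0.0, None))
    resp = np.where(tau <= 0.0, 0.0, np.where(tau <= dur, during, post))
    terms = (coef / lam) * resp  # (n,e,k,m)
    per_event = terms.sum(axis=2)  # (n,e,m)
    return np.einsum("ne,nem->nm", np.atleast_2d(rates), per_event)


def _exp_integral(lam: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Integral of exp(-lam * t) over [a, b] (elementwise, a <= b)."""
    with np.errstate(over="ignore"):
        return (np.exp(-lam * a) - np.exp(-lam * b)) / lam


def infusion_auc(
    lam: np.ndarray,
    coef: np.ndarray,
    starts: np.ndarray,
    durations: np.ndarray,
    rates: np.ndarray,
    t0: np.ndarray,
    t1: np.ndarray,
) -> np.ndarray:
    """Exact AUC of the superposed infusion response over windows [t0, t1].

    ``t0``/``t1`` are (w,) window edges; returns shape (n, w). Each
    exponential term is integrated in closed form over the portions of the
    window during and after each infusion.
    """
    lam = np.atleast_2d(lam)[:, None, :, None]  # (n,1,k,1)
    coef = np.atleast_2d(coef)[:, None, :, None]
    s = starts[None, :, None, None]
    dur = durations[None, :, None, None]
    t0 = np.asarray(t0, dtype=float)[None, None, None, :]
    t1 = np.asarray(t1, dtype=float)[None, None, None, :]

    # during-infusion piece: integrand (1 - exp(-lam (t - s))) on [s, s+dur]
    u = np.clip(t0 - s, 0.0, dur)
    v = np.clip(t1 - s, 0.0, dur)
    inside = (v - u) - _exp_integral(lam, u, v)
    # post-infusion piece: (1 - exp(-lam dur)) exp(-lam (t - s - dur)) on [s+dur, inf)
    u2 = np.clip(t0 - s - dur, 0.0, None)
    v2 = np.clip(t1 - s - dur, 0.0, None)
    with np.errstate(over="ignore"):
        tail = (1.0 - np.exp(-lam * dur)) * _exp_integral(lam, u2, v2)
    terms = (coef / lam) * (inside + tail)  # (n,e,k,w)
    per_event = terms.sum(axis=2)
    return np.einsum("ne,new->nw", np.atleast_2d(rates), per_event)


def _resolve_events(
    regimen: Regimen | Sequence[DoseEvent],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(regimen, Regimen):
        if regimen.per_kg:
            raise ValueError(
                "regimen doses are per-kg; resolve against a body weight first"
            )
        events = regimen.events()
    else:
        events = list(regimen)
    starts = np.array([e.time for e in events], dtype=float)
    durations = np.array([e.duration for e in events], dtype=float)
    rates = np.array([e.rate for e in events], dtype=float)
    return starts, durations, rates


def simulate_profile(
    p: IndividualParams,
    regimen: Regimen | Sequence[DoseEvent],
    times: Sequence[float] | np.ndarray,
) -> ConcentrationProfile:
    """Model-predicted concentrations for one subject under a dosing schedule.

    The analytic superposition of zero-order-infusion responses is used;
    concentrations are exactly linear in dose and zero before the first
    infusion starts. Overlapping infusions simply add their rates.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("simulation times must be nonnegative")
    starts, durations, rates = _resolve_events(regimen)
    disp = disposition_of(p)
    if starts.size == 0:
        conc = np.zeros_like(times)
    else:
        conc = infusion_conc(
            disp.lambdas, disp.coeffs, starts, durations, rates[None, :], times
        )[0]
    record = regimen if isinstance(regimen, Regimen) else list(regimen)
    return ConcentrationProfile(times=times, conc=conc, dose_record=record)


def auc_interval(
    p: IndividualParams,
    regimen: Regimen | Sequence[DoseEvent],
    t0: float,
    t1: float,
) -> float:
    """Exact AUC (mg·h/L) of the model-predicted profile over [t0, t1]."""
    if t1 < t0 or t0 < 0:
        raise ValueError("need 0 <= t0 <= t1")
    starts, durations, rates = _resolve_events(regimen)
    if starts.size == 0:
        return 0.0
    disp = disposition_of(p)
    return float(
        infusion_auc(
            disp.lambdas,
            disp.coeffs,
            starts,
            durations,
            rates[None, :],
            np.array([t0]),
            np.array([t1]),
        )[0, 0]
    )


def load_model(path) -> PopPKModel:
    """Load model parameters from a JSON or YAML file.

    Keys must match :class:`PopPKModel` field names; unknown keys raise.
    """
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ValueError(f"model file {path!s} does not contain a mapping")
    valid = set(PopPKModel.__dataclass_fields__)
    unknown = set(payload) - valid
    if unknown:
        raise ValueError(f"unknown model parameter keys: {sorted(unknown)}")
    return PopPKModel(**payload)
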