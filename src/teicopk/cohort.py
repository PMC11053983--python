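"""Virtual-patient cohorts for Monte Carlo dosing simulation.

Covariates (body weight, BSA-adjusted eGFR) are drawn from truncated
lognormal distributions parameterized by arithmetic mean and CV; the
defaults emulate a normal-renal-function adult population (weight mean
64.8 kg, CV 19.9%; eGFR mean 103 mL/min, CV 15.5%, truncated to
80–140 mL/min). Interindividual variability enters as lognormal
multipliers exp(eta) on each typical parameter value with
eta ~ Normal(0, omega²), omega equal to the reported CV fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import IndividualParams, PopPKModel
from .regimen import Regimen

__all__ = ["CohortSpec", "VirtualSubject", "Cohort", "sample_cohort", "resolve_doses"]

PARAM_NAMES = ("CL", "V1", "Q2", "V2", "Q3", "V3")


@dataclass(frozen=True)
class CohortSpec:
    """Covariate distribution and size of a virtual cohort."""

    n: int = 5000
    weight_mean: float = 64.8  # kg
    weight_cv: float = 0.199
    weight_bounds: tuple[float, float] = (40.0, 120.0)
    egfr_mean: float = 103.0  # mL/min (BSA-adjusted CKD-EPI creatinine)
    egfr_cv: float = 0.155
    egfr_bounds: tuple[float, float] = (80.0, 140.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be at least 1")
        if self.weight_mean <= 0 or self.egfr_mean <= 0:
            raise ValueError("covariate means must be positive")
        if self.weight_cv < 0 or self.egfr_cv < 0:
            raise ValueError("covariate CVs must be nonnegative")
        for lo, hi in (self.weight_bounds, self.egfr_bounds):
            if not lo < hi:
                raise ValueError("truncation bounds must be ordered (low < high)")


@dataclass(frozen=True)
class VirtualSubject:
    """One simulated patient: covariates, realized parameters, random effects."""

    id: int
    weight: float
    egfr: float
    params: IndividualParams
    etas: dict[str, float] = field(default_factory=dict)


@dataclass
class Cohort:
    """Column-oriented container of virtual subjects (fast to simulate over)."""

    weight: np.ndarray
    egfr: np.ndarray
    params: dict[str, np.ndarray]  # name -> (n,) realized values
    etas: dict[str, np.ndarray]

    def __len__(self) -> int:
        return self.weight.size

    def __getitem__(self, i: int) -> VirtualSubject:
        return VirtualSubject(
            id=int(i),
            weight=float(self.weight[i]),
            egfr=float(self.egfr[i]),
            params=IndividualParams(**{k: float(v[i]) for k, v in self.params.items()}),
            etas={k: float(v[i]) for k, v in self.etas.items()},
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: covariates plus realized parameter columns."""
        data = {"id": np.arange(len(self)), "weight_kg": self.weight, "egfr_ml_min": self.egfr}
        data.update({k: v for k, v in self.params.items()})
        data.update({f"eta_{k}": v for k, v in self.etas.items()})
        return pd.DataFrame(data)


def _lognormal_mean_cv(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of ln X such that X has the given arithmetic mean and CV."""
    sigma2 = np.log1p(cv**2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _sample_truncated_lognormal(
    rng: np.random.Generator,
    n: int,
    mean: float,
    cv: float,
    bounds: tuple[float, float],
) -> np.ndarray:
    if cv == 0.0:
        if not bounds[0] <= mean <= bounds[1]:
            raise ValueError("degenerate distribution falls outside truncation bounds")
        return np.full(n, mean)
    mu, sigma = _lognormal_mean_cv(mean, cv)
    dist = stats.lognorm(s=sigma, scale=np.exp(mu))
    mass = dist.cdf(bounds[1]) - dist.cdf(bounds[0])
    if mass < 1e-6:
        raise ValueError(
            f"truncation bounds {bounds} contain negligible probability mass"
        )
    # inverse-CDF sampling restricted to the retained mass: exact and cheap
    u = rng.uniform(dist.cdf(bounds[0]), dist.cdf(bounds[1]), size=n)
    return dist.ppf(u)


def sample_cohort(
    model: PopPKModel,
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Draw a virtual cohort: covariates, etas, and realized parameters.

    Deterministic for a fixed ``spec.seed`` (or an explicitly supplied
    generator). Weight and eGFR are sampled independently.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    weight = _sample_truncated_lognormal(
        rng, spec.n, spec.weight_mean, spec.weight_cv, spec.weight_bounds
    )
    egfr = _sample_truncated_lognormal(
        rng, spec.n, spec.egfr_mean, spec.egfr_cv, spec.egfr_bounds
    )
    tv = {
        "CL": model.theta1_CL * (egfr / model.egfr_ref) ** model.theta2_CL_exp,
        "V1": np.full(spec.n, model.theta3_V1),
        "Q2": np.full(spec.n, model.theta4_Q2),
        "V2": np.full(spec.n, model.theta5_V2),
        "Q3": np.full(spec.n, model.theta6_Q3),
        "V3": model.theta7_V3 * (weight / model.wt_ref) ** model.theta8_V3_exp,
    }
    etas = {}
    params = {}
    for name in PARAM_NAMES:
        omega = float(model.iiv_cv.get(name, 0.0))
        eta = rng.normal(0.0, omega, size=spec.n) if omega > 0 else np.zeros(spec.n)
        etas[name] = eta
        params[name] = tv[name] * np.exp(eta)
    return Cohort(weight=weight, egfr=egfr, params=params, etas=etas)


def resolve_doses(subject: VirtualSubject, regimen_per_kg: Regimen) -> Regimen:
    """Convert a mg/kg regimen into absolute mg doses for one subject."""
    return regimen_per_kg.resolved(subject.weight)
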