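"""Renal-function estimators and body-surface-area adjustment.

Implements the five renal equations used as clearance covariates —
Cockcroft–Gault creatinine clearance, MDRD, the 2021 race-free CKD-EPI
creatinine equation, the CKD-EPI creatinine + cystatin C equation — plus
BSA computation (DuBois by default, Mosteller optional) and the conversion
of a standardized eGFR (mL/min/1.73 m²) to an absolute rate (mL/min).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

__all__ = [
    "SubjectCovariates",
    "creatinine_clearance_cg",
    "egfr_mdrd",
    "egfr_ckd_epi_cr",
    "egfr_ckd_epi_cr_cys",
    "bsa",
    "bmi",
    "adjust_egfr_for_bsa",
]

BSA_REFERENCE = 1.73  # m², the standardization surface of eGFR equations


@dataclass(frozen=True)
class SubjectCovariates:
    """Demographics and chemistry needed by the renal equations.

    ``cystatin_c`` (mg/L) is optional; only the combined CKD-EPI equation
    requires it.
    """

    age: float  # years
    sex: Literal["male", "female"]
    weight: float  # kg
    height: float  # cm
    serum_creatinine: float  # mg/dL
    cystatin_c: float | None = None  # mg/L

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.weight <= 0 or self.height <= 0:
            raise ValueError("weight and height must be positive")
        if self.serum_creatinine <= 0:
            raise ValueError("serum creatinine must be positive")
        if self.cystatin_c is not None and self.cystatin_c <= 0:
            raise ValueError("cystatin C must be positive when present")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")


def creatinine_clearance_cg(cov: SubjectCovariates) -> float:
    """Cockcroft–Gault creatinine clearance, mL/min.

    CLcr = (140 − age) · weight / (72 · Scr), × 0.85 for females.
    """
    if cov.age >= 140:
        raise ValueError("Cockcroft–Gault is undefined for age >= 140")
    clcr = (140.0 - cov.age) * cov.weight / (72.0 * cov.serum_creatinine)
    if cov.sex == "female":
        clcr *= 0.85
    return clcr


def egfr_mdrd(cov: SubjectCovariates) -> float:
    """MDRD study equation (175 variant), mL/min/1.73 m²."""
    egfr = 175.0 * cov.serum_creatinine**-1.154 * cov.age**-0.203
    if cov.sex == "female":
        egfr *= 0.742
    return egfr


def egfr_ckd_epi_cr(cov: SubjectCovariates) -> float:
    """2021 race-free CKD-EPI creatinine equation, mL/min/1.73 m².

    Sex-specific creatinine knot κ (0.7 female / 0.9 male) with a shallow
    exponent below the knot and −1.200 above; female values carry a 1.012
    multiplier.
    """
    cr = cov.serum_creatinine
    if cov.sex == "female":
        kappa, alpha, sex_factor = 0.7, -0.241, 1.012
    else:
        kappa, alpha, sex_factor = 0.9, -0.302, 1.0
    return (
        142.0
        * min(cr / kappa, 1.0) ** alpha
        * max(cr / kappa, 1.0) ** -1.200
        * 0.9938**cov.age
        * sex_factor
    )


def egfr_ckd_epi_cr_cys(cov: SubjectCovariates) -> float:
    """2021 CKD-EPI creatinine + cystatin C equation, mL/min/1.73 m²."""
    if cov.cystatin_c is None:
        raise ValueError("cystatin C is required for the combined CKD-EPI equation")
    cr, cys = cov.serum_creatinine, cov.cystatin_c
    if cov.sex == "female":
        kappa, alpha, sex_factor = 0.7, -0.219, 0.963
    else:
        kappa, alpha, sex_factor = 0.9, -0.144, 1.0
    return (
        135.0
        * min(cr / kappa, 1.0) ** alpha
        * max(cr / kappa, 1.0) ** -0.544
        * min(cys / 0.8, 1.0) ** 0.323
        * max(cys / 0.8, 1.0) ** -0.778
        * 0.9961**cov.age
        * sex_factor
    )


def bsa(
    cov: SubjectCovariates, formula: Literal["dubois", "mosteller"] = "dubois"
) -> float:
    """Body surface area in m² (DuBois–DuBois by default)."""
    if formula == "dubois":
        return 0.007184 * cov.height**0.725 * cov.weight**0.425
    if formula == "mosteller":
        return (cov.height * cov.weight / 3600.0) ** 0.5
    raise ValueError(f"unknown BSA formula {formula!r}")


def bmi(cov: SubjectCovariates) -> float:
    """Body mass index, kg/m² (cohort summaries only)."""
    return cov.weight / (cov.height / 100.0) ** 2


def adjust_egfr_for_bsa(egfr_std: float, bsa_m2: float) -> float:
    """Convert eGFR in mL/min/1.73 m² to an absolute mL/min for a given BSA."""
    if egfr_std <= 0 or bsa_m2 <= 0:
        raise ValueError("eGFR and BSA must be positive")
    return egfr_std * bsa_m2 / BSA_REFERENCE
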