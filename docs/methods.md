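# Methods

## Structural model

Teicoplanin disposition is described by a linear three-compartment
mammillary model with zero-order (constant-rate) intravenous infusion
input into the central compartment and first-order elimination from it.
With macro parameters CL (total clearance), V1 (central volume), Q2/V2
(shallow peripheral exchange and volume) and Q3/V3 (deep peripheral), the
micro constants are

    k10 = CL/V1,  k12 = Q2/V1,  k21 = Q2/V2,  k13 = Q3/V1,  k31 = Q3/V3.

The bolus response of the central concentration is a sum of three
exponentials, C(t) = Σᵢ cᵢ·e^(−λᵢ t), obtained by eigen-decomposition of
the 3×3 micro-constant rate matrix. The coefficients satisfy Σᵢ cᵢ = 1/V1
(a bolus starts entirely in the central compartment) and Σᵢ cᵢ/λᵢ = 1/CL
(the unit-dose AUC). Infusion responses are the exact time integrals of
the bolus response over the infusion window; multi-dose profiles are
superpositions of time-shifted infusion responses, so simulation is
analytic — no ODE solver is used at run time. Daily AUCs are likewise
computed term-by-term in closed form, not by quadrature.

When an intercompartmental clearance is zero, the affected peripheral
compartment is dropped before decomposition, so the model degrades exactly
to the two- and one-compartment closed forms. If two disposition rates
coincide within a relative gap of 1e−10 the decomposition raises a
`DegenerateDispositionError` rather than returning an ill-conditioned
tri-exponential; physiological parameter sets do not approach this
regime (the typical rates differ by more than an order of magnitude).

## Covariate and variability sub-models

Fixed effects (packaged in `data/teicoplanin_model.json`):

| parameter | value | units | role |
|---|---|---|---|
| θ1 | 0.693 | L/h | CL at the reference eGFR |
| θ2 | 0.785 | – | eGFR power on CL |
| θ3–θ6 | 3.96 / 4.45 / 8.24 / 1.76 | L, L/h, L, L/h | V1, Q2, V2, Q3 |
| θ7 | 69.8 | L | V3 at the reference weight |
| θ8 | 1.73 | – | weight power on V3 |

    CL = θ1 · (eGFR / 105.27)^θ2        V3 = θ7 · (WT / 67.85)^θ8

where eGFR is the BSA-adjusted CKD-EPI (creatinine) estimate in mL/min and
WT is body weight in kg. The typical subject has Vss = V1+V2+V3 = 82.0 L
and disposition half-lives of roughly 0.33, 4.0 and 106 h.

Interindividual variability is lognormal: each parameter P is realized as
TV_P·exp(η_P), η_P ~ N(0, ω_P²). ω_P is taken as the reported CV fraction
directly (CL 0.0883, V1 0.238, Q2 0.327, V2 0.239, Q3 0.310, V3 0.0754),
the conventional reading of %CV-reported variances; the ln(1+CV²)
transform differs by <0.5% at these magnitudes. Residual error is
proportional with CV 6.33% and is applied only by the synthetic study
generator: the dosing simulations score the model-predicted concentration
itself, since the attainment targets are defined on the underlying
exposure, not on a noisy measurement of it.

## Renal-function estimators

Five equations are provided, exactly as used for the clearance covariate:
Cockcroft–Gault creatinine clearance ((140−age)·weight/(72·Scr), ×0.85
female), the MDRD-175 equation, the 2021 race-free CKD-EPI creatinine
equation (knots 0.7/0.9, female factor 1.012), the CKD-EPI
creatinine+cystatin C equation (female factor 0.963), and the BSA
adjustment eGFR·BSA/1.73 converting a standardized estimate to mL/min.
BSA defaults to DuBois–DuBois (0.007184·H^0.725·W^0.425); the source
study never names its BSA formula, so Mosteller is available as an
option — the choice moves adjusted eGFR by about a percent.

## Virtual cohort

The cohort emulates adults with normal renal function. Weight ~ lognormal
(arithmetic mean 64.8 kg, CV 19.9%) truncated to 40–120 kg; BSA-adjusted
eGFR ~ lognormal(mean 103 mL/min, CV 15.5%) truncated to 80–140 mL/min.
The means and CVs are the study cohort's summary statistics; the
truncation encodes "normal renal function" and plausible adult weights.
Weight and eGFR are sampled independently (no correlation was reported).
Truncated variates are drawn by inverse-CDF sampling restricted to the
retained probability mass, so cohorts are exactly reproducible from a
seed, and every grid cell of a regimen sweep reuses the same cohort
(common random numbers), which makes attainment surfaces smooth and
monotone in dose.

## Dosing simulation and targets

Regimens are loading doses q12h ×4 (at 0, 12, 24, 36 h) followed by
maintenance doses starting at 48 h, q24h ×5 or q12h ×10; doses are mg/kg,
resolved against each subject's weight; all infusions last 0.5 h (the
duration stated for the clinical study dose; the simulation sections are
silent, so the same duration is used throughout and is configurable).

Day d ∈ {3..7} is scored by
* trough: the concentration at t = 24·(d−1) h, evaluated immediately
  before any dose scheduled at that instant. Both maintenance schedules
  place a dose at these times, making the convention uniform; the day-3
  trough therefore depends only on the loading phase.
* AUC24: the exact integral of the concentration over [24(d−1), 24d] h.

PTA targets: trough strictly above 10/15/20/30 mg/L (the "exceeded"
criterion), and the joint criterion trough ≥ 20 mg/L AND AUC24/MIC ≥ 800
(the "at least" criterion); both inequalities are configurable. MIC is
either a shared scalar (per-panel analysis) or assigned per subject from
the EUCAST MRSA distribution (0.25/0.5/1/2 mg/L with probabilities
31/224/239/61 out of 555). The safety metric is the fraction of subjects
with trough > 60 mg/L, a nephrotoxicity marker, reported per day for
every scenario.

## Noncompartmental analysis

λz is the negated OLS slope of ln C vs t over a fixed window of the last
3–6 positive concentrations (default 4, matching the source analysis; an
adjusted-R² automatic window is available but off by default). AUC/AUMC
use the linear-up/log-down trapezoid: rising, flat or zero-touching
segments use the linear rule, strictly falling positive segments the
logarithmic rule. Extrapolation and derived parameters:

    AUC_inf  = AUC_last + C_last/λz
    AUMC_inf = AUMC_last + T_last·C_last/λz + C_last/λz²
    MRT_inf  = AUMC_inf/AUC_inf − T_inf/2
    CL = dose/AUC_inf,  Vz = CL/λz,  Vss = MRT_inf·CL,  t½ = ln2/λz

Cmax/Tlast/Clast are read directly from observations, never interpolated.
Subjects with too few terminal points are reported as failed rows, not
dropped. On noise-free densely sampled simulated profiles the engine
recovers CL within 3%; Vss carries a larger extrapolation bias (tested at
15%), mirroring the well-known NCA/compartmental Vss discrepancy under
sparse terminal sampling of a long-half-life drug.

## Synthetic study generator

Emulates the single-dose design: 12 subjects, 200 mg infused over 30 min,
8 samples per subject at 33, 36, 45, 90 min and 4, 8 h after infusion
start, plus one uniform draw in each of the 48–120 h and 168–240 h
collection windows (the design records windows, not exact times).
Proportional error DV = C·(1+ε), ε ~ N(0, 0.0633²), truncated at −0.99 to
keep concentrations positive (a ~16σ event; the truncation is stated for
completeness, not because it occurs). The generator emulates the study's
design variables only: it does not model assay calibration,
below-quantification-limit censoring, or covariate correlations, so
passing recovery tests demonstrates estimator correctness under the
declared error model, not robustness to real-data pathologies.

## Problem sizes and numerical choices

Dosing simulations use n = 5000 virtual subjects, the published
simulation size; the acceptance checks additionally verify every regimen
conclusion on three independently seeded cohorts. IIV-recovery checks use
n = 50 000 (±0.5 percentage points on an 8.83% CV). The analytic
simulator is validated against a stiff ODE integration (LSODA, rtol
1e−10, integrated piecewise between infusion edges) at relative deviation
< 1e−6 over 100 random parameter sets on t ∈ [0, 500] h; unit tests keep
smaller replicates of the same comparison.

## Limitations

* No parameter estimation: the model consumes published fixed/random
  effects; it cannot refit clinical data.
* Fixed-effect uncertainty (bootstrap CIs) is not propagated into the
  simulations; PTA uncertainty reflects interindividual variability only.
* The virtual-cohort covariate distribution behind the published figures
  is not fully specified; the defaults here are the study cohort's
  moments with a normal-renal-function truncation, and all of them are
  configurable.
* Nephrotoxicity is summarized only as the trough > 60 mg/L flag; no
  exposure–toxicity model is implied.
* Renal-impairment dosing is out of scope; the covariate model was
  estimated in healthy adults with eGFR near or above normal.
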