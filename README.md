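# teicopk

Teicoplanin dosing for patients with **normal renal function** is a known
problem: the drug's terminal half-life is on the order of 100 hours, so
standard label regimens under-expose patients with good clearance for the
first week of therapy. `teicopk` is a pharmacometrics toolkit that turns a
published population pharmacokinetic model for teicoplanin in healthy
adults into a reusable simulation pipeline for answering the practical
question: *which loading/maintenance regimen reaches the trough and
AUC/MIC targets by days 3–7, and at what nephrotoxicity risk?*

It is aimed at clinical pharmacologists and pharmacometricians who want
to run probability-of-target-attainment (PTA) analyses, reproduce or
extend the published dosing recommendations, or exercise a complete
noncompartmental analysis (NCA) workflow on simulated or observed data.

## What's inside

* **Three-compartment IV-infusion model** (`teicopk.model`) — analytic
  tri-exponential disposition via eigen-decomposition of the
  micro-constant rate matrix; exact multi-dose superposition and exact
  daily AUCs (no ODE solver at run time). Covariate sub-models
  `CL = θ1·(eGFR/105.27)^θ2` and `V3 = θ7·(WT/67.85)^θ8`; the published
  parameter set ships as the packaged default (typical CL 0.693 L/h,
  Vss 82.0 L).
* **Renal function & anthropometrics** (`teicopk.renal`) —
  Cockcroft–Gault, MDRD, CKD-EPI creatinine (2021), CKD-EPI
  creatinine+cystatin C, DuBois/Mosteller BSA, and BSA adjustment of
  standardized eGFR.
* **Virtual cohorts** (`teicopk.cohort`) — truncated-lognormal covariates
  (weight mean 64.8 kg CV 19.9%; eGFR mean 103 mL/min CV 15.5%,
  truncated to 80–140 mL/min) with lognormal interindividual variability
  on every PK parameter; fully seeded.
* **NCA engine** (`teicopk.nca`) — λz by terminal log-linear regression,
  linear-up/log-down AUC/AUMC, extrapolation to infinity, CL/Vz/Vss/MRT
  and /kg variants, per-subject tables and mean (CV%) / median (IQR)
  summaries.
* **Dosing simulator** (`teicopk.dosing`) — loading (q12h ×4) +
  maintenance (q24h ×5 or q12h ×10) regimens in mg/kg, daily troughs and
  AUC24 for days 3–7, PTA for trough targets (10/15/20/30 mg/L) and the
  joint target trough ≥ 20 mg/L & AUC24/MIC ≥ 800 (scalar MIC or the
  EUCAST MRSA MIC distribution), trough > 60 mg/L safety fractions, and
  full LD×MD regimen sweeps with common random numbers.
* **Synthetic study generator** (`teicopk.study`) — emulates the
  single-dose clinical design (12 subjects, 200 mg over 30 min, 8 samples
  each, 6.33% proportional error) as a NONMEM-style CSV plus truth table,
  with an NCA recovery harness.

See `docs/methods.md` for the model equations, conventions and
limitations.

## Worked example

Evaluate the recommended regimen for a pathogen with MIC 1 mg/L — a
loading dose of 14 mg/kg q12h ×4 followed by 16 mg/kg q24h — against the
joint efficacy target in 5000 virtual patients with normal renal
function:

```python
import numpy as np
import teicopk as tk

model = tk.PopPKModel.default()
typ = model.typical_params()
print("half-lives (h):", np.round(tk.half_lives(typ), 2))
print("Vss (L):", tk.steady_state_volume(typ))

cohort = tk.sample_cohort(model, tk.CohortSpec(n=5000, seed=42))
regimen = tk.Regimen(ld_dose=14.0, md_dose=16.0)   # mg/kg; LD q12h x4, MD q24h x5
table = tk.pta_joint(cohort, regimen, mic=1.0)
for day, pta, tox in zip(table.days, table.pta, table.frac_gt60):
    print(f"day {day}: joint PTA = {100*pta:5.1f}%   trough>60 mg/L: {100*tox:.2f}%")
```

Output:

```
half-lives (h): [  0.33   4.04 106.43]
Vss (L): 82.0
day 3: joint PTA =  99.6%   trough>60 mg/L: 0.00%
day 4: joint PTA =  97.2%   trough>60 mg/L: 0.00%
day 5: joint PTA =  98.8%   trough>60 mg/L: 0.00%
day 6: joint PTA =  99.4%   trough>60 mg/L: 0.00%
day 7: joint PTA =  99.6%   trough>60 mg/L: 0.00%
```

The three half-lives (≈20 min, 4 h, 106 h) are the tri-exponential
disposition phases; the terminal phase is why a loading phase is
mandatory. The regimen keeps every simulated day at ≥ 97% attainment of
trough ≥ 20 mg/L with AUC24/MIC ≥ 800, with no subject crossing the
60 mg/L nephrotoxicity trough marker.

The same analyses are available from the shell:

```bash
teicopk generate-study --seed 1 --out study        # synthetic single-dose study
teicopk nca study_data.csv --out nca               # per-subject NCA + summary
teicopk simulate-pta --target joint --mic 1 --ld 14 --md 16 --out pta.csv
teicopk sweep --targets both --md-interval 24 --outdir grids --heatmaps
```

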