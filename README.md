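# vancopk

Population pharmacokinetics of intravenous vancomycin in pediatric liver-transplant
recipients: a one-compartment nonlinear mixed-effects (NLME) model with renal and
post-transplant covariates, plus the surrounding workflow a pharmacometrician needs —
synthetic study populations, Laplace/FOCE-style estimation with stepwise covariate
selection, bootstrap and visual-predictive-check validation, and Monte Carlo
probability-of-target-attainment dosing simulations.

## Who this is for

Vancomycin is first-line therapy for MRSA infection after pediatric liver
transplantation, and its exposure target (AUC₂₄/MIC ≥ 400, or trough ≥ 10 µg/mL)
is hard to hit in this population: glomerular filtration is high in infants, and
clearance is further elevated early after transplant. This package implements the
full analysis pipeline for studying that problem — for teaching, method development,
and design of TDM strategies — driven entirely by simulated cohorts that match the
published baseline characteristics of a 161-patient transplant cohort
(weight median 9.1 kg, sCr median 0.16 mg/dL, 17 days from transplant to treatment).

## The model

Individual clearance and volume follow an allometric one-compartment model with
zero-order infusion input:

```
CL_i (L/h) = θ_CL · wt^0.75 · (sCr/0.16)^θ_sCr · (DFLT/17)^θ_DFLT · exp(η_CL,i)
V_i  (L)   = θ_V  · wt · exp(η_V,i)
y_ij       = f(t_ij; CL_i, V_i) · (1 + ε_prop) + ε_add
```

with η ~ N(0, ω²) (diagonal, exponential between-subject variability), DFLT = days
from liver transplantation, and a combined residual model. Package defaults are the
published final-model estimates (θ_CL = 0.29 L/h/kg^0.75, θ_sCr = −0.70,
θ_DFLT = −0.09, θ_V = 1.00 L/kg, ω_CL = 46.5%, ω_V = 48.1%, σ_prop = 56.5%).
The marginal likelihood is computed by a Laplace approximation with exact
conditional Hessians; −2·log L (the OFV) drives estimation and the stepwise
covariate search (forward ΔOFV > 3.84, backward ΔOFV < 7.88).

## Worked example

```python
import numpy as np
import vancopk as v

# 1. simulate a study-sized TDM dataset from the default (published) model
data = v.simulate_dataset(n_subjects=161, seed=42)
print(len(data), sum(len(r.observations) for r in data))   # 279 1213

# 2. refit it from neutral starting values
result = v.fit(data, v.final_model_spec(), compute_se=False)
print(round(result.params["theta_cl"], 3),
      round(result.params["theta_v"], 3),
      round(result.params["beta_scr_CL"], 3))               # 0.273 1.008 -0.493

# 3. post hoc (empirical Bayes) clearance per kilogram
cl = np.array([v.typical_clearance(r.covariates, result.estimates)
               for r in data]) * np.exp(result.ebes[:, 0])
wt = np.array([r.covariates.weight for r in data])
print(round(float(np.mean(cl / wt)), 3))                    # 0.183  (L/h/kg)

# 4. Monte Carlo dosing simulation
table = v.simulate_attainment(n_profiles=1000, seed=7)
print(v.attainment_report(table))
```

Each fitted coefficient lands within one published bootstrap-CI width of its
generating value (CI widths: θ_CL 0.06, θ_V 0.25, θ_sCr 0.22, θ_DFLT 0.12),
and the mean post hoc clearance of ~0.18 L/h/kg matches the reported
population average. The attainment
report prints regimen × target grids stratified by days-from-transplant and
Schwartz creatinine clearance; with between-subject variability near 50%,
standard 15 mg/kg q6h dosing reaches AUC₂₄/MIC ≥ 400 (MIC 1 µg/mL) in only a
minority of virtual patients, which is the study's central dosing message.

## Command line

Each pipeline stage is exposed as a `vancopk` subcommand driven by a YAML config:

```bash
vancopk simulate -c config.yaml -o out/    # NONMEM-style CSV dataset
vancopk fit -c config.yaml -o out/         # estimates, GOF table, shrinkage
vancopk stepwise -c config.yaml -o out/    # covariate screening log
vancopk bootstrap -c config.yaml -o out/   # subject-resampling CIs
vancopk vpc -c config.yaml -o out/         # predictive-check bands
vancopk mcs -c config.yaml -o out/         # attainment tables
```

Every run writes a log with the package version, seed and config hash, and is
byte-reproducible from (config, seed).

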