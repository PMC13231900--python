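# neopk — population pharmacokinetics of ceftazidime in neonates

`neopk` is a Python package for the complete population-PK workflow behind
neonatal ceftazidime dose optimisation: a one-compartment intravenous-infusion
model with allometric weight scaling and sigmoidal clearance maturation,
conditional-estimation (FOCE-type) fitting of sparse dried-blood-spot data,
model diagnostics (goodness-of-fit residuals, visual predictive checks, a
subject-resampling bootstrap), and Monte Carlo probability-of-target-attainment
(PTA) simulation over candidate dosing regimens. A synthetic-study generator
reproduces the structure of a sparse neonatal micro-sampling design so every
stage is testable without patient data.

It is aimed at pharmacometricians and quantitative clinical pharmacologists
who want a scriptable, reproducible re-implementation of this analysis type
outside NONMEM.

## The model

For a neonate with body weight WT (kg) and postmenstrual age PMA (weeks):

```
CL = TVCL · (WT/70)^0.75 · PMA^H / (PMA^H + TM50^H) · exp(η_CL)
V  = TVV  · (WT/70)               · exp(η_V)
```

with allometric exponents fixed at 0.75 (clearance) and 1 (volume), and renal
maturation fixed at TM50 = 47.7 weeks, Hill H = 3.4. Random effects
η ~ N(0, ω²) are log-normal on both parameters; the residual is exponential
(additive Gaussian in the log domain). Concentration–time profiles are the
closed-form superposition of constant-rate infusion segments with
k = CL/V.

The reference (default) parameter values shipped with the package are
TVCL = 19.6 L/h/70 kg, TVV = 70.6 L/70 kg, IIV 28.1/42.4 CV%, residual
22.3 CV%.

Estimation maximises the Laplace-approximate marginal likelihood after log
transformation of both sides: per subject the conditional mode of
(η_CL, η_V) is found by damped Gauss–Newton with analytic derivatives, and
−2 log L accumulates the exact-Hessian Laplace determinant (details in
`docs/methods.md`). The inner loop is numba-compiled; a pure-numpy reference
path (`foce_objective(..., compiled=False)`) computes identical values.

For dosing simulation, whole-blood concentrations are converted to unbound
plasma with `C_u = fu · C_blood / BP` (fu = 0.9, blood-to-plasma ratio
BP = 0.72 for ceftazidime), and PTA is the fraction of a virtual neonatal
cohort keeping unbound plasma above the MIC for ≥ 70% of a steady-state
dosing interval (`%fT>MIC ≥ 70`); a regimen is considered adequate at
PTA ≥ 90%.

## Worked example

```python
import neopk as npk

truth = npk.final_model_params()
dataset, _ = npk.generate_study(truth, seed=1)          # 72 neonates, ~140 samples
dataset = npk.handle_blq(npk.impute_missing_scr(dataset))

fit = npk.fit_population(dataset, init=truth)
p = fit.params
print(f"OFV {fit.ofv:.1f}  converged={fit.converged}")
print(f"CL  {p.tvcl:5.1f} L/h/70 kg   (IIV {npk.cv_percent(p.omega2_cl):.1f} CV%)")
print(f"V   {p.tvv:5.1f} L/70 kg     (IIV {npk.cv_percent(p.omega2_v):.1f} CV%)")

pta = npk.pta_table(fit.params, (npk.Regimen(25, 8), npk.Regimen(25, 12)),
                    mic_grid=(2.0, 4.0, 8.0), subgroups=((38.0, 42.0),),
                    n=10_000, seed=2)
print(pta.table.pivot_table(index="regimen", columns="mic", values="pta"))
```

prints

```
OFV 130.3  converged=True
CL   20.3 L/h/70 kg   (IIV 25.8 CV%)
V    66.6 L/70 kg     (IIV 45.7 CV%)
mic              2.0    4.0    8.0
regimen
25 mg/kg q12h  84.36  62.12  22.56
25 mg/kg q8h   98.05  93.03  71.19
```

The fit recovers the generating parameters (CL 20.3 vs 19.6 L/h/70 kg,
V 66.6 vs 70.6 L/70 kg) from only ~2 samples per neonate, and the dosing
simulation shows 25 mg/kg q8h holding PTA ≥ 90% up to MIC 4 mg/L in
term-age neonates while the same daily dose given q12h does not — the
core clinical conclusion this model family supports.

## Command line

A `neopk` executable mirrors the analysis sequence:

```sh
neopk synth --seed 1 --out study.csv        # simulate a sparse study
neopk fit study.csv --out report/           # population fit + GOF plots
neopk vpc study.csv                         # visual predictive check
neopk bootstrap study.csv --n-replicates 200
neopk pta --n 10000 --seed 1                # 12-regimen PTA table + plot
neopk run-all --out bundle/ --seed 1        # everything, stamped + reproducible
```

Datasets use a NONMEM-style CSV layout (`ID, TIME, AMT, DUR, DV, EVID, MDV`
plus covariate columns `WT, PMA, GA, PNA, SCR, SEX`); times are hours since
first dose, concentrations mg/L whole blood.

## Layout

- `src/neopk/datamodel.py`, `io.py` — longitudinal PK data model, CSV dialect,
  creatinine imputation, BLQ policies
- `src/neopk/pkmodel.py` — structural model and covariate functions
- `src/neopk/estimation.py`, `_foce_core.py` — conditional-estimation engine,
  empirical Bayes, shrinkage, stepwise covariate screening
- `src/neopk/diagnostics.py` — GOF/CWRES, VPC, bootstrap
- `src/neopk/pta.py` — virtual cohorts, %fT>MIC, PTA tables
- `src/neopk/synth.py` — synthetic sparse-study generator
- `src/neopk/cli.py` — command line and report bundling
- `docs/methods.md` — modelling and numerical methods note
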