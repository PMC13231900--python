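# Methods note

This note records the modelling assumptions, numerical choices and known
limitations of `neopk`, in the spirit of a statistical appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Structural and statistical model

Ceftazidime in neonates is described by a one-compartment model with
zero-order (constant-rate) intravenous infusion input and first-order
elimination. Clearance carries fixed allometric scaling (exponent 0.75 on
WT/70 kg) and a sigmoidal renal-maturation factor in postmenstrual age,
`PMA^H / (PMA^H + TM50^H)` with TM50 = 47.7 weeks and H = 3.4; volume
scales linearly with weight. TM50 and Hill are treated as known constants
(glomerular-filtration maturation values): a 72-neonate study spanning
PMA 32.7–41.9 weeks observes only the lower flank of the maturation curve
and cannot identify them, so they are never estimated.

Interindividual variability is log-normal on CL and V with independent
variances (no ω covariance term, and no inter-occasion variability — the
design samples each neonate within a single dosing occasion). The residual
is exponential; after log transformation of observations and predictions it
is additive Gaussian with constant variance σ². Reported CV% for all
variance components uses the log-normal convention
`CV% = 100·sqrt(exp(ω²) − 1)`; the reference values used as simulation
defaults (TVCL 19.6 L/h/70 kg, TVV 70.6 L/70 kg, IIV 28.1/42.4 CV%,
residual 22.3 CV%) convert to ω² = 0.0760, 0.1653 and σ² = 0.0485.

All data handling is in whole-blood concentration units (the quantity a
volumetric dried-blood-spot assay measures); plasma conversion happens only
inside the dosing simulation.

## Likelihood approximation

The marginal likelihood of each subject integrates over (η_CL, η_V). We
use a Laplace expansion at the conditional mode (the empirical Bayes
estimate), found by damped Gauss–Newton with analytic derivatives of the
log-domain infusion model (inner step tolerance 1e−8, cold-started at the
prior mode on every evaluation so the objective is a deterministic function
of data and parameters). The −2 log-likelihood accumulates, per subject,

    m·log(2πσ²) + |r|²/σ² + η̂'Ω⁻¹η̂ + log det Ω
      + log det(Ω⁻¹ + (J'J + Σ_j r_j ∇²r_j)/σ²)

with `r` the log-scale residual vector at the mode and `J` its η-Jacobian.
Under the log-additive residual with constant σ, the η-dependence of the
residual variance ("interaction") is identically zero, so this is the
conditional-estimation family with the interaction question moot.

Two numerical choices matter here:

- **Exact versus Gauss–Newton Hessian.** The determinant uses the exact
  conditional Hessian (second derivatives obtained by central differences
  of the analytic Jacobian, step 1e−5). Against a dense two-dimensional
  quadrature oracle the exact-Hessian version tracks the true marginal
  likelihood within about 1% on 5-subject sets with four samples per
  subject, where the common J'J-only variant is several-fold coarser; it
  also removes most of the small upward bias in TVCL seen with the
  Gauss–Newton determinant on the sparse design.
- **Determinant floor.** For subjects with one or two observations the
  exact conditional Hessian can approach singularity, and an optimizer
  will exploit `log det → −∞` to drive the objective down spuriously. The
  determinant is therefore floored at half its (always positive-definite)
  Gauss–Newton value — a continuous safeguard that caps the second-order
  correction at log 2 per subject. With the floor in place,
  likelihood-ratio statistics for a null covariate follow their nominal
  χ² reference (measured forward-inclusion rate 9/100 at the 3.84
  threshold over 100 simulated studies; without it, basin-hopping produced
  both negative and grossly inflated ΔOFV values).

Zero variance components pin the corresponding η at 0 and drop out of the
determinant, recovering the fixed-effects likelihood exactly.

The outer problem minimises over log-transformed (TVCL, TVV, ω²_CL, ω²_V,
σ²) plus any covariate coefficients with Powell's method (relative
tolerance 1e−6). Powell matched Nelder–Mead's optima on every dataset
tried at roughly a quarter of the evaluations, whereas finite-difference
quasi-Newton methods stalled above the optimum; see the package history
for measurements. Non-convergence and boundary variance estimates
(ω² < 1e−4) are flagged on the result rather than raised. The per-subject
inner loop is numba-compiled; `foce_objective(..., compiled=False)` runs a
pure-numpy reference implementation that agrees to ~1e−9 and is used by
the diagnostics.

Parameter uncertainty comes from the nonparametric bootstrap (below), not
from an asymptotic covariance matrix: the package's headline use is
simulation from point estimates, and percentile intervals from subject
resampling are both more robust on 1–4-sample-per-subject designs and
match how such analyses conventionally report uncertainty.

## Covariate screening

Weight and PMA enter the structural model a priori and are never candidates
for removal. Additional covariate–parameter relations (power form for
continuous covariates, proportional `1 + θ·x` for binary ones) are screened
stepwise: forward inclusion requires ΔOFV ≥ 3.84 (χ²₁, p < 0.05), backward
elimination removes terms whose deletion raises the OFV by < 6.63
(p < 0.01). Candidates with multi-parameter forms would need the matching
χ² quantile; the shipped forms are all single-parameter.

## Diagnostics

- **GOF table**: PRED at η = 0, IPRED at the EBEs,
  `IWRES = (log DV − log IPRED)/σ`, and CWRES from the
  first-order-conditional linearization around the EBEs — the subject's
  log-observations are approximately normal with mean `h(η̂) − Gη̂` and
  covariance `GΩG' + σ²I`; the residual vector is whitened by the Cholesky
  factor of that covariance. Any whitening gives standard-normal residuals
  under the model; Cholesky is used for determinism.
- **VPC**: replicates are simulated at the exact original design (same
  subjects, doses, times, covariates; fresh η and ε). Default time bins
  are the design's sampling windows (0–0.5, 2–3, 4–6 h); empty bins merge
  into their nearest neighbour with a warning. `coverage` is the
  percentage of observations inside their pointwise simulated 90%
  prediction interval, so on self-simulated data it calibrates to ≈ 90%.
- **Bootstrap**: subjects are resampled with replacement to the original
  cohort size (the subject is the exchangeable unit of a hierarchical
  design; records are never split). A replicate counts as converged when
  the optimizer succeeded with all variances off the boundary; percentile
  95% intervals and RSE% summarise converged replicates, falling back to
  all completed replicates (with a warning) if none meets the strict
  criterion.

## Dosing simulation

Virtual cohorts draw PMA uniformly within a subgroup (32–35, 35–38, 38–42
weeks), weight from a PMA-conditional model (below) truncated to the study
range 1.8–4.2 kg, and η from the model's ω². Per-kg doses are
individualised by each subject's weight and rounded to 0.1 mg. %fT>MIC is
evaluated over one dosing interval at effective steady state, defined by a
pre-dose concentration change below 0.1% between consecutive intervals
(≈ 7 half-lives of accumulation); the dose train up to that point is summed
in closed form. Crossing times are solved analytically in the
post-infusion mono-exponential segment and counted on a 1-millihour grid
during the infusion, keeping the fT>MIC error below 0.1 percentage points.

Blood-to-plasma conversion: ceftazidime distributes poorly into
erythrocytes, so with BP = C_blood/C_plasma = 0.72 and unbound fraction
fu = 0.9 (low protein binding), unbound plasma is `fu · C_blood / BP`.
Conversion chains are sometimes printed as a product `fu · C_blood · BP`
with "BP" denoting the inverse ratio; `ConversionParams(multiply_bp=True)`
selects that reading. The divide form is the default because only under it
does the reference model reproduce the published neonatal dosing
conclusions (e.g. 25 mg/kg q8h adequate at MIC ≤ 4 mg/L, 25 mg/kg q6h and
50 mg/kg q8h adequate at MIC ≤ 8 mg/L, 25/50 mg/kg q12h inadequate);
under the product form those claims fail broadly. Published
plasma-standardised summary values of CL and V for this model family are
not reproducible from the stated equations under either direction and are
not used anywhere.

PTA at standard conditions is computed with n = 10,000 per subgroup
(binomial standard error ≤ 0.5 percentage points); the MIC grid is the
doubling series 0.25–32 mg/L.

## Synthetic study generator

The generator emulates a sparse neonatal capillary micro-sampling design
and is the basis of all tests:

- 72 neonates; samples per subject drawn from P(1..4) = (0.35, 0.45, 0.12,
  0.08) — median 2, expectation ≈ 1.94, so ≈ 140 samples per study;
- one sampling time uniform within each selected window (0–0.5, 2–3,
  4–6 h after the first dose; postnatal ages of 1–4 days imply sampling
  early in therapy, so later-dose sampling is off by default and available
  via `n_doses_recorded`);
- PMA from a left-skewed (skew-normal, shape −4, loc 46.03, scale 5.08)
  distribution truncated to 32.7–41.9 weeks — calibrated once so the
  median is 39.7 weeks and ≈ 19.4% of neonates are preterm (GA < 37 wk,
  with GA = PMA − PNA/7 and PNA uniform on 1–4 days);
- weight `WT = (−4.68 + 0.20·PMA) · exp(N(0, 0.1²))` kg, rejection-sampled
  into 1.8–4.2 kg (median ≈ 3.2 kg at the median PMA);
- serum creatinine log-normal (median 56.7 µmol/L, log-sd 0.28) truncated
  to 23.7–88.0; sex 60/40 male/female; covariates independent given PMA;
- dosing 25 or 50 mg/kg (equal probability) every 8 or 12 h as 30-min
  infusions — plausible clinical practice, configurable, and irrelevant to
  parameter recovery as long as concentrations stay quantifiable;
- concentrations carry log-normal residual error and are flagged BLQ below
  0.25 mg/L (the assay's lower limit). The default BLQ policy discards
  flagged records (M1); `loq/2` substitution is available.

What the generator does **not** emulate: assay-specific error structure
(hematocrit effects on dried-blood-spot quantification), covariate
correlations beyond WT–PMA (e.g. SCR–PNA), dose-amount rounding to vial
sizes, and any real-world discrepancy between charted and actual sampling
times. Tests passing on these data therefore demonstrate the correctness
and calibration of the algorithms under the stated model, not the model's
adequacy for any particular clinical dataset.

## Problem sizes used by the test suite

Parameter recovery refits 20 independently simulated 72-neonate studies;
the null-covariate calibration uses 100 such studies (forward step only);
VPC calibration uses 1,000 replicates at one study; oracle equivalences
use 5-subject sets (four samples per subject for the quadrature
comparison, where the Laplace expansion's ~1% agreement band is
meaningful — on 1–2-sample subjects no Laplace-family approximation is
that close, which is a property of the approximation, not a defect).
`scripts/acceptance.py` simulates 10,000 virtual neonates per endpoint.

## Known limitations

- The maturation function induces a PMA-subgroup gradient in PTA (younger
  subgroups clear slower and attain more); with our demographic model,
  25 mg/kg q12h is adequate at MIC 4 mg/L in the 32–35-week subgroup while
  clearly inadequate at term. Reports that subgroups behave identically
  presumably reflect a different joint PMA–weight demographic than our
  synthetic one; the term subgroup (38–42 wk) is the binding case for all
  adequacy claims and is the default evaluation cohort.
- The weight-given-PMA model is a two-parameter stand-in for a real
  demographic database and is exposed in `StudyDesignConfig`.
- FOCE/Laplace likelihood-ratio tests on sparse designs are mildly
  anticonservative even with the determinant floor (measured 9% at nominal
  5%); stepwise decisions near the threshold should be read accordingly.
- PTA is evaluated at steady state; first-dose attainment is lower for
  accumulating regimens and is not reported.
- No two-compartment alternative, CSF penetration, toxicity thresholds, or
  MIC-distribution-weighted response fractions.
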