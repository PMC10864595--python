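# Methods

## Structural model and covariate model

Tacrolimus disposition is modeled as one compartment with first-order
absorption and elimination. The published covariate model supplies only
apparent clearance (CL/F) and apparent volume (Vd/F); the absorption rate
constant is not part of it, so the package fixes k_a = 4.48 h⁻¹, a
conventional value for immediate-release tacrolimus, configurable through
`ModelDefinition`. Troughs are insensitive to k_a in the realistic range
(with τ = 12 h the absorption phase has fully decayed:
e^{−k_aτ} ≈ 3·10⁻²⁴ at the default), so this assumption carries little
risk; k_a ≤ k_e is rejected as a parameterization error rather than
remapped, since the flip-flop regime is outside the model's scope.

Clearance covariates and their directions: allometric weight (0.75),
hematocrit (−0.868: lower hematocrit → faster apparent whole-blood
clearance → lower troughs; this is why the low-hematocrit companion
scenario recommends higher doses), total daily dose (0.616: apparent
clearance grows with dose, so exposure grows sublinearly but strictly —
net dose exponent 1 − 0.616 > 0), postoperative day (0.0807, weak), a
×1.3 CYP3A5*1-carrier factor and a ×0.638 voriconazole factor. The daily
dose inside CL/F is fully determined by the simulated regimen and weight,
so no iteration is needed. All constants live in one immutable record.

Units: doses mg, volumes L, time h, concentrations ng/ml (mg/L × 1000).
The per-administration dose is exactly DD/2; no rounding to capsule
strengths. Non-positive covariates are rejected by preconditions, not
clamped.

## Trough definition

Two interpretations of the simulated concentration are implemented:

- `pod_accumulation` (default): the trough after POD × 2 twice-daily
  doses, i.e. after 16 doses on postoperative day 8. This matches the
  clinical anchor of the analysis (troughs regarded as established on
  day 8) and, empirically, the scale of the published results.
- `steady_state`: the analytic infinite-time limit. With pediatric
  half-lives of ~100 h under this model, day-8 troughs are well below
  steady state; running the recommender in this mode pushes every
  recommendation to the lowest grid dose, which is a useful sensitivity
  bound but does not reproduce the published table.

The closed form is validated against an independent ODE integration of
the same dosing history (1e-6 relative, randomized parameters) and
against its own n → ∞ limit.

## Variability assumptions and calibration

The published analysis states that 1,000 Monte Carlo replicates were
simulated per cell but not what was perturbed or by how much. The package
therefore treats variability as an explicit assumption:
lognormal inter-individual deviations on CL/F (ω_CL) and Vd/F (ω_V),
independent, ka unperturbed, plus an optional proportional residual error
(σ_prop, floored at zero concentration, floor events counted). Defaults
before calibration are ω_CL = 0.35, ω_V = 0.30, σ_prop = 0; residual
error is excluded from attainment by default because the window criterion
concerns true exposure, not assay noise.

`calibrate_omega` pins ω_CL by grid search over 0.05–0.80 (step 0.05),
minimizing the RMSE between the computed per-band maximum exceedance
probability — at the *published* band/dose table, 1-kg scan — and the
published per-band bounds, treated as equality targets. The search
selects ω_CL = 0.25 (RMSE ≈ 9 percentage points) with ω_V and σ_prop held
at 0.30 and 0. The calibrated value is used by the acceptance pipeline
and the worked examples; it is deliberately *not* re-tuned per cell.

## Randomness

One master seed; every (category, weight, dose) cell draws from a
substream keyed by a stable integer tuple, so any cell is reproducible in
isolation and adding or removing cells never changes the others. Dose and
weight scans that feed the recommender reuse one set of η draws per
category (common random numbers), which makes dose comparisons paired and
the recommendation path deterministic given the seed. Residual error is
incompatible with the shared-η scan and is rejected there.

## Recommender

Per cell, the recommended regimen maximizes P(trough ∈ [5, 15] ng/ml)
(closed window; exceedance is strictly > 15), ties broken toward the
lower dose — conservative initial dosing, with safety reported
separately. An alternative constrained rule (maximize PTA subject to
P(>15) ≤ threshold) is available via `max_p_above`. Weight bands come
from a 1-kg scan: the breakpoint is the first weight at which the
recommendation changes, which is how breakpoints off the 10/20/30/40-kg
grid (e.g. 15, 17, 32 kg in the published table) can arise. Isolated
single-step flips of the recommendation are Monte Carlo jitter and are
smoothed by requiring a change to persist at least two consecutive scan
steps. Exceedance is reported per band as the maximum over scanned
weights at the band's dose (band endpoints are also reported, since a
printed "less than" bound could refer to either).

## Reproduction of the published table

Under the calibrated assumption the recommender reproduces the published
dose for most category/weight cells (A at 10–30 kg, B at 10 kg, C at
10 kg, D at 15–40 kg, and the overall category-D dose of 0.02 mg/kg/day),
and every computed exceedance probability at the recommended regimens
falls below the corresponding published bound. Two kinds of cell do not
reproduce under *any* ω in the calibration range, and
`reproduction_report` surfaces them with the best-achieving assumption
instead of passing silently:

- the heaviest-band doses for categories A and B (published 0.03 and
  0.04 at 32–40 kg; this package selects 0.02–0.03), and the HCT-30
  scenario's 40-kg dose. With any roughly log-symmetric trough
  distribution, the PTA-maximizing dose is the one whose typical trough
  is nearest the geometric window center (~8.7 ng/ml); the published
  heavy-weight doses place the typical day-8 trough well above it. The
  assumption set that produced those published cells (variability
  magnitudes, trough definition) is not recoverable from the printed
  information.
- band *boundaries* can differ by a few kg from the published ones even
  where the doses match; only the dose per tested cell is compared.

## Synthetic cohorts

`tacrodose.cohort` generates virtual covariate sets (uniform or
truncated-normal weight, fixed or uniform hematocrit, Bernoulli carrier
and voriconazole flags) and pseudo-TDM tables with one simulated trough
per patient and the ground-truth individual parameters retained. The
pediatric default mirrors the simulation scenario (10–40 kg, HCT 40,
POD 8); an adult-like spec covers the source model's ranges (32–75 kg,
HCT 18–41.7%). These fixtures emulate the statistical *structure* the
analysis assumes — they contain no real measurements, no covariate
correlations, no inter-occasion variability and no adherence or sampling-
time noise, so passing tests demonstrate internal consistency of the
simulator, not clinical validity.

## Problem sizes and numerics

The full simulation grid (4 categories × 4 weights × 14 regimens × 1,000
replicates = 224,000 troughs) is vectorized and runs in about a second;
calibration (16 ω values × 8 published bands × 1-kg scan × 1,000
replicates) takes a few seconds; the acceptance pipeline uses 1,000
replicates per regimen throughout. Probabilities are computed from
integer counts, which partition each sample exactly; their float
quotients sum to 1 within machine precision. Attainment uses closed
interval bounds so boundary troughs (exactly 5 or 15 ng/ml) count as
within-window.

## Known limitations

Pediatric use of an adult-derived model is an extrapolation; the model
has no CYP3A4 phenotype, no mechanistic hematocrit partitioning, no
two-compartment or transit-absorption variants, and the package performs
no estimation from concentration data and no Bayesian dose adaptation
after the initial dose.
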