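# tacrodose

Model-informed selection of the **initial tacrolimus dose** for pediatric
lung-transplant recipients with normal hematocrit, for pharmacometricians
and clinical pharmacologists who want a reproducible, testable version of
the Monte Carlo dose-finding workflow: a covariate-parameterized
population-pharmacokinetic model, a virtual-patient simulator,
probability-of-target-attainment (PTA) statistics, and a weight-band dose
recommender.

## The model

Apparent oral clearance and volume follow a published population-PK model
for tacrolimus in lung transplantation:

```
CL/F = 13.1 · (WT/70)^0.75 · (HCT/30)^-0.868 · (DD/3)^0.616 · (POD/30)^0.0807
            · 1.3^[CYP3A5*1 carrier] · 0.638^[voriconazole]      (L/h)
Vd/F = 636 · (WT/70)                                             (L)
```

with WT body weight (kg), HCT hematocrit (%), DD total daily dose (mg) —
a covariate as well as the administered amount — and POD the postoperative
day. Disposition is one-compartment with first-order absorption
(k_a = 4.48 h⁻¹, an assumption; see `docs/methods.md`) and elimination
k_e = CL/Vd. The trough before dose *n*+1 of a twice-daily regimen is the
closed-form superposition

```
C_min(n) = (D/Vd) · k_a/(k_a − k_e) · [ S_n(k_e) − S_n(k_a) ] · 1000  (ng/ml),
S_n(k) = e^{−kτ}(1 − e^{−nkτ})/(1 − e^{−kτ}),   τ = 12 h,
```

evaluated by default at *n* = 16 (day 8 after transplant, when troughs are
considered established clinically; the analytic *n* → ∞ steady state is
available as a sensitivity mode).

Virtual patients perturb CL/F and Vd/F lognormally
(CLᵢ = TVCL·e^η, η ~ N(0, ω²)). For each of four categories (CYP3A5*1
carrier × voriconazole co-therapy: A = neither, B = carrier, C =
voriconazole, D = both), each weight, and each of 14 regimens
(0.01–0.14 mg/kg/day, split into two doses), 1,000 replicates are
simulated; efficacy is P(trough ∈ [5, 15] ng/ml) and safety is
P(trough > 15 ng/ml). The recommended regimen maximizes the in-window
probability (ties to the lower dose); a 1-kg weight scan with common
random numbers merges into contiguous weight bands. Because the published
analysis does not print its variability magnitudes, ω_CL is calibrated by
grid search against the published per-band exceedance bounds
(`tacrodose.calibrate_omega`).

## Worked example

```python
from tacrodose import (CovariateSet, RegimenSpec, SimulationConfig,
                       build_recommendation_table, calibrate_omega,
                       predict_trough)

cov = CovariateSet(wt_kg=20, hct_pct=40, pod_days=8)
print(predict_trough(cov, RegimenSpec(0.02)))   # 10.35 ng/ml on day 8

config = SimulationConfig(n_replicates=1000, seed=1)
cal = calibrate_omega(config)                   # omega_cl = 0.25
table = build_recommendation_table(config, cal.variability)
print(table.to_frame())
```

which prints (seed 1):

```
category weight_band_kg  dose_mg_kg_day
       A          10-40            0.02
       B          10-35            0.02
       B          35-40            0.03
       C          10-30            0.01
       C          30-40            0.02
       D          10-15            0.01
       D          15-40            0.02
```

Read: a 20-kg non-carrier child without voriconazole (category A) starts
at 0.02 mg/kg/day split into two doses — its typical day-8 trough,
10.35 ng/ml, sits mid-window, and 97% of simulated patients attain the
window at that dose. Voriconazole co-therapy (C, D) lowers clearance and
therefore the recommended dose; CYP3A5*1 carriage (B, D) raises both.
The band-level worst-case exceedance probabilities (e.g. 8.4% for the
category-A band) come from `exceedance_report`; see
`examples/03_recommendation_table.py` for the full printed report, and
the other `examples/` scripts for the per-dose PTA table and the
synthetic-cohort fixtures.

The same pipelines are scriptable from the shell:

```
tacrodose simulate config.yaml -o run/     # raw troughs + attainment tables
tacrodose recommend config.yaml -o run/    # weight-band table + safety report
tacrodose calibrate config.yaml -o run/    # omega grid search
tacrodose plot run/                        # scatter / PTA / exceedance figures
```

where `config.yaml` is a flat key-value file (`hct_pct: 30` switches to
the low-hematocrit companion scenario). Every output directory archives
its config and a log of the seed and assumptions; re-running reproduces
the tables byte-for-byte.

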