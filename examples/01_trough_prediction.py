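"""Typical trough prediction for one virtual patient.

Builds the covariate model for a 20-kg child at hematocrit 40% on
postoperative day 8, and predicts the pre-dose (trough) concentration of
a 0.02 mg/kg/day twice-daily tacrolimus regimen, both after the 16 doses
actually given by day 8 and at the analytic steady state.
"""

from tacrodose import (
    CovariateSet,
    RegimenSpec,
    daily_dose,
    predict_trough,
    typical_clearance,
    typical_volume,
)

cov = CovariateSet(wt_kg=20, hct_pct=40, pod_days=8)
regimen = RegimenSpec(per_kg_daily_dose=0.02)

dd = daily_dose(regimen, cov.wt_kg)
cl = typical_clearance(cov, dd)
vd = typical_volume(cov)
print(f"daily dose      : {dd:.2f} mg ({regimen.dose_per_admin_mg(cov.wt_kg):.2f} mg per administration)")
print(f"typical CL/F    : {cl:.3f} L/h")
print(f"typical Vd/F    : {vd:.1f} L")
print(f"trough, day 8   : {predict_trough(cov, regimen, 'pod_accumulation'):.2f} ng/ml")
print(f"trough, steady  : {predict_trough(cov, regimen, 'steady_state'):.2f} ng/ml")
print()
print("The day-8 trough is what therapeutic drug monitoring would see on the")
print("postoperative day the analysis simulates; the long half-life means the")
print("analytic steady state lies noticeably higher.")
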