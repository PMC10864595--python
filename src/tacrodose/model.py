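"""Deterministic pharmacokinetic core.

A one-compartment model with first-order absorption and first-order
elimination, parameterized for oral tacrolimus in lung-transplant
recipients.  Apparent clearance (CL/F) follows a published covariate
model: allometric body weight (exponent 0.75), a negative power of
hematocrit (tacrolimus partitions into erythrocytes, so whole-blood
clearance falls as hematocrit rises), a positive power of the total
daily dose (dose-dependent apparent clearance), a weak power of the
postoperative day, a x1.3 factor for CYP3A5*1 carriers and a x0.638
factor under voriconazole co-therapy.  Apparent volume (Vd/F) is linear
in weight.

The absorption rate constant is not part of the covariate model; the
default of 4.48 1/h is a conventional fixed value for immediate-release
tacrolimus and is configurable through :class:`ModelDefinition`.

Troughs are pre-dose concentrations under repeated twice-daily dosing,
computed in closed form by geometric-series superposition of single-dose
profiles.  Concentrations are in ng/ml, doses in mg, volumes in L,
time in hours.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ModelDefinition",
    "DEFAULT_MODEL",
    "CovariateSet",
    "RegimenSpec",
    "StructuralParams",
    "typical_clearance",
    "typical_volume",
    "daily_dose",
    "trough_after_n_doses",
    "steady_state_trough",
    "predict_trough",
    "DEFAULT_DOSE_GRID",
]

#: The 14 per-kg daily-dose regimens scanned by the dose-finding analysis,
#: mg/kg/day, each split into two administrations.
DEFAULT_DOSE_GRID: tuple[float, ...] = tuple(round(0.01 * i, 2) for i in range(1, 15))

MG_PER_L_TO_NG_PER_ML = 1000.0


@dataclass(frozen=True)
class ModelDefinition:
    """Immutable constants of the covariate model.

    Kept in one record so an alternative published model can be swapped in
    without touching the simulation machinery.
    """

    cl_ref_l_h: float = 13.1        # CL/F at reference covariates, L/h
    wt_ref_kg: float = 70.0
    wt_exponent: float = 0.75       # allometric clearance exponent
    hct_ref_pct: float = 30.0
    hct_exponent: float = -0.868
    dd_ref_mg: float = 3.0
    dd_exponent: float = 0.616
    pod_ref_days: float = 30.0
    pod_exponent: float = 0.0807
    cyp3a5_factor: float = 1.3      # multiplies CL/F for CYP3A5*1 carriers
    voriconazole_factor: float = 0.638
    v_ref_l: float = 636.0          # Vd/F at 70 kg, L (linear in weight)
    ka_per_h: float = 4.48          # assumed absorption rate constant, 1/h


DEFAULT_MODEL = ModelDefinition()


@dataclass(frozen=True)
class CovariateSet:
    """One patient's covariates for the clearance/volume model."""

    wt_kg: float
    hct_pct: float = 40.0
    pod_days: float = 8.0
    cyp3a5_expresser: bool = False
    voriconazole: bool = False

    def __post_init__(self) -> None:
        if not self.wt_kg > 0:
            raise ValueError(f"wt_kg must be > 0, got {self.wt_kg}")
        if not self.hct_pct > 0:
            raise ValueError(f"hct_pct must be > 0, got {self.hct_pct}")
        if not self.pod_days > 0:
            raise ValueError(f"pod_days must be > 0, got {self.pod_days}")


@dataclass(frozen=True)
class RegimenSpec:
    """A twice-daily regimen expressed per kg of body weight per day.

    The daily dose (DD, mg) and per-administration dose are always derived
    from the current weight, never stored.
    """

    per_kg_daily_dose: float
    doses_per_day: int = 2
    interval_h: float = 12.0

    def __post_init__(self) -> None:
        if not self.per_kg_daily_dose > 0:
            raise ValueError("per_kg_daily_dose must be > 0")
        if self.doses_per_day != 2:
            raise ValueError("only twice-daily regimens are supported")
        if self.interval_h != 24.0 / self.doses_per_day:
            raise ValueError("interval_h must equal 24 / doses_per_day")

    def dd_mg(self, wt_kg: float) -> float:
        """Total daily dose in mg for a patient of the given weight."""
        return daily_dose(self, wt_kg)

    def dose_per_admin_mg(self, wt_kg: float) -> float:
        """Amount per administration in mg (DD split evenly, no rounding)."""
        return self.dd_mg(wt_kg) / self.doses_per_day


@dataclass(frozen=True)
class StructuralParams:
    """An individual's structural PK parameters."""

    cl_f: float        # apparent oral clearance, L/h
    vd_f: float        # apparent distribution volume, L
    ka_per_h: float = DEFAULT_MODEL.ka_per_h

    def __post_init__(self) -> None:
        if not (self.cl_f > 0 and self.vd_f > 0 and self.ka_per_h > 0):
            raise ValueError("cl_f, vd_f and ka_per_h must all be > 0")
        if self.ka_per_h <= self.kel_per_h:
            raise ValueError(
                f"ka ({self.ka_per_h}/h) must exceed kel "
                f"({self.kel_per_h:.4g}/h) for the standard parameterization"
            )

    @property
    def kel_per_h(self) -> float:
        """First-order elimination rate constant, CL/Vd, 1/h."""
        return self.cl_f / self.vd_f


def typical_clearance(
    cov: CovariateSet, dd_mg: float, model: ModelDefinition = DEFAULT_MODEL
) -> float:
    """Typical-value CL/F (L/h) from the covariate model.

    ``dd_mg`` is the total daily dose, which enters the clearance model as
    a covariate as well as being the administered amount.
    """
    if not dd_mg > 0:
        raise ValueError(f"dd_mg must be > 0, got {dd_mg}")
    cl = (
        model.cl_ref_l_h
        * (cov.wt_kg / model.wt_ref_kg) ** model.wt_exponent
        * (cov.hct_pct / model.hct_ref_pct) ** model.hct_exponent
        * (dd_mg / model.dd_ref_mg) ** model.dd_exponent
        * (cov.pod_days / model.pod_ref_days) ** model.pod_exponent
    )
    if cov.cyp3a5_expresser:
        cl *= model.cyp3a5_factor
    if cov.voriconazole:
        cl *= model.voriconazole_factor
    return cl


def typical_volume(cov: CovariateSet, model: ModelDefinition = DEFAULT_MODEL) -> float:
    """Typical-value Vd/F (L): linear in body weight."""
    return model.v_ref_l * (cov.wt_kg / model.wt_ref_kg)


def daily_dose(regimen: RegimenSpec, wt_kg: float) -> float:
    """Total daily dose DD (mg/day) = per-kg daily dose x weight."""
    if not wt_kg > 0:
        raise ValueError(f"wt_kg must be > 0, got {wt_kg}")
    return regimen.per_kg_daily_dose * wt_kg


def _trough_core(cl, vd, ka, dose_mg, interval_h, n_doses):
    """Vectorized trough after ``n_doses`` administrations.

    Superposition of one-compartment first-order-absorption profiles,
    summed in closed form as two geometric series (one per exponential).
    ``n_doses=None`` gives the infinite-dose (steady-state) limit.
    Returns ng/ml.
    """
    cl = np.asarray(cl, dtype=float)
    vd = np.asarray(vd, dtype=float)
    ka = np.asarray(ka, dtype=float)
    kel = cl / vd
    if np.any(kel >= ka):
        raise ValueError("ka must exceed kel for every individual")
    ek = np.exp(-kel * interval_h)
    ea = np.exp(-ka * interval_h)
    if n_doses is None:
        acc_k = ek / (1.0 - ek)
        acc_a = ea / (1.0 - ea)
    else:
        acc_k = ek * (1.0 - ek**n_doses) / (1.0 - ek)
        acc_a = ea * (1.0 - ea**n_doses) / (1.0 - ea)
    conc_mg_l = (dose_mg / vd) * (ka / (ka - kel)) * (acc_k - acc_a)
    return conc_mg_l * MG_PER_L_TO_NG_PER_ML


def trough_after_n_doses(
    params: StructuralParams,
    dose_per_admin_mg: float,
    interval_h: float,
    n_doses: int,
) -> float:
    """Concentration (ng/ml) immediately before dose ``n_doses + 1``.

    Evaluated at time ``n_doses * interval_h`` after the first dose.
    """
    if n_doses < 1:
        raise ValueError(f"n_doses must be >= 1, got {n_doses}")
    if dose_per_admin_mg < 0:
        raise ValueError("dose_per_admin_mg must be >= 0")
    return float(
        _trough_core(
            params.cl_f, params.vd_f, params.ka_per_h,
            dose_per_admin_mg, interval_h, n_doses,
        )
    )


def steady_state_trough(
    params: StructuralParams, dose_per_admin_mg: float, interval_h: float
) -> float:
    """Steady-state (infinite-dose limit) trough concentration, ng/ml."""
    if dose_per_admin_mg < 0:
        raise ValueError("dose_per_admin_mg must be >= 0")
    return float(
        _trough_core(
            params.cl_f, params.vd_f, params.ka_per_h,
            dose_per_admin_mg, interval_h, None,
        )
    )


def individual_params(
    cov: CovariateSet,
    regimen: RegimenSpec,
    model: ModelDefinition = DEFAULT_MODEL,
) -> StructuralParams:
    """Typical structural parameters for the given covariates and regimen."""
    dd = daily_dose(regimen, cov.wt_kg)
    return StructuralParams(
        cl_f=typical_clearance(cov, dd, model),
        vd_f=typical_volume(cov, model),
        ka_per_h=model.ka_per_h,
    )


def predict_trough(
    cov: CovariateSet,
    regimen: RegimenSpec,
    mode: str = "pod_accumulation",
    model: ModelDefinition = DEFAULT_MODEL,
    params: StructuralParams | None = None,
) -> float:
    """Trough prediction composing the covariate model and the dose profile.

    ``mode='pod_accumulation'`` accumulates 2 doses/day for ``pod_days``
    days (the clinically observed trough on that postoperative day);
    ``mode='steady_state'`` uses the analytic infinite-time limit.
    ``params`` overrides the typical individual (for sampled virtual
    patients).
    """
    if params is None:
        params = individual_params(cov, regimen, model)
    dose = regimen.dose_per_admin_mg(cov.wt_kg)
    if mode == "pod_accumulation":
        n_doses = int(round(cov.pod_days * regimen.doses_per_day))
        return trough_after_n_doses(params, dose, regimen.interval_h, n_doses)
    if mode == "steady_state":
        return steady_state_trough(params, dose, regimen.interval_h)
    raise ValueError(f"unknown mode {mode!r}")


def with_ka(model: ModelDefinition, ka_per_h: float) -> ModelDefinition:
    """A copy of ``model`` with a different absorption rate constant."""
    return replace(model, ka_per_h=ka_per_h)
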