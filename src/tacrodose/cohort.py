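"""Synthetic virtual cohorts and pseudo-TDM fixtures.

Generates covariate sets with the statistical structure the dose-finding
analysis assumes, so every downstream stage can be exercised without any
external data.  The pediatric default mirrors the simulation scenario
(uniform weight 10-40 kg, hematocrit fixed at 40%, postoperative day 8);
an adult-like spec covering the source model's covariate ranges
(32-75 kg, hematocrit 18-41.7%) is available for cross-checks.

``generate_pseudo_tdm`` produces one simulated trough per patient with
the ground-truth individual parameters retained alongside, enabling
recovery-style tests of the simulator.  It emulates the *shape* of an
observed therapeutic-drug-monitoring dataset, not any real measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_MODEL,
    CovariateSet,
    ModelDefinition,
    RegimenSpec,
    StructuralParams,
    daily_dose,
    predict_trough,
    typical_clearance,
    typical_volume,
)
from .simulate import VariabilityModel, draw_etas

__all__ = ["CohortSpec", "ADULT_SOURCE_SPEC", "generate_cohort", "generate_pseudo_tdm"]

#: Distribution specs are ("fixed", value), ("uniform", low, high) or
#: ("truncnorm", mean, sd, low, high).
Distribution = tuple


def _validate_distribution(name: str, dist: Distribution) -> None:
    kind = dist[0]
    if kind == "fixed":
        if len(dist) != 2 or dist[1] <= 0:
            raise ValueError(f"{name}: fixed distribution needs one positive value")
    elif kind == "uniform":
        if len(dist) != 3 or not 0 < dist[1] < dist[2]:
            raise ValueError(f"{name}: uniform bounds must be positive and ordered")
    elif kind == "truncnorm":
        if len(dist) != 5 or dist[2] <= 0 or not 0 < dist[3] < dist[4]:
            raise ValueError(f"{name}: truncnorm needs (mean, sd>0, low<high)")
    else:
        raise ValueError(f"{name}: unknown distribution kind {kind!r}")


def _draw(dist: Distribution, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "fixed":
        return np.full(n, float(dist[1]))
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], n)
    # truncated normal by rejection; the truncation ranges used here keep
    # the acceptance rate high
    mean, sd, lo, hi = dist[1:]
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, 2 * (n - filled) + 16)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


@dataclass(frozen=True)
class CohortSpec:
    """A virtual cohort's covariate distributions."""

    n_patients: int
    weight_distribution: Distribution = ("uniform", 10.0, 40.0)
    hct_distribution: Distribution = ("fixed", 40.0)
    expresser_fraction: float = 0.0
    voriconazole_fraction: float = 0.0
    pod_days: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.expresser_fraction <= 1:
            raise ValueError("expresser_fraction must be in [0, 1]")
        if not 0 <= self.voriconazole_fraction <= 1:
            raise ValueError("voriconazole_fraction must be in [0, 1]")
        if self.pod_days <= 0:
            raise ValueError("pod_days must be > 0")
        _validate_distribution("weight_distribution", self.weight_distribution)
        _validate_distribution("hct_distribution", self.hct_distribution)


#: Covariate ranges of the adult source population behind the model.
ADULT_SOURCE_SPEC = CohortSpec(
    n_patients=1000,
    weight_distribution=("uniform", 32.0, 75.0),
    hct_distribution=("uniform", 18.0, 41.7),
    expresser_fraction=0.3,
    voriconazole_fraction=0.2,
    pod_days=8.0,
)


def generate_cohort(spec: CohortSpec) -> list[CovariateSet]:
    """Draw ``n_patients`` covariate sets; reproducible under the seed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 271]))
    n = spec.n_patients
    wt = _draw(spec.weight_distribution, n, rng)
    hct = _draw(spec.hct_distribution, n, rng)
    expresser = rng.random(n) < spec.expresser_fraction
    vori = rng.random(n) < spec.voriconazole_fraction
    return [
        CovariateSet(
            wt_kg=float(wt[i]),
            hct_pct=float(hct[i]),
            pod_days=spec.pod_days,
            cyp3a5_expresser=bool(expresser[i]),
            voriconazole=bool(vori[i]),
        )
        for i in range(n)
    ]


def cohort_frame(patients: list[CovariateSet]) -> pd.DataFrame:
    """Tidy table of a cohort (column schema documented in the README)."""
    return pd.DataFrame(
        {
            "patient": np.arange(1, len(patients) + 1),
            "wt_kg": [p.wt_kg for p in patients],
            "hct_pct": [p.hct_pct for p in patients],
            "pod_days": [p.pod_days for p in patients],
            "cyp3a5_expresser": [p.cyp3a5_expresser for p in patients],
            "voriconazole": [p.voriconazole for p in patients],
        }
    )


def generate_pseudo_tdm(
    spec: CohortSpec,
    regimen: RegimenSpec,
    var: VariabilityModel,
    mode: str = "pod_accumulation",
    model: ModelDefinition = DEFAULT_MODEL,
) -> pd.DataFrame:
    """One simulated trough per patient, with ground truth retained.

    Columns: the covariates, the per-administration dose, the true
    individual CL/F and Vd/F, and the simulated trough (with residual
    error applied when sigma_prop > 0, floored at zero).
    """
    patients = generate_cohort(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 272]))
    eta_cl, eta_v = draw_etas(var, len(patients), rng)
    eps = (
        rng.normal(0.0, var.sigma_prop, len(patients))
        if var.sigma_prop > 0
        else np.zeros(len(patients))
    )
    rows = []
    for i, cov in enumerate(patients):
        dd = daily_dose(regimen, cov.wt_kg)
        params = StructuralParams(
            cl_f=typical_clearance(cov, dd, model) * float(np.exp(eta_cl[i])),
            vd_f=typical_volume(cov, model) * float(np.exp(eta_v[i])),
            ka_per_h=model.ka_per_h,
        )
        trough = predict_trough(cov, regimen, mode, model, params)
        trough = max(trough * (1.0 + eps[i]), 0.0)
        rows.append(
            {
                "patient": i + 1,
                "wt_kg": cov.wt_kg,
                "hct_pct": cov.hct_pct,
                "pod_days": cov.pod_days,
                "cyp3a5_expresser": cov.cyp3a5_expresser,
                "voriconazole": cov.voriconazole,
                "dose_mg_kg_day": regimen.per_kg_daily_dose,
                "dose_per_admin_mg": regimen.dose_per_admin_mg(cov.wt_kg),
                "cl_f_true": params.cl_f,
                "vd_f_true": params.vd_f,
                "trough_ng_ml": trough,
            }
        )
    return pd.DataFrame(rows)
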