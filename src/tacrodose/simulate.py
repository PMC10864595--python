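"""Monte Carlo virtual-patient engine.

Samples individuals around the typical covariate model with lognormal
inter-individual variability on CL/F and Vd/F and simulates trough
concentrations for every category x weight x regimen cell.

The four simulated patient categories cross CYP3A5*1 carrier status with
voriconazole co-therapy:

====  ==================  =============
name  CYP3A5*1 carrier    voriconazole
====  ==================  =============
A     no                  no
B     yes                 no
C     no                  yes
D     yes                 yes
====  ==================  =============

Randomness is organized as keyed substreams: each (category, weight,
dose) cell owns an independent stream derived from the master seed, so
cells are reproducible in isolation and adding or removing cells never
perturbs the others.  A common-random-numbers mode reuses one set of
individual deviations across the dose (and weight) grid for
variance-reduced comparisons.

The variability magnitudes are assumptions of this analysis, not outputs
of it: the defaults (omega_cl = 0.35, omega_v = 0.30, sigma_prop = 0)
are conventional moderate-IIV values, and :mod:`tacrodose.calibrate`
provides a grid search of omega_cl against published safety bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_DOSE_GRID,
    DEFAULT_MODEL,
    CovariateSet,
    ModelDefinition,
    RegimenSpec,
    StructuralParams,
    _trough_core,
    daily_dose,
    typical_clearance,
    typical_volume,
)

__all__ = [
    "VariabilityModel",
    "Category",
    "CATEGORIES",
    "SimulationConfig",
    "sample_individual",
    "simulate_cell",
    "simulate_grid",
    "cell_troughs",
    "draw_etas",
]

SAMPLE_COLUMNS = ["category", "wt_kg", "dose_mg_kg_day", "replicate", "trough_ng_ml"]


@dataclass(frozen=True)
class VariabilityModel:
    """Stochastic components applied around the typical individual.

    omega_* are SDs of normal deviations on the log scale (lognormal
    multiplicative IIV); sigma_prop is the SD of a proportional residual
    error applied to the simulated concentration (0 disables it).
    """

    omega_cl: float = 0.35
    omega_v: float = 0.30
    sigma_prop: float = 0.0

    def __post_init__(self) -> None:
        if self.omega_cl < 0 or self.omega_v < 0 or self.sigma_prop < 0:
            raise ValueError("variability SDs must be >= 0")


@dataclass(frozen=True)
class Category:
    label: str
    cyp3a5_expresser: bool
    voriconazole: bool


CATEGORIES: dict[str, Category] = {
    "A": Category("A", False, False),
    "B": Category("B", True, False),
    "C": Category("C", False, True),
    "D": Category("D", True, True),
}
_CATEGORY_INDEX = {label: i for i, label in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario definition for the dose-finding simulation."""

    n_replicates: int = 1000
    seed: int = 0
    dose_grid: tuple[float, ...] = DEFAULT_DOSE_GRID
    weight_grid: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0)
    weight_scan_step: float = 1.0
    mode: str = "pod_accumulation"
    hct_pct: float = 40.0
    pod_days: float = 8.0
    model: ModelDefinition = field(default=DEFAULT_MODEL)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        doses = tuple(self.dose_grid)
        if not doses or any(d <= 0 for d in doses):
            raise ValueError("dose_grid must be non-empty and positive")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("dose_grid must be strictly increasing")
        if not self.weight_grid or any(w <= 0 for w in self.weight_grid):
            raise ValueError("weight_grid must be non-empty and positive")
        if self.mode not in ("pod_accumulation", "steady_state"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def covariates(self, category: Category, wt_kg: float) -> CovariateSet:
        return CovariateSet(
            wt_kg=wt_kg,
            hct_pct=self.hct_pct,
            pod_days=self.pod_days,
            cyp3a5_expresser=category.cyp3a5_expresser,
            voriconazole=category.voriconazole,
        )

    @property
    def n_doses(self) -> int | None:
        """Number of accumulated doses, or None for the steady-state limit."""
        if self.mode == "steady_state":
            return None
        return int(round(self.pod_days * 2))


def _cell_seed_seq(seed: int, category: Category, wt_kg: float | None,
                   dose_index: int | None) -> np.random.SeedSequence:
    """Stable substream key for a simulation cell.

    ``None`` components are omitted from the key, which is how common
    random numbers across doses (and weights) are obtained.
    """
    key = [int(seed), _CATEGORY_INDEX[category.label]]
    if wt_kg is not None:
        key.append(int(round(wt_kg * 1000)))
    if dose_index is not None:
        key.append(1_000_000 + int(dose_index))
    return np.random.SeedSequence(key)


def draw_etas(
    var: VariabilityModel, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (eta_cl, eta_v): independent N(0, omega^2) log-scale deviations."""
    return (
        rng.normal(0.0, var.omega_cl, n) if var.omega_cl > 0 else np.zeros(n),
        rng.normal(0.0, var.omega_v, n) if var.omega_v > 0 else np.zeros(n),
    )


def sample_individual(
    cov: CovariateSet,
    regimen: RegimenSpec,
    var: VariabilityModel,
    rng: np.random.Generator,
    model: ModelDefinition = DEFAULT_MODEL,
) -> StructuralParams:
    """One virtual individual: CL_i = TVCL e^eta1, Vd_i = TVV e^eta2.

    ka is not perturbed.
    """
    dd = daily_dose(regimen, cov.wt_kg)
    eta_cl, eta_v = draw_etas(var, 1, rng)
    return StructuralParams(
        cl_f=typical_clearance(cov, dd, model) * float(np.exp(eta_cl[0])),
        vd_f=typical_volume(cov, model) * float(np.exp(eta_v[0])),
        ka_per_h=model.ka_per_h,
    )


def cell_troughs(
    category: Category,
    wt_kg: float,
    per_kg_daily_dose: float,
    var: VariabilityModel,
    config: SimulationConfig,
    etas: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Simulated troughs (ng/ml) for one cell, as a length-n array.

    ``etas`` supplies pre-drawn deviations for common-random-number
    comparisons; by default the cell draws from its own keyed substream.
    Residual error, if enabled, multiplies by (1 + eps) and floors at 0.
    """
    regimen = RegimenSpec(per_kg_daily_dose)
    cov = config.covariates(category, wt_kg)
    dd = daily_dose(regimen, wt_kg)
    tvcl = typical_clearance(cov, dd, config.model)
    tvv = typical_volume(cov, config.model)

    if etas is None:
        dose_index = (
            config.dose_grid.index(per_kg_daily_dose)
            if per_kg_daily_dose in config.dose_grid
            else int(round(per_kg_daily_dose * 10000))
        )
        rng = np.random.default_rng(
            _cell_seed_seq(config.seed, category, wt_kg, dose_index)
        )
        eta_cl, eta_v = draw_etas(var, config.n_replicates, rng)
    else:
        eta_cl, eta_v = etas
        rng = None

    cl = tvcl * np.exp(eta_cl)
    vd = tvv * np.exp(eta_v)
    troughs = _trough_core(
        cl, vd, config.model.ka_per_h,
        regimen.dose_per_admin_mg(wt_kg), regimen.interval_h, config.n_doses,
    )
    if var.sigma_prop > 0:
        if rng is None:
            raise ValueError(
                "residual error needs a cell-owned stream; "
                "pass sigma_prop=0 when supplying etas"
            )
        eps = rng.normal(0.0, var.sigma_prop, troughs.shape)
        troughs = np.maximum(troughs * (1.0 + eps), 0.0)
    return troughs


def simulate_cell(
    category: Category,
    wt_kg: float,
    regimen: RegimenSpec,
    var: VariabilityModel,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Simulate one cell and return a tidy table of replicates."""
    troughs = cell_troughs(category, wt_kg, regimen.per_kg_daily_dose, var, config)
    return pd.DataFrame(
        {
            "category": category.label,
            "wt_kg": wt_kg,
            "dose_mg_kg_day": regimen.per_kg_daily_dose,
            "replicate": np.arange(1, config.n_replicates + 1),
            "trough_ng_ml": troughs,
        }
    )


def simulate_grid(config: SimulationConfig, var: VariabilityModel) -> pd.DataFrame:
    """All categories x weights x regimens, ``n_replicates`` troughs each.

    Each cell draws from its own keyed substream, so the result for any
    cell is independent of which other cells are simulated.
    """
    frames = [
        simulate_cell(category, wt, RegimenSpec(dose), var, config)
        for category in CATEGORIES.values()
        for wt in config.weight_grid
        for dose in config.dose_grid
    ]
    return pd.concat(frames, ignore_index=True)[SAMPLE_COLUMNS]
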