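"""Target-attainment statistics and the weight-band dose recommender.

Efficacy is the probability that a simulated trough lies inside the
therapeutic window (closed interval, default 5-15 ng/ml); safety is the
probability of exceeding the upper limit (strictly > 15 ng/ml).  The
recommended regimen for a cell is the grid dose maximizing the in-window
probability, with ties broken toward the lower dose (conservative
initial dosing; safety is reported separately).  An optional constrained
rule restricts the argmax to doses whose exceedance stays below a
threshold.

Weight bands are found by scanning weight at a fine step (default 1 kg)
with common random numbers across weights and doses, then merging
consecutive weights that share a recommended dose.  Isolated
single-step flips of the recommendation (Monte Carlo jitter) are
smoothed away by requiring a change to persist for at least two
consecutive scan steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import (
    CATEGORIES,
    Category,
    SimulationConfig,
    VariabilityModel,
    cell_troughs,
    draw_etas,
    _cell_seed_seq,
)

__all__ = [
    "TherapeuticWindow",
    "AttainmentSummary",
    "RecommendationEntry",
    "attainment",
    "attainment_table",
    "select_regimen",
    "scan_weights",
    "weight_breakpoints",
    "exceedance_report",
    "build_recommendation_table",
    "RecommendationTable",
]


@dataclass(frozen=True)
class TherapeuticWindow:
    lower_ng_ml: float = 5.0
    upper_ng_ml: float = 15.0

    def __post_init__(self) -> None:
        if not 0 < self.lower_ng_ml < self.upper_ng_ml:
            raise ValueError("window must satisfy 0 < lower < upper")


@dataclass(frozen=True)
class AttainmentSummary:
    """Window-attainment fractions for one (category, weight, dose) cell.

    The counts partition the sample exactly (n_below + n_within + n_above
    = n); the fractions are their float quotients.
    """

    category: str
    wt_kg: float
    per_kg_daily_dose: float
    p_below: float
    p_within: float
    p_above: float
    n: int
    n_below: int = 0
    n_within: int = 0
    n_above: int = 0


@dataclass(frozen=True)
class RecommendationEntry:
    """One weight band of the recommendation table."""

    category: str
    weight_low_kg: float
    weight_high_kg: float
    dose_mg_kg_day: float


def attainment(
    troughs,
    window: TherapeuticWindow,
    category: str = "",
    wt_kg: float = float("nan"),
    per_kg_daily_dose: float = float("nan"),
) -> AttainmentSummary:
    """Partition a cell's troughs into below / within / above the window.

    The window is closed: boundary values count as within.  Counts
    partition the sample, so the three fractions sum to 1 exactly.
    """
    t = np.asarray(troughs, dtype=float)
    if t.size == 0:
        raise ValueError("attainment needs a non-empty sample")
    n = t.size
    n_above = int(np.count_nonzero(t > window.upper_ng_ml))
    n_within = int(
        np.count_nonzero((t >= window.lower_ng_ml) & (t <= window.upper_ng_ml))
    )
    n_below = n - n_within - n_above
    return AttainmentSummary(
        category, wt_kg, per_kg_daily_dose,
        n_below / n, n_within / n, n_above / n, n,
        n_below, n_within, n_above,
    )


def attainment_table(samples: pd.DataFrame, window: TherapeuticWindow) -> pd.DataFrame:
    """Per-cell attainment summaries from a tidy replicate table."""
    rows = []
    for (cat, wt, dose), grp in samples.groupby(
        ["category", "wt_kg", "dose_mg_kg_day"], sort=True
    ):
        s = attainment(grp["trough_ng_ml"].to_numpy(), window, cat, wt, dose)
        rows.append(s.__dict__)
    return pd.DataFrame(rows)


def select_regimen(
    summaries: list[AttainmentSummary],
    dose_grid: tuple[float, ...] | None = None,
    max_p_above: float | None = None,
) -> float:
    """Dose maximizing p_within; ties break toward the lowest dose.

    ``max_p_above`` activates the constrained rule: only doses with
    p_above <= threshold compete (falling back to the unconstrained
    argmax if no dose qualifies).
    """
    if not summaries:
        raise ValueError("no summaries supplied")
    by_dose = sorted(summaries, key=lambda s: s.per_kg_daily_dose)
    doses = [s.per_kg_daily_dose for s in by_dose]
    if len(set(doses)) != len(doses):
        raise ValueError("duplicate doses in summaries")
    if dose_grid is not None and tuple(doses) != tuple(dose_grid):
        raise ValueError("summaries do not cover the dose grid exactly")
    pool = by_dose
    if max_p_above is not None:
        feasible = [s for s in by_dose if s.p_above <= max_p_above]
        if feasible:
            pool = feasible
    best = max(pool, key=lambda s: s.p_within)
    # ties toward the lowest dose: max() keeps the first maximum, and the
    # pool is sorted ascending by dose
    return best.per_kg_daily_dose


def _scan_summaries(
    category: Category,
    weights: np.ndarray,
    config: SimulationConfig,
    var: VariabilityModel,
    window: TherapeuticWindow,
) -> dict[float, list[AttainmentSummary]]:
    """Attainment at every (weight, dose), common random numbers throughout.

    One set of eta draws, keyed by category alone, is reused across every
    weight and dose of the scan, so dose and weight comparisons are made
    on the same virtual individuals.
    """
    if var.sigma_prop > 0:
        raise ValueError("the common-random-number scan requires sigma_prop = 0")
    rng = np.random.default_rng(_cell_seed_seq(config.seed, category, None, None))
    etas = draw_etas(var, config.n_replicates, rng)
    out: dict[float, list[AttainmentSummary]] = {}
    for wt in weights:
        out[float(wt)] = [
            attainment(
                cell_troughs(category, float(wt), dose, var, config, etas=etas),
                window, category.label, float(wt), dose,
            )
            for dose in config.dose_grid
        ]
    return out


def scan_weights(
    category: Category,
    config: SimulationConfig,
    var: VariabilityModel,
    window: TherapeuticWindow,
    weight_range: tuple[float, float] = (10.0, 40.0),
    max_p_above: float | None = None,
) -> pd.DataFrame:
    """Optimal regimen at each scanned weight (before band merging)."""
    lo, hi = weight_range
    weights = np.arange(lo, hi + 1e-9, config.weight_scan_step)
    summaries = _scan_summaries(category, weights, config, var, window)
    rows = []
    for wt in weights:
        cell = summaries[float(wt)]
        dose = select_regimen(cell, config.dose_grid, max_p_above)
        best = next(s for s in cell if s.per_kg_daily_dose == dose)
        rows.append(
            {
                "category": category.label,
                "wt_kg": float(wt),
                "dose_mg_kg_day": dose,
                "p_within": best.p_within,
                "p_above": best.p_above,
            }
        )
    return pd.DataFrame(rows)


def _smooth_flips(doses: list[float]) -> tuple[list[float], int]:
    """Remove recommendation changes that do not persist >= 2 scan steps."""
    out = list(doses)
    n_smoothed = 0
    for i in range(1, len(out)):
        if out[i] != out[i - 1] and (i + 1 == len(out) or out[i + 1] != out[i]):
            out[i] = out[i - 1]
            n_smoothed += 1
    return out, n_smoothed


def weight_breakpoints(
    category: Category,
    config: SimulationConfig,
    var: VariabilityModel,
    window: TherapeuticWindow,
    weight_range: tuple[float, float] = (10.0, 40.0),
    max_p_above: float | None = None,
) -> list[RecommendationEntry]:
    """Contiguous weight bands sharing a recommended dose over the scan.

    A band boundary is the first scanned weight at which the (smoothed)
    recommendation changes; bands partition the scan range.
    """
    scan = scan_weights(category, config, var, window, weight_range, max_p_above)
    weights = scan["wt_kg"].tolist()
    doses, _ = _smooth_flips(scan["dose_mg_kg_day"].tolist())
    entries: list[RecommendationEntry] = []
    band_lo = weights[0]
    for i in range(1, len(weights)):
        if doses[i] != doses[i - 1]:
            entries.append(
                RecommendationEntry(category.label, band_lo, weights[i], doses[i - 1])
            )
            band_lo = weights[i]
    entries.append(RecommendationEntry(category.label, band_lo, weights[-1], doses[-1]))
    return entries


def exceedance_report(
    category: Category,
    entries: list[RecommendationEntry],
    config: SimulationConfig,
    var: VariabilityModel,
    window: TherapeuticWindow = TherapeuticWindow(),
) -> pd.DataFrame:
    """Per-band safety: max exceedance over the band at the band's dose.

    Returns one row per band with the maximum over scanned weights of
    P(trough > upper limit), plus the same probability at the band's
    endpoints for reference.
    """
    rows = []
    for e in entries:
        weights = np.arange(
            e.weight_low_kg, e.weight_high_kg + 1e-9, config.weight_scan_step
        )
        p_above = []
        for wt in weights:
            t = cell_troughs(category, float(wt), e.dose_mg_kg_day, var, config)
            p_above.append(attainment(t, window).p_above)
        p_above = np.asarray(p_above)
        rows.append(
            {
                "category": e.category,
                "weight_low_kg": e.weight_low_kg,
                "weight_high_kg": e.weight_high_kg,
                "dose_mg_kg_day": e.dose_mg_kg_day,
                "max_p_above": float(p_above.max()),
                "argmax_wt_kg": float(weights[int(p_above.argmax())]),
                "p_above_at_low": float(p_above[0]),
                "p_above_at_high": float(p_above[-1]),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RecommendationTable:
    """Band lists for all four categories, Table-style serializable."""

    entries: dict[str, list[RecommendationEntry]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, cat in CATEGORIES.items():
            for e in self.entries[label]:
                rows.append(
                    {
                        "category": label,
                        "cyp3a5_carrier": cat.cyp3a5_expresser,
                        "voriconazole": cat.voriconazole,
                        "weight_band_kg": f"{e.weight_low_kg:g}-{e.weight_high_kg:g}",
                        "dose_mg_kg_day": e.dose_mg_kg_day,
                    }
                )
        return pd.DataFrame(rows)


def build_recommendation_table(
    config: SimulationConfig,
    var: VariabilityModel,
    window: TherapeuticWindow = TherapeuticWindow(),
    weight_range: tuple[float, float] = (10.0, 40.0),
    max_p_above: float | None = None,
) -> RecommendationTable:
    """Weight-band recommendations for all four categories."""
    return RecommendationTable(
        {
            label: weight_breakpoints(
                cat, config, var, window, weight_range, max_p_above
            )
            for label, cat in CATEGORIES.items()
        }
    )
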