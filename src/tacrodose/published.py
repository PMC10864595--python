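"""Published reference results used for calibration and validation.

The published model-based analysis of initial tacrolimus dosing in
pediatric lung transplantation at normal hematocrit (40%) reports a
weight-band dose table for the four CYP3A5 x voriconazole categories,
and, for each band, an upper bound on the probability that a trough
exceeds 15 ng/ml.  Because that analysis does not print the variability
magnitudes behind its Monte Carlo runs, these printed results serve two
roles here: the exceedance bounds are the calibration target for the
inter-individual variability assumption, and the dose table is the
benchmark the reproduction report compares against.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PublishedBand", "PUBLISHED_BANDS", "published_band_for"]


@dataclass(frozen=True)
class PublishedBand:
    category: str          # A-D, CYP3A5 carrier x voriconazole crossing
    weight_low_kg: float
    weight_high_kg: float
    dose_mg_kg_day: float
    exceedance_bound_pct: float   # printed "less than" bound on P(>15 ng/ml)


#: Published recommendation bands at hematocrit 40%, postoperative day 8.
PUBLISHED_BANDS: tuple[PublishedBand, ...] = (
    PublishedBand("A", 10, 32, 0.02, 21.5),
    PublishedBand("A", 32, 40, 0.03, 11.5),
    PublishedBand("B", 10, 15, 0.02, 6.5),
    PublishedBand("B", 15, 32, 0.03, 13.5),
    PublishedBand("B", 32, 40, 0.04, 4.5),
    PublishedBand("C", 10, 17, 0.01, 11.0),
    PublishedBand("C", 17, 40, 0.02, 31.0),
    PublishedBand("D", 10, 40, 0.02, 28.4),
)


def published_band_for(category: str, wt_kg: float) -> PublishedBand:
    """The published band containing a weight (upper edges inclusive)."""
    cands = [b for b in PUBLISHED_BANDS if b.category == category]
    for b in cands:
        if b.weight_low_kg <= wt_kg < b.weight_high_kg:
            return b
    last = cands[-1]
    if wt_kg == last.weight_high_kg:
        return last
    raise ValueError(f"no published band for category {category} at {wt_kg} kg")
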