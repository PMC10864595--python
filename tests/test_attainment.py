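"""Attainment statistics, dose selection, weight bands, exceedance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tacrodose import (
    CATEGORIES,
    AttainmentSummary,
    CovariateSet,
    RegimenSpec,
    SimulationConfig,
    TherapeuticWindow,
    VariabilityModel,
    attainment,
    build_recommendation_table,
    cell_troughs,
    exceedance_report,
    predict_trough,
    select_regimen,
    weight_breakpoints,
)
from tacrodose.attainment import scan_weights


class TestAttainment:
    def test_all_within(self, window):
        s = attainment([6, 10, 14.9], window)
        assert (s.p_below, s.p_within, s.p_above) == (0.0, 1.0, 0.0)

    def test_direct_counts(self, window):
        s = attainment([4, 6, 16, 10], window)
        assert (s.p_below, s.p_within, s.p_above) == (0.25, 0.5, 0.25)

    def test_closed_interval_boundaries(self, window):
        """5 and 15 ng/ml count as within; exceedance is strictly > 15."""
        s = attainment([5.0, 15.0], window)
        assert s.p_within == 1.0 and s.p_above == 0.0

    def test_empty_rejected(self, window):
        with pytest.raises(ValueError):
            attainment([], window)

    @given(
        st.lists(st.floats(0.0, 40.0, allow_nan=False), min_size=1, max_size=200)
    )
    @settings(max_examples=100, deadline=None)
    def test_partition_sums_to_one(self, troughs):
        s = attainment(troughs, TherapeuticWindow())
        # counts partition the sample exactly; fractions to float precision
        assert s.n_below + s.n_within + s.n_above == s.n
        assert s.p_below + s.p_within + s.p_above == pytest.approx(1.0, abs=1e-12)
        assert 0 <= s.p_below <= 1 and 0 <= s.p_within <= 1 and 0 <= s.p_above <= 1


def _summaries(pw, pa=None):
    pa = pa or {d: 0.0 for d in pw}
    return [
        AttainmentSummary("A", 20.0, d, 1 - w - pa[d], w, pa[d], 1000)
        for d, w in pw.items()
    ]


class TestSelectRegimen:
    def test_argmax(self):
        assert select_regimen(_summaries({0.01: 0.4, 0.02: 0.7, 0.03: 0.6})) == 0.02

    def test_tie_breaks_to_lower_dose(self):
        assert select_regimen(_summaries({0.01: 0.4, 0.02: 0.7, 0.03: 0.7})) == 0.02

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            select_regimen(
                _summaries({0.01: 0.4, 0.02: 0.7}), dose_grid=(0.01, 0.02, 0.03)
            )

    def test_constrained_rule_respects_exceedance_cap(self):
        s = _summaries({0.01: 0.5, 0.02: 0.8}, {0.01: 0.01, 0.02: 0.3})
        assert select_regimen(s, max_p_above=0.1) == 0.01

    def test_zero_variability_unique_in_window_dose(self, window):
        """With variability off, the one dose whose typical trough lands
        in-window wins with p_within 1 vs 0."""
        cfg = SimulationConfig(n_replicates=50, seed=0)
        var = VariabilityModel(0, 0, 0)
        cat = CATEGORIES["A"]
        summaries = [
            attainment(
                cell_troughs(cat, 10.0, d, var, cfg), window, "A", 10.0, d
            )
            for d in cfg.dose_grid
        ]
        in_window = [s for s in summaries if s.p_within == 1.0]
        assert in_window, "at least one typical trough lies in the window"
        assert select_regimen(summaries) == min(
            s.per_kg_daily_dose for s in in_window
        )


def _brute_force_dose(cat, wt, cfg, window):
    """Independent typical-value optimum: lowest grid dose whose typical
    trough lies inside the window (all p_within ties at 1), else the
    lowest dose (all tie at 0)."""
    cov = CovariateSet(wt, cfg.hct_pct, cfg.pod_days,
                       cat.cyp3a5_expresser, cat.voriconazole)
    in_window = [
        d for d in cfg.dose_grid
        if window.lower_ng_ml
        <= predict_trough(cov, RegimenSpec(d), cfg.mode)
        <= window.upper_ng_ml
    ]
    return min(in_window) if in_window else cfg.dose_grid[0]


class TestWeightBands:
    def test_zero_variability_matches_brute_force(self, window):
        """The full recommender at omega=0 equals an exhaustive scan of the
        deterministic typical-value surface, at 0.5-kg resolution."""
        cfg = SimulationConfig(n_replicates=10, seed=0, weight_scan_step=0.5)
        var = VariabilityModel(0, 0, 0)
        for label in ("A", "D"):
            cat = CATEGORIES[label]
            entries = weight_breakpoints(cat, cfg, var, window)
            for wt in np.arange(10.0, 40.01, 0.5):
                expected = _brute_force_dose(cat, float(wt), cfg, window)
                band = next(
                    e for e in entries
                    if e.weight_low_kg <= wt <= e.weight_high_kg
                    and (wt < e.weight_high_kg or e is entries[-1]
                         or wt == e.weight_low_kg)
                )
                assert band.dose_mg_kg_day == expected, (label, wt)

    def test_bands_contiguous_and_cover_range(self, small_config,
                                              moderate_variability, window):
        for cat in CATEGORIES.values():
            entries = weight_breakpoints(cat, small_config, moderate_variability,
                                         window)
            assert entries[0].weight_low_kg == 10.0
            assert entries[-1].weight_high_kg == 40.0
            for a, b in zip(entries, entries[1:]):
                assert a.weight_high_kg == b.weight_low_kg
                assert a.dose_mg_kg_day != b.dose_mg_kg_day

    def test_doses_are_grid_members(self, small_config, moderate_variability,
                                    window):
        for cat in CATEGORIES.values():
            for e in weight_breakpoints(cat, small_config, moderate_variability,
                                        window):
                assert e.dose_mg_kg_day in small_config.dose_grid


class TestExceedance:
    def test_zero_variability_in_window_gives_zero(self, window):
        cfg = SimulationConfig(n_replicates=10, seed=0, weight_scan_step=2.0)
        var = VariabilityModel(0, 0, 0)
        entries = weight_breakpoints(CATEGORIES["A"], cfg, var, window)
        report = exceedance_report(CATEGORIES["A"], entries, cfg, var, window)
        assert len(report) == len(entries)
        # the deterministic recommender only picks in-window doses here
        assert (report["max_p_above"] == 0.0).all()

    def test_exceedance_monotone_in_dose_with_crn(self, small_config, window):
        """With common random numbers, P(>15) never falls as dose rises."""
        var = VariabilityModel(0.35, 0.30, 0.0)
        scan = scan_weights(CATEGORIES["A"], small_config, var, window,
                            weight_range=(20.0, 20.0))
        # recompute the full dose profile at 20 kg with shared etas
        from tacrodose.simulate import draw_etas, _cell_seed_seq

        rng = np.random.default_rng(
            _cell_seed_seq(small_config.seed, CATEGORIES["A"], None, None)
        )
        etas = draw_etas(var, small_config.n_replicates, rng)
        p_above = [
            attainment(
                cell_troughs(CATEGORIES["A"], 20.0, d, var, small_config,
                             etas=etas),
                window,
            ).p_above
            for d in small_config.dose_grid
        ]
        assert all(b >= a for a, b in zip(p_above, p_above[1:]))
        assert scan is not None


@pytest.fixture(scope="module")
def table(small_config, moderate_variability, window):
    return build_recommendation_table(small_config, moderate_variability, window)


class TestRecommendationTable:
    def test_four_categories(self, table):
        assert set(table.entries) == {"A", "B", "C", "D"}
        frame = table.to_frame()
        assert frame["category"].nunique() == 4

    @staticmethod
    def _dose_at(entries, wt):
        for e in entries:
            if e.weight_low_kg <= wt < e.weight_high_kg:
                return e.dose_mg_kg_day
        return entries[-1].dose_mg_kg_day

    @pytest.mark.parametrize("wt", [10.0, 20.0, 30.0, 40.0])
    def test_voriconazole_never_raises_recommended_dose(self, table, wt):
        assert self._dose_at(table.entries["C"], wt) <= self._dose_at(
            table.entries["A"], wt
        )
        assert self._dose_at(table.entries["D"], wt) <= self._dose_at(
            table.entries["B"], wt
        )

    @pytest.mark.parametrize("wt", [10.0, 20.0, 30.0, 40.0])
    def test_carrier_never_lowers_recommended_dose(self, table, wt):
        assert self._dose_at(table.entries["B"], wt) >= self._dose_at(
            table.entries["A"], wt
        )
        assert self._dose_at(table.entries["D"], wt) >= self._dose_at(
            table.entries["C"], wt
        )

    def test_dose_non_decreasing_in_weight(self, table):
        for entries in table.entries.values():
            doses = [e.dose_mg_kg_day for e in entries]
            assert doses == sorted(doses)
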