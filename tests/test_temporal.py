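"""Creation-year dynamics: cumulative series, eligibility, rates."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from settlecarbon import temporal
from settlecarbon.synth import default_carbon_table
from settlecarbon.temporal import (AnnualSeries, Period, cumulative_cleared,
                                   eligibility_filter, forest_accounting,
                                   mean_annual_rate, per_family_rate)

TABLE = default_carbon_table()


def _frag(final_class, area_ha, year=None, carbon_class=1, sid="A", reclassified=False):
    return {"settlement_id": sid, "final_class": final_class, "prodes_year": year,
            "reclassified": reclassified, "carbon_class": carbon_class,
            "area_ha": area_ha, "geometry": box(0, 0, 1, 1)}


def _settlement(sid="A", creation=2003, families=100, group="traditional",
                in_arc=True):
    return pd.Series({"settlement_id": sid, "creation_year": creation,
                      "families": families, "group": group, "in_arc": in_arc,
                      "category": "PA"})


class TestCumulative:
    def test_no_deforestation_is_zero_everywhere(self):
        frags = pd.DataFrame([_frag("FOREST", 100.0)])
        for y in (2000, 2005, 2013):
            assert cumulative_cleared(frags, y) == 0.0

    def test_inclusive_year_convention(self):
        frags = pd.DataFrame([_frag("DEF_PRODES", 500.0, 2001),
                              _frag("DEF_PRODES", 700.0, 2003)])
        assert cumulative_cleared(frags, 2002) == pytest.approx(5.0)
        assert cumulative_cleared(frags, 2003) == pytest.approx(12.0)

    def test_before_baseline_returns_baseline(self):
        frags = pd.DataFrame([_frag("DEF_PRODES", 500.0, 2001)])
        assert cumulative_cleared(frags, 1995) == 0.0

    def test_reclassified_clearing_never_in_annual_series(self):
        frags = pd.DataFrame([_frag("DEF_PRODES", 500.0, None, reclassified=True)])
        assert cumulative_cleared(frags, 2013) == 0.0

    def test_matches_bruteforce_sum(self):
        rng = np.random.default_rng(17)
        years = rng.integers(2001, 2014, size=30)
        areas = rng.uniform(10, 800, size=30)
        frags = pd.DataFrame([_frag("DEF_PRODES", a, int(y))
                              for y, a in zip(years, areas)])
        for probe in (2001, 2004, 2009, 2013):
            brute = sum(a for y, a in zip(years, areas) if y <= probe) / 100.0
            assert cumulative_cleared(frags, probe) == pytest.approx(brute)


class TestEligibility:
    def _registry(self, rows):
        df = pd.DataFrame(rows)
        df["creation_year"] = df["creation_year"].astype("Int64")
        df["families"] = df["families"].astype("Int64")
        return df

    def test_window_and_pmdbbs_rules(self):
        reg = self._registry([
            {"settlement_id": "A", "creation_year": 1999, "families": 10},
            {"settlement_id": "B", "creation_year": 2003, "families": 10},
            {"settlement_id": "C", "creation_year": 2003, "families": 10},
            {"settlement_id": "D", "creation_year": pd.NA, "families": 10},
        ])
        frags = pd.DataFrame([_frag("CLEAR_PMDBBS", 10.0, sid="C"),
                              _frag("FOREST", 10.0, sid="B")])
        keep, log = eligibility_filter(reg, frags, "pre_post")
        assert list(keep["settlement_id"]) == ["B"]
        reasons = dict(zip(log["settlement_id"], log["reason"]))
        assert reasons["A"] == "creation_year_outside_window"
        assert reasons["C"] == "pmdbbs_clearing_present"
        assert reasons["D"] == "creation_year_absent"

    def test_family_mode_needs_family_count_and_forest(self):
        reg = self._registry([
            {"settlement_id": "A", "creation_year": 2005, "families": pd.NA},
            {"settlement_id": "B", "creation_year": 2005, "families": 40},
            {"settlement_id": "C", "creation_year": 2005, "families": 40},
        ])
        frags = pd.DataFrame([_frag("FOREST", 10.0, sid="B")])
        series = {"B": AnnualSeries("B", {}, 1.0, 1.0),
                  "C": AnnualSeries("C", {2003: 1.0}, 1.0, 0.0)}
        keep, log = eligibility_filter(reg, frags, "family", series)
        assert list(keep["settlement_id"]) == ["B"]
        reasons = dict(zip(log["settlement_id"], log["reason"]))
        assert reasons["A"] == "families_absent"
        assert reasons["C"] == "fully_cleared_before_creation"


class TestForestAccounting:
    def test_untouched_forest(self):
        frags = pd.DataFrame([_frag("FOREST", 10_000.0)])
        s = forest_accounting(_settlement(creation=2004), frags, TABLE)
        assert s.original_forest_km2 == pytest.approx(100.0)
        assert s.forest_at_creation_km2 == pytest.approx(100.0)

    def test_precreation_clearing_subtracted(self):
        frags = pd.DataFrame([_frag("FOREST", 9000.0),
                              _frag("DEF_PRODES", 1000.0, 2003)])
        s = forest_accounting(_settlement(creation=2003), frags, TABLE)
        assert s.original_forest_km2 == pytest.approx(100.0)
        assert s.forest_at_creation_km2 == pytest.approx(90.0)

    def test_nonforest_carbon_class_not_original_forest(self):
        # clearing over savanna-class vegetation is not lost *forest*
        frags = pd.DataFrame([_frag("FOREST", 9000.0),
                              _frag("DEF_PRODES", 1000.0, 2005, carbon_class=3)])
        s = forest_accounting(_settlement(creation=2003), frags, TABLE)
        assert s.original_forest_km2 == pytest.approx(90.0)

    def test_matches_generator_truth(self, dataset, fragments):
        eligible, _ = eligibility_filter(dataset.registry, fragments, "pre_post")
        series = temporal.build_series(eligible, fragments, dataset.carbon_table)
        for sid, s in series.items():
            assert s.original_forest_km2 == pytest.approx(
                dataset.truth.original_forest_km2[sid], abs=1e-9)
            assert s.forest_at_creation_km2 == pytest.approx(
                dataset.truth.forest_at_creation_km2[sid], abs=1e-9)


class TestRates:
    def test_first_period_mean(self):
        s = AnnualSeries("A", {2003: 10.0, 2004: 10.0, 2005: 10.0}, 100.0)
        rec = mean_annual_rate(s, 2002, Period.POSTCREATION_TO_2005)
        assert rec["mean_rate_km2_per_yr"] == pytest.approx(10.0)
        assert rec["n_years"] == 3

    def test_second_period_zero_over_eight_years(self):
        s = AnnualSeries("A", {2003: 10.0}, 100.0)
        rec = mean_annual_rate(s, 2002, Period.Y2006_TO_2013)
        assert rec["mean_rate_km2_per_yr"] == 0.0
        assert rec["n_years"] == 8

    def test_empty_period_rejected(self):
        s = AnnualSeries("A", {}, 100.0)
        with pytest.raises(ValueError):
            mean_annual_rate(s, 2005, Period.POSTCREATION_TO_2005)

    def test_matches_bruteforce_increment_mean(self):
        rng = np.random.default_rng(23)
        inc = {int(y): float(rng.uniform(0, 5)) for y in range(2001, 2014)}
        s = AnnualSeries("A", inc, 500.0)
        rec = mean_annual_rate(s, 2002, Period.POSTCREATION_TO_2005)
        brute = np.mean([inc[y] for y in (2003, 2004, 2005)])
        assert rec["mean_rate_km2_per_yr"] == pytest.approx(brute)

    def test_split_periods_recombine_exactly(self):
        """Year-weighted average of the two period rates equals the rate over
        the whole span."""
        rng = np.random.default_rng(29)
        inc = {int(y): float(rng.uniform(0, 5)) for y in range(2001, 2014)}
        s = AnnualSeries("A", inc, 500.0)
        r1 = mean_annual_rate(s, 2002, Period.POSTCREATION_TO_2005)
        r2 = mean_annual_rate(s, 2002, Period.Y2006_TO_2013)
        rall = mean_annual_rate(s, 2002, Period.POSTCREATION_TO_2013)
        recombined = (
            r1["mean_rate_km2_per_yr"] * r1["n_years"]
            + r2["mean_rate_km2_per_yr"] * r2["n_years"]
        ) / (r1["n_years"] + r2["n_years"])
        assert recombined == pytest.approx(rall["mean_rate_km2_per_yr"], rel=1e-12)


class TestFamilyRate:
    def test_window_rate(self):
        s = AnnualSeries("A", {2004: 2.0, 2006: 3.0}, 100.0)  # 500 ha in window
        rec = per_family_rate(_settlement(creation=2003, families=100), s)
        assert rec["rate_ha_per_family_per_yr"] == pytest.approx(1.0)

    def test_zero_clearing_is_zero(self):
        s = AnnualSeries("A", {}, 100.0)
        rec = per_family_rate(_settlement(creation=2003, families=100), s)
        assert rec["rate_ha_per_family_per_yr"] == 0.0

    def test_clearing_outside_window_ignored(self):
        # creation-year and post-window increments must not count
        s = AnnualSeries("A", {2003: 5.0, 2009: 7.0}, 100.0)
        rec = per_family_rate(_settlement(creation=2003, families=100), s)
        assert rec["rate_ha_per_family_per_yr"] == 0.0

    def test_zero_families_is_error(self):
        s = AnnualSeries("A", {}, 100.0)
        with pytest.raises(ValueError):
            per_family_rate(_settlement(families=0), s)
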