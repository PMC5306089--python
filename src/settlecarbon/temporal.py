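"""Clearing dynamics relative to settlement creation year.

The annual deforestation layer labels each clearing increment with a nominal
year (an August→July observation window); "cleared through year *y*" is the
cumulative area of increments with nominal year ≤ *y*, inclusive — a
settlement created early or late in the calendar year is treated the same.
Pre-baseline clearing (mapped before the first annual map) carries the
earliest nominal label present in the data; it counts toward pre-creation
clearing, never toward post-creation rates.

Analyses: original vs at-creation forest for settlements created 2000–2008,
period-stratified mean annual clearing rates (to 2005 vs 2006–2013), and
per-family clearing over the 5 years after creation, stratified by membership
in the arc of deforestation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .geodata import CarbonClassTable
from .reconcile import FinalClass

CREATION_WINDOW = (2000, 2008)   # eligible creation years
RATE_SPLIT_YEAR = 2006           # high-rate period ends 2005, slowdown starts 2006
LAST_YEAR = 2013                 # last nominal year of the annual data
FAMILY_WINDOW_YEARS = 5


class Period(str, Enum):
    POSTCREATION_TO_2005 = "postcreation_to_2005"
    Y2006_TO_2013 = "y2006_to_2013"
    POSTCREATION_TO_2013 = "postcreation_to_2013"


@dataclass
class AnnualSeries:
    """Cumulative cleared km² by nominal year for one settlement."""

    settlement_id: str
    increments_km2: dict[int, float] = field(default_factory=dict)
    original_forest_km2: float = 0.0
    forest_at_creation_km2: float = 0.0

    def cumulative(self, year: int) -> float:
        """Cumulative cleared km² through ``year`` (inclusive).  Years before
        the earliest mapped year return the (empty) baseline cumulative."""
        return sum(a for y, a in self.increments_km2.items() if y <= year)


def cumulative_cleared(fragments: pd.DataFrame, year: int) -> float:
    """Cumulative annual-deforestation area (km²) through nominal ``year``
    for the fragments of one settlement.  Reclassified clearing carries no
    nominal year and never enters the annual series."""
    mask = (
        (fragments["final_class"] == FinalClass.DEF_PRODES.value)
        & ~fragments["reclassified"].fillna(False).astype(bool)
        & fragments["prodes_year"].notna()
        & (fragments["prodes_year"].astype(float) <= year)
    )
    return float(fragments.loc[mask, "area_ha"].sum()) / 100.0


def annual_increments(fragments: pd.DataFrame) -> dict[int, float]:
    mask = (
        (fragments["final_class"] == FinalClass.DEF_PRODES.value)
        & ~fragments["reclassified"].fillna(False).astype(bool)
        & fragments["prodes_year"].notna()
    )
    grp = fragments.loc[mask].groupby("prodes_year")["area_ha"].sum() / 100.0
    return {int(y): float(a) for y, a in grp.items()}


def eligibility_filter(
    registry: pd.DataFrame,
    fragments: pd.DataFrame,
    mode: str,
    series_by_id: dict[str, AnnualSeries] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict to settlements the pre/post-creation analysis can use.

    ``pre_post`` keeps settlements created in the 2000–2008 window with no
    savanna-clearing fragments (those lack annual resolution).  ``family``
    additionally requires a family count and some forest left at creation.
    Returns (eligible registry rows, exclusion log).
    """
    if mode not in ("pre_post", "family"):
        raise ValueError(f"unknown eligibility mode {mode!r}")
    has_pmdbbs = set(
        fragments.loc[
            (fragments["final_class"] == FinalClass.CLEAR_PMDBBS.value)
            | fragments["reclassified"].fillna(False).astype(bool),
            "settlement_id",
        ]
    )
    keep, log = [], []
    for _, row in registry.iterrows():
        sid = row["settlement_id"]
        cy = row["creation_year"]
        if pd.isna(cy):
            log.append({"settlement_id": sid, "reason": "creation_year_absent"})
            continue
        if not (CREATION_WINDOW[0] <= int(cy) <= CREATION_WINDOW[1]):
            log.append({"settlement_id": sid, "reason": "creation_year_outside_window"})
            continue
        if sid in has_pmdbbs:
            log.append({"settlement_id": sid, "reason": "pmdbbs_clearing_present"})
            continue
        if mode == "family":
            if pd.isna(row["families"]) or int(row["families"]) == 0:
                log.append({"settlement_id": sid, "reason": "families_absent"})
                continue
            if series_by_id is not None:
                s = series_by_id.get(sid)
                if s is not None and s.forest_at_creation_km2 <= 0:
                    log.append({"settlement_id": sid, "reason": "fully_cleared_before_creation"})
                    continue
        keep.append(row)
    return pd.DataFrame(keep).reset_index(drop=True), pd.DataFrame(
        log, columns=["settlement_id", "reason"]
    )


def forest_accounting(
    settlement: pd.Series,
    fragments: pd.DataFrame,
    carbon_table: CarbonClassTable,
) -> AnnualSeries:
    """Original total forest and forest remaining at official creation.

    Original forest = current forest + cloud + cleared area whose original
    vegetation class is a forest type.  Forest at creation = original −
    cumulative cleared through the creation year; a negative remainder marks
    inconsistent data and raises.
    """
    sid = settlement["settlement_id"]
    forest_classes = set(
        carbon_table.table.loc[carbon_table.table["is_forest"], "class_id"]
    )
    fmask = fragments["final_class"].isin(
        [FinalClass.FOREST.value, FinalClass.CLOUD.value]
    )
    dmask = (
        (fragments["final_class"] == FinalClass.DEF_PRODES.value)
        & ~fragments["reclassified"].fillna(False).astype(bool)
        & fragments["carbon_class"].isin(forest_classes)
    )
    original = float(fragments.loc[fmask | dmask, "area_ha"].sum()) / 100.0
    series = AnnualSeries(
        settlement_id=sid,
        increments_km2=annual_increments(fragments),
        original_forest_km2=original,
    )
    cy = int(settlement["creation_year"])
    at_creation = original - series.cumulative(cy)
    if at_creation < -1e-9:
        raise ValueError(
            f"settlement {sid}: cleared-through-creation exceeds original forest"
        )
    series.forest_at_creation_km2 = max(at_creation, 0.0)
    return series


def mean_annual_rate(series: AnnualSeries, creation_year: int, period: Period):
    """Mean clearing rate (km²/yr) over a study period.

    Periods: from 1 year after creation to 2005; 2006–2013; or, for
    settlements created 2006–2008, from 1 year after creation to 2013.
    Raises on an empty period (creation at/after the period end).
    """
    if period == Period.POSTCREATION_TO_2005:
        start, end = creation_year + 1, RATE_SPLIT_YEAR - 1
    elif period == Period.Y2006_TO_2013:
        start, end = RATE_SPLIT_YEAR, LAST_YEAR
    else:
        start, end = creation_year + 1, LAST_YEAR
    if start > end:
        raise ValueError(
            f"empty rate period {period.value} for creation year {creation_year}"
        )
    n_years = end - start + 1
    rate = (series.cumulative(end) - series.cumulative(start - 1)) / n_years
    return {
        "settlement_id": series.settlement_id,
        "period": period.value,
        "mean_rate_km2_per_yr": rate,
        "n_years": n_years,
    }


def per_family_rate(settlement: pd.Series, series: AnnualSeries) -> dict:
    """Mean clearing per family (ha/family/yr) over the 5 years after creation."""
    families = settlement["families"]
    if pd.isna(families) or int(families) == 0:
        raise ValueError(
            f"settlement {settlement['settlement_id']}: family count absent or zero"
        )
    cy = int(settlement["creation_year"])
    cleared_ha = (series.cumulative(cy + FAMILY_WINDOW_YEARS) - series.cumulative(cy)) * 100.0
    return {
        "settlement_id": settlement["settlement_id"],
        "group": settlement["group"],
        "in_arc": bool(settlement["in_arc"]),
        "rate_ha_per_family_per_yr": cleared_ha / int(families) / FAMILY_WINDOW_YEARS,
    }


# ---------------------------------------------------------------------------
# cohort-level drivers


def build_series(
    registry: pd.DataFrame, fragments: pd.DataFrame, carbon_table: CarbonClassTable
) -> dict[str, AnnualSeries]:
    out = {}
    for _, row in registry.iterrows():
        frg = fragments[fragments["settlement_id"] == row["settlement_id"]]
        out[row["settlement_id"]] = forest_accounting(row, frg, carbon_table)
    return out


def period_rates(
    registry: pd.DataFrame, series_by_id: dict[str, AnnualSeries]
) -> pd.DataFrame:
    """Two-period rates for settlements created 2000–2004 (both periods) and
    the post-creation-to-2013 rate for 2006–2008 creations."""
    rows = []
    for _, row in registry.iterrows():
        cy = int(row["creation_year"])
        s = series_by_id[row["settlement_id"]]
        if cy <= RATE_SPLIT_YEAR - 2:  # created 2000–2004: two-period comparison
            for period in (Period.POSTCREATION_TO_2005, Period.Y2006_TO_2013):
                rec = mean_annual_rate(s, cy, period)
                rec.update(category=row["category"], group=row["group"])
                rows.append(rec)
        elif cy >= RATE_SPLIT_YEAR:
            rec = mean_annual_rate(s, cy, Period.POSTCREATION_TO_2013)
            rec.update(category=row["category"], group=row["group"])
            rows.append(rec)
    return pd.DataFrame(rows)


def group_rate_ratio(rates: pd.DataFrame, period: Period) -> float:
    """Traditional / environmentally-distinctive mean-rate ratio for a period."""
    sub = rates[rates["period"] == period.value]
    means = sub.groupby("group")["mean_rate_km2_per_yr"].mean()
    return float(means["traditional"] / means["environmentally_distinctive"])


def family_rates(
    registry: pd.DataFrame, series_by_id: dict[str, AnnualSeries]
) -> pd.DataFrame:
    rows = [
        per_family_rate(row, series_by_id[row["settlement_id"]])
        for _, row in registry.iterrows()
    ]
    return pd.DataFrame(rows)


def family_rate_summary(frates: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd of per-family clearing by (group, arc membership)."""
    return (
        frates.groupby(["group", "in_arc"])["rate_ha_per_family_per_yr"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
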