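"""Summary tables, shares, ratios and threshold censuses.

All percentages go through :func:`share` and all "X times higher" figures
through :func:`ratio`, both with round-half-away-from-zero — the rounding
convention the published category tables follow.  Aggregation happens at full
precision; rounding is applied only to the emitted numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from .reconcile import FinalClass


@dataclass(frozen=True)
class RegionReference:
    """Region-wide published denominators, supplied by configuration.

    Defaults are the Legal Amazonia reference values used for the settlement
    shares; none of them is consulted by any computation path — only by the
    report layer.
    """

    total_clearing_km2: float = 967_003.0
    prodes_total_clearing_km2: float = 758_638.0
    total_C_loss_Pg: float = 13.1
    remaining_C_Pg: float = 58.6
    premodern_C_Pg: float = 71.7
    region_area_km2: float = 5_068_433.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegionReference":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (1.5 → 2, −1.5 → −2)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def share(numerator: float, denominator: float, rounding: str = "integer-percent") -> float:
    """Percentage 100·num/den with the requested report rounding."""
    if denominator == 0:
        raise ZeroDivisionError("share() denominator is zero")
    pct = 100.0 * numerator / denominator
    return round_half_away(pct, 0 if rounding == "integer-percent" else 1)


def ratio(a: float, b: float) -> float:
    """a/b to 1 decimal (round half away from zero)."""
    if b == 0:
        raise ZeroDivisionError("ratio() divisor is zero")
    return round_half_away(a / b, 1)


# ---------------------------------------------------------------------------
# tables


def landcover_table(accounts: pd.DataFrame) -> pd.DataFrame:
    """Per-category land-cover area table (km², 1 decimal) + Total row.

    Columns: annual (PRODES-style) deforestation, savanna (PMDBBS-style)
    clearing including reclassified hydro-over-clearing, their total, forest,
    non-forest, clouds, water, and the analysed total.  Excluded classes are
    not part of the analysed area.
    """
    if accounts.empty:
        raise ValueError("landcover_table needs at least one account")
    acc = accounts.copy()
    km = lambda col: acc[col] / 100.0
    t = pd.DataFrame({
        "category": acc["category"],
        "prodes_deforestation_km2":
            km("area_DEF_PRODES_ha") - km("area_reclassified_ha"),
        "pmdbbs_clearing_km2":
            km("area_CLEAR_PMDBBS_ha") + km("area_reclassified_ha"),
    })
    t["total_deforestation_km2"] = (
        t["prodes_deforestation_km2"] + t["pmdbbs_clearing_km2"]
    )
    t["forest_km2"] = km("area_FOREST_ha")
    t["nonforest_km2"] = km("area_NONFOREST_ha")
    t["clouds_km2"] = km("area_CLOUD_ha")
    t["water_km2"] = km("area_WATER_ha")
    t["total_km2"] = (
        t["total_deforestation_km2"] + t["forest_km2"] + t["nonforest_km2"]
        + t["clouds_km2"] + t["water_km2"]
    )
    num = t.columns.drop("category")
    out = t.groupby("category", sort=True)[num].sum().reset_index()
    total = out[num].sum().to_frame().T
    total.insert(0, "category", "Total")
    out = pd.concat([out, total], ignore_index=True)
    out[num] = out[num].map(lambda v: round_half_away(v, 1))
    return out


def exclusions_table(accounts: pd.DataFrame) -> pd.DataFrame:
    """Initial / excluded / updated analysed area per category (km²).

    Excluded = urban + off-register hydrography; updated = initial − excluded.
    Percent excluded is relative to the initial area, to 1 decimal.
    """
    if accounts.empty:
        raise ValueError("exclusions_table needs at least one account")
    acc = accounts.copy()
    area_cols = [f"area_{fc.value}_ha" for fc in FinalClass]
    acc["initial_km2"] = acc[area_cols].sum(axis=1) / 100.0
    acc["excluded_km2"] = (
        acc["area_EXCLUDED_HYDRO_ha"] + acc["area_EXCLUDED_URBAN_ha"]
    ) / 100.0
    grp = acc.groupby("category", sort=True)[["initial_km2", "excluded_km2"]].sum()
    total = grp.sum().to_frame().T
    total.index = ["Total"]
    grp = pd.concat([grp, total])
    grp["updated_km2"] = grp["initial_km2"] - grp["excluded_km2"]
    grp["excluded_pct"] = [
        share(e, i, rounding="1-decimal") if i > 0 else 0.0
        for e, i in zip(grp["excluded_km2"], grp["initial_km2"])
    ]
    for c in ("initial_km2", "excluded_km2", "updated_km2"):
        grp[c] = grp[c].map(lambda v: round_half_away(v, 1))
    return grp.reset_index(names="category")


def cleared_fraction(account: pd.Series) -> float:
    """Cleared share of original vegetation (analysed area minus water)."""
    cleared = account["area_DEF_PRODES_ha"] + account["area_CLEAR_PMDBBS_ha"]
    denom = (
        cleared + account["area_FOREST_ha"] + account["area_NONFOREST_ha"]
        + account["area_CLOUD_ha"]
    )
    if denom <= 0:
        return 0.0
    return cleared / denom


def threshold_census(accounts: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Counts of settlements with cleared fraction = 0, ≥ 50 % (inclusive) and
    = 100 % of original vegetation, by category and state.

    Fractions are computed before any rounding; "fully cleared" means no
    vegetation fragment remains (fraction = 1 within 1e-9).
    """
    acc = accounts.copy()
    acc["cleared_fraction"] = acc.apply(cleared_fraction, axis=1)
    cleared_area = acc["area_DEF_PRODES_ha"] + acc["area_CLEAR_PMDBBS_ha"]
    acc["census_zero"] = cleared_area == 0
    acc["census_half"] = acc["cleared_fraction"] >= 0.5
    acc["census_full"] = acc["cleared_fraction"] >= 1.0 - 1e-9
    out = {}
    for name in ("census_zero", "census_half", "census_full"):
        by_cat = acc.groupby("category")[name].sum().astype(int)
        by_state = acc.groupby("state")[name].sum().astype(int)
        out[name] = pd.DataFrame({
            "key": list(by_cat.index) + list(by_state.index) + ["total"],
            "kind": ["category"] * len(by_cat) + ["state"] * len(by_state) + ["total"],
            "count": list(by_cat) + list(by_state) + [int(acc[name].sum())],
        })
    return out


def region_shares(landcover_total: pd.Series, carbon_total: pd.Series,
                  ref: RegionReference) -> dict[str, float]:
    """Headline shares of the settlement totals in the region-wide reference."""
    return {
        "share_of_region_area_pct": share(
            landcover_total["total_km2"], ref.region_area_km2),
        "share_of_total_clearing_pct": share(
            landcover_total["total_deforestation_km2"], ref.total_clearing_km2),
        "share_of_prodes_clearing_pct": share(
            landcover_total["prodes_deforestation_km2"], ref.prodes_total_clearing_km2),
        "share_of_carbon_loss_pct": share(
            carbon_total["lost_MgC"] / 1e9, ref.total_C_loss_Pg),
        "share_of_remaining_carbon_pct": share(
            carbon_total["remaining_MgC"] / 1e9, ref.remaining_C_Pg),
        "share_of_premodern_carbon_pct": share(
            carbon_total["premodern_MgC"] / 1e9, ref.premodern_C_Pg),
    }
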