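"""Settlement-layer cleaning: filtering and one-polygon-per-settlement resolution.

The raw settlement map may contain features outside the study region,
non-settlement categories, settlements absent from the registry, and
settlements represented by several polygons (duplicates, satellites mapped in
the wrong municipality, or genuine splits).  Cleaning filters the layer and
collapses each kept settlement to exactly one polygon, logging a
:class:`CleaningDecision` for every input feature so the log partitions the
input.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .geodata import CATEGORIES, area_ha


class Action(str, Enum):
    KEPT = "kept"
    DROPPED_OUTSIDE_REGION = "dropped_outside_region"
    DROPPED_NOT_IN_REGISTRY = "dropped_not_in_registry"
    DROPPED_NON_SETTLEMENT = "dropped_non_settlement"
    POLYGON_DEDUPLICATED = "polygon_deduplicated"
    POLYGON_DROPPED_WRONG_MUNICIPALITY = "polygon_dropped_wrong_municipality"
    POLYGON_SELECTED_CLOSEST_AREA = "polygon_selected_closest_area"
    POLYGONS_MERGED = "polygons_merged"


@dataclass
class CleaningDecision:
    settlement_id: str
    action: Action
    detail: str = ""


#: symmetric-difference area below which two polygons count as congruent (ha)
CONGRUENCE_HA = 1e-6


def filter_settlements(
    layer: pd.DataFrame,
    registry: pd.DataFrame,
    region_boundary: BaseGeometry,
    allowed_categories=frozenset(CATEGORIES),
) -> tuple[pd.DataFrame, list[CleaningDecision]]:
    """Keep settlements 100 % inside the region, of an allowed category, and
    listed in the registry.  Order-independent; an empty result is legal."""
    decisions: list[CleaningDecision] = []
    registry_ids = set(registry["settlement_id"])
    keep_mask = []
    # evaluate containment per settlement on the union of its features
    union_by_id = {
        sid: shapely.union_all(list(grp["geometry"]))
        for sid, grp in layer.groupby("settlement_id")
    }
    for _, row in layer.iterrows():
        sid = row["settlement_id"]
        if row["category"] not in allowed_categories:
            decisions.append(
                CleaningDecision(sid, Action.DROPPED_NON_SETTLEMENT, f"category={row['category']}")
            )
            keep_mask.append(False)
        elif not region_boundary.covers(union_by_id[sid]):
            decisions.append(CleaningDecision(sid, Action.DROPPED_OUTSIDE_REGION))
            keep_mask.append(False)
        elif sid not in registry_ids:
            decisions.append(CleaningDecision(sid, Action.DROPPED_NOT_IN_REGISTRY))
            keep_mask.append(False)
        else:
            keep_mask.append(True)
    return layer.loc[keep_mask].reset_index(drop=True), decisions


def resolve_multipolygons(
    polygons: list[tuple[str, BaseGeometry, str]],
    reported_area_ha: float,
    official_municipality: str,
) -> tuple[BaseGeometry | None, list[CleaningDecision], str]:
    """Collapse the features of one settlement to a single geometry.

    ``polygons`` is a list of (feature_id, geometry, declared municipality).
    In order: (1) drop features declared in a municipality other than the
    official one; (2) among congruent duplicates keep one; (3) merge all if
    the summed area is at least as close to the reported area as any single
    polygon, else keep the polygon whose area is closest (ties: larger area,
    then lexicographically first feature id).

    Returns (geometry or None, decisions, settlement_id placeholder-free);
    geometry is None when no polygon survives step (1) — the settlement is
    flagged and excluded.
    """
    if not polygons:
        raise ValueError("resolve_multipolygons needs at least one polygon")
    decisions: list[CleaningDecision] = []
    sid = polygons[0][0].split("#")[0]

    survivors = []
    for fid, geom, muni in polygons:
        if muni != official_municipality:
            decisions.append(
                CleaningDecision(sid, Action.POLYGON_DROPPED_WRONG_MUNICIPALITY,
                                 f"feature={fid} municipality={muni}")
            )
        else:
            survivors.append((fid, geom))
    if not survivors:
        return None, decisions, sid

    # (2) deduplicate congruent polygons (symmetric difference ≤ CONGRUENCE_HA)
    deduped: list[tuple[str, BaseGeometry]] = []
    for fid, geom in sorted(survivors, key=lambda t: t[0]):
        dup = False
        for kfid, kept in deduped:
            if area_ha(kept.symmetric_difference(geom)) <= CONGRUENCE_HA:
                decisions.append(
                    CleaningDecision(sid, Action.POLYGON_DEDUPLICATED,
                                     f"feature={fid} congruent_with={kfid}")
                )
                dup = True
                break
        if not dup:
            deduped.append((fid, geom))

    if len(deduped) == 1:
        fid, geom = deduped[0]
        decisions.append(CleaningDecision(sid, Action.KEPT, f"feature={fid}"))
        return geom, decisions, sid

    # (3) merge-vs-closest by distance to the reported area
    areas = [(fid, geom, area_ha(geom)) for fid, geom in deduped]
    sum_area = sum(a for _, _, a in areas)
    best_single = min(abs(a - reported_area_ha) for _, _, a in areas)
    if abs(sum_area - reported_area_ha) <= best_single:
        merged = shapely.union_all([g for _, g, _ in areas])
        decisions.append(
            CleaningDecision(sid, Action.POLYGONS_MERGED,
                             f"n={len(areas)} sum_area_ha={sum_area:.4f}")
        )
        return merged, decisions, sid
    # closest single; ties → larger area, then lexicographic feature id
    chosen = min(areas, key=lambda t: (abs(t[2] - reported_area_ha), -t[2], t[0]))
    for fid, _, a in areas:
        if fid != chosen[0]:
            decisions.append(
                CleaningDecision(sid, Action.POLYGON_SELECTED_CLOSEST_AREA,
                                 f"dropped feature={fid} area_ha={a:.4f}")
            )
    decisions.append(CleaningDecision(sid, Action.KEPT, f"feature={chosen[0]}"))
    return chosen[1], decisions, sid


def clean_settlements(
    layer: pd.DataFrame,
    registry: pd.DataFrame,
    region_boundary: BaseGeometry,
    allowed_categories=frozenset(CATEGORIES),
) -> tuple[pd.DataFrame, list[CleaningDecision]]:
    """Full cleaning pass: filter, then resolve each settlement to one polygon.

    Returns a DataFrame with one row per kept settlement (registry attributes
    joined, geometry column) plus the complete decision log.
    """
    kept, decisions = filter_settlements(layer, registry, region_boundary, allowed_categories)
    rows = []
    for sid, grp in kept.groupby("settlement_id", sort=True):
        reg = registry.loc[registry["settlement_id"] == sid].iloc[0]
        polys = [
            (str(row.get("feature_id", f"{sid}#{i}")), row["geometry"],
             row.get("municipality", reg["municipality"]))
            for i, (_, row) in enumerate(grp.iterrows())
        ]
        geom, dec, _ = resolve_multipolygons(
            polys, float(reg["reported_area_ha"]), reg["municipality"]
        )
        decisions.extend(dec)
        if geom is None:
            continue
        rec = reg.to_dict()
        rec["geometry"] = geom
        rec["area_ha"] = area_ha(geom)
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["crs"] = layer.attrs.get("crs")
    return out, decisions


def decisions_frame(decisions: list[CleaningDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"settlement_id": d.settlement_id, "action": d.action.value, "detail": d.detail}
         for d in decisions],
        columns=["settlement_id", "action", "detail"],
    )
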