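"""Multi-source land-cover reconciliation.

Clips the forest-biome monitoring layer (classes forest / non-forest /
hydrography / cloud / annual deforestation), the savanna clearing layer
(single clearing class) and the vegetation-carbon map (vegetation classes +
hydrography + urban) to the cleaned settlements, unions them into atomic
fragments, and assigns each fragment exactly one final class under explicit
precedence rules:

1. carbon-map urban            → EXCLUDED_URBAN (dropped from all analysis)
2. carbon-map hydrography      → WATER (zero carbon, stays in the area total)
3. monitor hydrography over savanna clearing → DEF_PRODES, reclassified flag
   (no nominal year; counted with the savanna clearing total in reports)
4. monitor hydrography         → EXCLUDED_HYDRO (off-register river pixels)
5. annual deforestation        → DEF_PRODES(nominal year) — annual data wins
6. savanna clearing            → CLEAR_PMDBBS (its 2 ha minimum mapping unit
   sees clearings the forest monitor misses)
7. forest / cloud / non-forest → FOREST / CLOUD / NONFOREST

Clouds are retained and carbon-bearing: cloud-covered cells were mapped as
forest in earlier years.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
import shapely
from shapely import STRtree
from shapely.geometry.base import BaseGeometry
from shapely.ops import polygonize

from .geodata import area_ha

#: fragments smaller than this (ha) are dissolved into a neighbour
DEFAULT_SLIVER_HA = 1e-4

PRODES_CLASSES = ("forest", "nonforest", "hydro", "cloud", "deforestation")


class FinalClass(str, Enum):
    DEF_PRODES = "DEF_PRODES"
    CLEAR_PMDBBS = "CLEAR_PMDBBS"
    FOREST = "FOREST"
    NONFOREST = "NONFOREST"
    CLOUD = "CLOUD"
    WATER = "WATER"
    EXCLUDED_HYDRO = "EXCLUDED_HYDRO"
    EXCLUDED_URBAN = "EXCLUDED_URBAN"


#: classes whose area counts as cleared
CLEARED_CLASSES = (FinalClass.DEF_PRODES, FinalClass.CLEAR_PMDBBS)
#: classes whose area counts as remaining vegetation
REMAINING_CLASSES = (FinalClass.FOREST, FinalClass.NONFOREST, FinalClass.CLOUD)
#: classes excluded from the analysed (updated) area
EXCLUDED_CLASSES = (FinalClass.EXCLUDED_HYDRO, FinalClass.EXCLUDED_URBAN)


class CoverageGapError(ValueError):
    """A fragment carries no attribute from any source layer."""


def assign_final_class(
    prodes_class: str | None,
    prodes_year: int | None,
    pmdbbs_clearing: bool,
    carbon_class,
    hydro_class_id=None,
    urban_class_id=None,
) -> tuple[FinalClass, int | None, bool]:
    """Decision table, first match wins.  Returns (class, nominal year,
    reclassified-clearing flag)."""
    if carbon_class is not None and urban_class_id is not None and carbon_class == urban_class_id:
        return FinalClass.EXCLUDED_URBAN, None, False
    if carbon_class is not None and hydro_class_id is not None and carbon_class == hydro_class_id:
        return FinalClass.WATER, None, False
    if prodes_class == "hydro":
        if pmdbbs_clearing:
            return FinalClass.DEF_PRODES, None, True
        return FinalClass.EXCLUDED_HYDRO, None, False
    if prodes_class == "deforestation":
        return FinalClass.DEF_PRODES, prodes_year, False
    if pmdbbs_clearing:
        return FinalClass.CLEAR_PMDBBS, None, False
    if prodes_class == "forest":
        return FinalClass.FOREST, None, False
    if prodes_class == "cloud":
        return FinalClass.CLOUD, None, False
    if prodes_class == "nonforest":
        return FinalClass.NONFOREST, None, False
    raise CoverageGapError("fragment carries no source-layer attribute")


def _polygonal(geom: BaseGeometry) -> BaseGeometry:
    """Keep only the areal part of a geometry (drop lines/points)."""
    if geom.is_empty:
        return geom
    if geom.geom_type in ("Polygon", "MultiPolygon"):
        return geom
    if geom.geom_type == "GeometryCollection":
        parts = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        return shapely.union_all(parts) if parts else shapely.Polygon()
    return shapely.Polygon()


def clip_to_settlements(layer: pd.DataFrame, settlements: pd.DataFrame) -> pd.DataFrame:
    """Intersect a land-cover layer with settlement polygons, tagging each
    piece with its settlement_id.  Pieces outside settlements are discarded."""
    if layer is None or layer.empty or settlements.empty:
        cols = [] if layer is None else list(layer.columns)
        return pd.DataFrame(columns=cols + ["settlement_id"])
    geoms = list(layer["geometry"])
    tree = STRtree(geoms)
    rows = []
    for _, srow in settlements.iterrows():
        sgeom = srow["geometry"]
        for idx in tree.query(sgeom, predicate="intersects"):
            piece = _polygonal(sgeom.intersection(geoms[idx]))
            if piece.is_empty or piece.area <= 0:
                continue
            rec = layer.iloc[idx].to_dict()
            rec["geometry"] = piece
            rec["settlement_id"] = srow["settlement_id"]
            rows.append(rec)
    return pd.DataFrame(rows)


def _lookup_layer(tree: STRtree | None, geoms, points):
    """For each representative point, index of the covering layer polygon or -1."""
    out = np.full(len(points), -1, dtype=int)
    if tree is None:
        return out
    idx_pts, idx_geoms = tree.query(points, predicate="within")
    out[idx_pts] = idx_geoms
    return out


def union_layers(
    settlement_geom: BaseGeometry,
    settlement_id: str,
    prodes: pd.DataFrame,
    pmdbbs: pd.DataFrame,
    carbon: pd.DataFrame,
    sliver_ha: float = DEFAULT_SLIVER_HA,
) -> pd.DataFrame:
    """Planar-partition union of all layers inside one settlement.

    Builds the arrangement of all polygon boundaries, polygonizes it into
    atomic faces, and attribute-stacks each face by point-in-polygon lookup
    against every source layer.  Output faces are pairwise disjoint and
    jointly cover the settlement; slivers below ``sliver_ha`` are dissolved
    into the neighbouring fragment sharing the longest boundary.
    """
    def layer_geoms(df):
        return [] if df is None or df.empty else list(df["geometry"])

    p_geoms, m_geoms, c_geoms = layer_geoms(prodes), layer_geoms(pmdbbs), layer_geoms(carbon)
    lines = [shapely.boundary(settlement_geom)]
    for g in p_geoms + m_geoms + c_geoms:
        lines.append(shapely.boundary(g))
    arrangement = shapely.union_all(lines)
    faces = list(polygonize([arrangement]))

    pts = shapely.point_on_surface(faces)
    inside = shapely.within(pts, settlement_geom.buffer(0))
    faces = [f for f, ok in zip(faces, inside) if ok]
    pts = pts[inside]

    p_tree = STRtree(p_geoms) if p_geoms else None
    m_tree = STRtree(m_geoms) if m_geoms else None
    c_tree = STRtree(c_geoms) if c_geoms else None
    p_idx = _lookup_layer(p_tree, p_geoms, pts)
    m_idx = _lookup_layer(m_tree, m_geoms, pts)
    c_idx = _lookup_layer(c_tree, c_geoms, pts)

    rows = []
    for k, face in enumerate(faces):
        rec = {
            "settlement_id": settlement_id,
            "geometry": face,
            "area_ha": area_ha(face),
            "prodes_class": None,
            "prodes_year": None,
            "pmdbbs_clearing": m_idx[k] >= 0,
            "carbon_class": None,
        }
        if p_idx[k] >= 0:
            prow = prodes.iloc[p_idx[k]]
            rec["prodes_class"] = prow["prodes_class"]
            y = prow.get("prodes_year")
            rec["prodes_year"] = None if pd.isna(y) else int(y)
        if c_idx[k] >= 0:
            rec["carbon_class"] = carbon.iloc[c_idx[k]]["carbon_class"]
        rows.append(rec)
    frags = pd.DataFrame(rows)
    if not frags.empty:
        # class ids may be ints or strings: keep them as-is, absent = None
        frags["carbon_class"] = pd.Series(
            [r["carbon_class"] for r in rows], dtype=object)
    return _dissolve_slivers(frags, sliver_ha)


def _dissolve_slivers(frags: pd.DataFrame, sliver_ha: float) -> pd.DataFrame:
    """Merge fragments below the sliver threshold into the neighbour with the
    longest shared boundary (the neighbour keeps its attributes)."""
    if frags.empty:
        return frags
    small = frags.index[frags["area_ha"] < sliver_ha]
    if len(small) == 0:
        return frags.reset_index(drop=True)
    keep = frags.drop(index=small).reset_index(drop=True)
    if keep.empty:  # nothing to absorb into: keep everything
        return frags.reset_index(drop=True)
    tree = STRtree(list(keep["geometry"]))
    for i in small:
        sgeom = frags.at[i, "geometry"]
        cand = tree.query(sgeom, predicate="intersects")
        if len(cand) == 0:
            continue
        shared = [keep.at[int(j), "geometry"].intersection(sgeom).length for j in cand]
        j = int(cand[int(np.argmax(shared))])
        merged = shapely.union_all([keep.at[j, "geometry"], sgeom])
        keep.at[j, "geometry"] = merged
        keep.at[j, "area_ha"] = area_ha(merged)
    return keep.reset_index(drop=True)


def reconcile(
    settlements: pd.DataFrame,
    prodes: pd.DataFrame,
    pmdbbs: pd.DataFrame,
    carbon: pd.DataFrame,
    hydro_class_id=None,
    urban_class_id=None,
    sliver_ha: float = DEFAULT_SLIVER_HA,
) -> pd.DataFrame:
    """Full reconciliation: clip, union and classify for every settlement.

    Returns one row per reconciled fragment with columns
    ``settlement_id, final_class, prodes_year, reclassified, carbon_class,
    area_ha, geometry``.
    """
    p_clip = clip_to_settlements(prodes, settlements)
    m_clip = clip_to_settlements(pmdbbs, settlements)
    c_clip = clip_to_settlements(carbon, settlements)
    out = []
    for _, srow in settlements.iterrows():
        sid = srow["settlement_id"]
        frags = union_layers(
            srow["geometry"], sid,
            p_clip[p_clip.get("settlement_id", pd.Series(dtype=object)) == sid] if not p_clip.empty else p_clip,
            m_clip[m_clip.get("settlement_id", pd.Series(dtype=object)) == sid] if not m_clip.empty else m_clip,
            c_clip[c_clip.get("settlement_id", pd.Series(dtype=object)) == sid] if not c_clip.empty else c_clip,
            sliver_ha=sliver_ha,
        )
        for _, f in frags.iterrows():
            fc, year, reclass = assign_final_class(
                f["prodes_class"], f["prodes_year"], bool(f["pmdbbs_clearing"]),
                f["carbon_class"], hydro_class_id, urban_class_id,
            )
            out.append({
                "settlement_id": sid,
                "final_class": fc.value,
                "prodes_year": year,
                "reclassified": reclass,
                "carbon_class": f["carbon_class"],
                "area_ha": f["area_ha"],
                "geometry": f["geometry"],
            })
    df = pd.DataFrame(out, columns=[
        "settlement_id", "final_class", "prodes_year", "reclassified",
        "carbon_class", "area_ha", "geometry",
    ])
    df["prodes_year"] = df["prodes_year"].astype("Int64")
    return df


def class_areas(fragments: pd.DataFrame) -> pd.DataFrame:
    """Per-settlement area (ha) by final class (wide table, absent class = 0)."""
    if fragments.empty:
        return pd.DataFrame()
    piv = fragments.pivot_table(
        index="settlement_id", columns="final_class", values="area_ha",
        aggfunc="sum", fill_value=0.0,
    )
    for fc in FinalClass:
        if fc.value not in piv.columns:
            piv[fc.value] = 0.0
    return piv[[fc.value for fc in FinalClass]]
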