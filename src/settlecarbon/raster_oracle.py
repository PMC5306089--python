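"""Brute-force rasterized cross-check of the vector overlay path.

Rasterizes every clipped source layer on a common grid of square cells
(class of each cell decided by its centre point), applies the same final-class
decision table cell by cell, and sums cell areas.  Entirely independent of the
polygon-arrangement code in :mod:`settlecarbon.reconcile`: agreement between
the two routes validates the vector overlay.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely

from .reconcile import CoverageGapError, FinalClass, assign_final_class

#: sentinel for "no polygon covers this cell"
_NONE = -1


def _rasterize_indices(geoms, xs, ys, window=None) -> np.ndarray:
    """Index of the covering polygon per cell centre (row-major ys × xs), or -1.

    Each polygon only tests the cells inside its bounding box; ``window``
    (a box geometry) pre-clips every polygon, which keeps the point-in-polygon
    tests cheap for region-scale background polygons.
    """
    grid = np.full((len(ys), len(xs)), _NONE, dtype=np.int32)
    for i, geom in enumerate(geoms):
        if window is not None:
            if not geom.intersects(window):
                continue
            geom = geom.intersection(window)
            if geom.is_empty:
                continue
        minx, miny, maxx, maxy = geom.bounds
        jx = np.where((xs >= minx) & (xs <= maxx))[0]
        jy = np.where((ys >= miny) & (ys <= maxy))[0]
        if len(jx) == 0 or len(jy) == 0:
            continue
        gx, gy = np.meshgrid(xs[jx], ys[jy])
        shapely.prepare(geom)
        mask = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(gy.shape)
        sub = grid[np.ix_(jy, jx)]
        sub[mask] = i
        grid[np.ix_(jy, jx)] = sub
    return grid


def raster_area_oracle(
    settlements: pd.DataFrame,
    prodes: pd.DataFrame,
    pmdbbs: pd.DataFrame,
    carbon: pd.DataFrame,
    resolution_m: float = 1.0,
    hydro_class_id=None,
    urban_class_id=None,
) -> pd.DataFrame:
    """Per-settlement final-class areas (ha) computed on a raster grid.

    Cell centres sit at half-cell offsets from the settlement's lower-left
    bounding corner, so integer-metre geometry is resolved exactly at 1 m.
    Emits a warning when the resolution is coarse relative to the smallest
    input polygon.
    """
    min_width = np.inf
    for df in (prodes, pmdbbs, carbon):
        if df is not None and not df.empty:
            for g in df["geometry"]:
                minx, miny, maxx, maxy = g.bounds
                min_width = min(min_width, maxx - minx, maxy - miny)
    if np.isfinite(min_width) and resolution_m > min_width / 10.0:
        warnings.warn(
            f"raster resolution {resolution_m} m is coarse for the smallest "
            f"input polygon (width {min_width:.1f} m)", stacklevel=2,
        )

    cell_ha = resolution_m * resolution_m / 10_000.0
    rows = []
    for _, srow in settlements.iterrows():
        sid = srow["settlement_id"]
        sgeom = srow["geometry"]
        minx, miny, maxx, maxy = sgeom.bounds
        # sample at 3/4-cell offsets: centres stay off the integer-metre
        # lattice for any resolution 2^k, so integer geometry never puts a
        # sample point exactly on a polygon edge
        xs = np.arange(minx + 0.75 * resolution_m, maxx, resolution_m)
        ys = np.arange(miny + 0.75 * resolution_m, maxy, resolution_m)
        if len(xs) == 0 or len(ys) == 0:
            continue

        window = shapely.box(minx, miny, maxx, maxy)
        s_grid = _rasterize_indices([sgeom], xs, ys)
        inside = s_grid >= 0

        def layer_grid(df):
            if df is None or df.empty:
                return np.full(inside.shape, _NONE, dtype=np.int32)
            return _rasterize_indices(list(df["geometry"]), xs, ys, window=window)

        p_grid = layer_grid(prodes)
        m_grid = layer_grid(pmdbbs)
        c_grid = layer_grid(carbon)

        # classify per unique attribute combination, not per cell
        stacked = np.stack([p_grid, m_grid >= 0, c_grid])
        combos = stacked.reshape(3, -1).T[inside.ravel()]
        counts: dict[tuple, int] = {}
        for combo in map(tuple, combos):
            counts[combo] = counts.get(combo, 0) + 1

        acc: dict[tuple, float] = {}
        for (pi, mflag, ci), n in counts.items():
            p_class, p_year = None, None
            if pi >= 0:
                prow = prodes.iloc[int(pi)]
                p_class = prow["prodes_class"]
                y = prow.get("prodes_year")
                p_year = None if pd.isna(y) else int(y)
            c_class = carbon.iloc[int(ci)]["carbon_class"] if ci >= 0 else None
            try:
                fc, year, reclass = assign_final_class(
                    p_class, p_year, bool(mflag), c_class, hydro_class_id, urban_class_id
                )
                key = (fc.value, year, reclass)
            except CoverageGapError:
                # cell centre in a numerical gap between adjacent polygons:
                # tally separately; this area vanishes as the grid refines
                key = ("UNRESOLVED", None, False)
            acc[key] = acc.get(key, 0.0) + n * cell_ha
        for (fc, year, reclass), a in acc.items():
            rows.append({
                "settlement_id": sid, "final_class": fc,
                "prodes_year": year, "reclassified": reclass, "area_ha": a,
            })
    return pd.DataFrame(rows, columns=[
        "settlement_id", "final_class", "prodes_year", "reclassified", "area_ha"
    ])


def oracle_class_areas(oracle_df: pd.DataFrame) -> pd.DataFrame:
    """Wide per-settlement × final-class area table from the oracle output."""
    if oracle_df.empty:
        return pd.DataFrame()
    piv = oracle_df.pivot_table(
        index="settlement_id", columns="final_class", values="area_ha",
        aggfunc="sum", fill_value=0.0,
    )
    for fc in FinalClass:
        if fc.value not in piv.columns:
            piv[fc.value] = 0.0
    return piv[[fc.value for fc in FinalClass]]
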