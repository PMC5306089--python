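"""Synthetic landscape generator with exact ground truth.

Emulates the four proprietary inputs of the settlement carbon accounting —
the settlement vector map + registry, the annual forest-biome deforestation
monitor, the savanna clearing monitor, and the vegetation-carbon map — on a
planar metre grid with origin (0, 0).  All geometry is built from
integer-metre axis-aligned rectangles and their differences, so a 1 m
centre-sampled raster resolves it exactly and the recorded
:class:`GroundTruth` is exact by construction.

The region splits into a forest biome (west) and a savanna biome (east).
Settlements are non-overlapping rectangles placed on a grid of cells.
Forest-biome settlements clear in a fishbone: perpendicular "teeth" grow
outward from a central road year by year, each mapped patch respecting the
6.25 ha minimum mapping unit of the annual monitor (annual targets below the
unit accumulate until mappable).  Savanna-biome settlements receive a single
un-dated clearing polygon (≥ 2 ha) plus deliberately injected overlaps —
clearing over the forest monitor's forest/cloud/non-forest classes, dated
deforestation over clearing, and off-register hydrography — to exercise
every branch of the reconciliation precedence table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from .geodata import (CarbonClassTable, PlanarCrs, area_ha, group_for_category,
                      write_registry, write_vector_layer)

MMU_DEF_M2 = 62_500.0     # 6.25 ha: minimum mapped annual-deforestation patch
MMU_CLEAR_M2 = 20_000.0   # 2 ha: minimum mapped savanna-clearing patch
TOOTH_W = 280             # fishbone tooth width (m)
QUANTUM_M2 = 70_000.0     # nominal tooth-extension patch, 7 ha
FIRST_YEAR = 2001         # earliest nominal year of the annual monitor
LAST_YEAR = 2013

HYDRO_CLASS = 90
URBAN_CLASS = 91

STATES = ("Pará", "Amazonas", "Mato Grosso", "Rondônia", "Maranhão", "Acre")

DEFAULT_CATEGORY_MIX = {
    "PA": 0.50, "PAE": 0.14, "PDS": 0.06, "PE": 0.06, "PIC": 0.05,
    "PAC": 0.05, "PAD": 0.04, "PCA": 0.03, "PAR": 0.02, "PAF": 0.02,
    "PEAEX": 0.01, "PEAS": 0.01, "PAM": 0.01,
}


@dataclass
class ClearingSchedule:
    """Annual clearing intensity for one settlement group.

    ``period`` mode clears at a fixed km²/yr per settlement in each rate
    regime; ``per_family`` mode clears ``families × ha_per_family`` per year
    for the five years after creation.  Pre-creation clearing runs from the
    first nominal year through the creation year.
    """

    mode: str = "period"                     # "period" | "per_family"
    pre_creation_km2_per_yr: float = 0.4
    rate_to2005_km2_per_yr: float = 0.6
    rate_2006_2013_km2_per_yr: float = 0.25
    ha_per_family_per_yr_in_arc: float = 1.7
    ha_per_family_per_yr_out_arc: float = 1.0


def default_carbon_table() -> CarbonClassTable:
    return CarbonClassTable(pd.DataFrame({
        "class_id": [1, 2, 3, HYDRO_CLASS, URBAN_CLASS],
        "class_name": ["dense forest", "open forest", "savanna", "hydro", "urban"],
        "carbon_density_MgC_per_ha": [150.0, 120.0, 30.0, 0.0, 0.0],
        "is_forest": [True, True, False, False, False],
    }))


@dataclass
class SyntheticConfig:
    region_km: tuple[float, float] = (42.0, 35.0)
    n_settlements: int = 20
    category_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CATEGORY_MIX))
    forest_fraction: float = 0.75
    settlement_size_km: tuple[float, float] = (4.0, 6.0)
    clearing: dict[str, ClearingSchedule] = field(default_factory=lambda: {
        "traditional": ClearingSchedule(),
        "environmentally_distinctive": ClearingSchedule(
            pre_creation_km2_per_yr=0.02,
            rate_to2005_km2_per_yr=0.12,
            rate_2006_2013_km2_per_yr=0.08,
            ha_per_family_per_yr_in_arc=1.6,
            ha_per_family_per_yr_out_arc=0.2,
        ),
    })
    creation_year_range: tuple[int, int] = (2000, 2008)
    families_range: tuple[int, int] = (80, 150)
    missing_families_fraction: float = 0.05
    hydro_fraction: float = 0.015
    n_hydro_strips: int = 2
    hydro_offregister_frac: float = 0.3
    urban_patches: int = 2
    urban_patch_m: int = 300
    pmdbbs_cleared_fraction: float = 0.3
    cloud_probability: float = 0.4
    cloud_patch_m: int = 600
    arc_probability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        s = sum(self.category_mix.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"category_mix probabilities sum to {s}, expected 1")
        for name, value in (("forest_fraction", self.forest_fraction),
                            ("hydro_fraction", self.hydro_fraction),
                            ("pmdbbs_cleared_fraction", self.pmdbbs_cleared_fraction)):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    """Exact per-settlement outcomes implied by the generated geometry."""

    class_areas: pd.DataFrame          # settlement_id × final-class areas (ha)
    carbon: pd.DataFrame               # settlement_id, premodern/lost/remaining Mg C
    annual_km2: dict[str, dict[int, float]]
    original_forest_km2: dict[str, float]
    forest_at_creation_km2: dict[str, float]
    family_rate: dict[str, float]      # ha/family/yr over the 5-yr window


@dataclass
class SyntheticDataset:
    settlements: pd.DataFrame
    registry: pd.DataFrame
    prodes: pd.DataFrame
    pmdbbs: pd.DataFrame
    carbon: pd.DataFrame
    carbon_table: CarbonClassTable
    region_boundary: BaseGeometry
    truth: GroundTruth
    config: SyntheticConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vector_layer(self.settlements, out / "settlements.geojson")
        write_vector_layer(self.prodes, out / "prodes.geojson")
        write_vector_layer(self.pmdbbs, out / "pmdbbs.geojson")
        write_vector_layer(self.carbon, out / "carbon.geojson")
        write_registry(self.registry, out / "registry.csv")
        self.carbon_table.write_csv(out / "carbon_classes.csv")
        write_vector_layer(
            pd.DataFrame([{"name": "region", "geometry": self.region_boundary}]),
            out / "region.geojson",
        )
        truth = {
            "class_areas": self.truth.class_areas.to_dict(orient="list"),
            "carbon": self.truth.carbon.to_dict(orient="list"),
            "annual_km2": {k: {str(y): v for y, v in d.items()}
                           for k, d in self.truth.annual_km2.items()},
            "original_forest_km2": self.truth.original_forest_km2,
            "forest_at_creation_km2": self.truth.forest_at_creation_km2,
            "family_rate": self.truth.family_rate,
        }
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# fishbone clearing allocation


class _Fishbone:
    """Tracks tooth extensions for one settlement and allocates annual areas."""

    def __init__(self, x0, x1, y0, y1, total_demand_m2):
        self.yc = (y0 + y1) // 2
        self.lmax = (y1 - y0) // 2 - 60
        usable = (x1 - x0) - 400
        per_tooth = TOOTH_W * 2 * max(self.lmax, 1)
        n_needed = int(np.ceil(total_demand_m2 / max(per_tooth * 0.9, 1.0)))
        n_max = usable // (TOOTH_W + 120)   # spacing > tooth width: no overlap
        if n_max < 1 or self.lmax < 300:
            raise ValueError("infeasible packing: settlement too small for fishbone")
        n_teeth = max(min(2, n_max), min(n_needed + 1, n_max))
        spacing = usable // n_teeth
        self.xs = [x0 + 200 + spacing // 2 + i * spacing for i in range(int(n_teeth))]
        self.extent = {(i, s): 30 for i in range(len(self.xs)) for s in (1, -1)}
        self.carry = 0.0
        self.min_dl = int(np.ceil(MMU_DEF_M2 / TOOTH_W))

    def _available(self):
        return [k for k, L in self.extent.items() if L + self.min_dl <= self.lmax]

    def allocate(self, target_m2: float) -> list[BaseGeometry]:
        """Emit integer-metre rectangles totalling ≈ the accumulated target;
        sub-MMU remainders carry over to the next year."""
        remaining = target_m2 + self.carry
        self.carry = 0.0
        pieces = []
        while remaining >= MMU_DEF_M2:
            avail = self._available()
            if not avail:
                return pieces  # capacity exhausted; shortfall dropped
            key = min(avail, key=lambda k: (self.extent[k], k))
            want = remaining if remaining < MMU_DEF_M2 + QUANTUM_M2 else QUANTUM_M2
            dl = max(self.min_dl, int(round(want / TOOTH_W)))
            dl = min(dl, self.lmax - self.extent[key])
            if dl < self.min_dl:
                continue
            i, s = key
            L0, L1 = self.extent[key], self.extent[key] + dl
            x = self.xs[i]
            if s > 0:
                rect = box(x - TOOTH_W // 2, self.yc + L0, x + TOOTH_W // 2, self.yc + L1)
            else:
                rect = box(x - TOOTH_W // 2, self.yc - L1, x + TOOTH_W // 2, self.yc - L0)
            self.extent[key] = L1
            pieces.append(rect)
            remaining -= dl * TOOTH_W
        if remaining > 0:
            self.carry = remaining
        return pieces


# ---------------------------------------------------------------------------
# generator


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Build the full synthetic dataset; same config + seed ⇒ identical output."""
    rng = np.random.default_rng(config.seed)
    W = int(config.region_km[0] * 1000)
    H = int(config.region_km[1] * 1000)
    region = box(0, 0, W, H)
    x_forest = int(config.forest_fraction * W)
    forest_zone = box(0, 0, x_forest, H)
    savanna_zone = box(x_forest, 0, W, H)

    # --- settlement placement on a cell grid -------------------------------
    max_side = int(config.settlement_size_km[1] * 1000)
    cell = max_side + 600
    ncols, nrows = W // cell, H // cell
    if ncols * nrows < config.n_settlements:
        raise ValueError(
            f"infeasible packing: {config.n_settlements} settlements need more "
            f"than the {ncols * nrows} available cells"
        )
    cells = rng.permutation(ncols * nrows)[: config.n_settlements]
    cats = rng.choice(list(config.category_mix), size=config.n_settlements,
                      p=list(config.category_mix.values()))
    side_lo, side_hi = (int(s * 1000) for s in config.settlement_size_km)

    # --- hydrography strips ------------------------------------------------
    hh = max(10, int(config.hydro_fraction * H / max(config.n_hydro_strips, 1)))
    ys_hydro = sorted(rng.integers(200, H - 200 - hh, size=config.n_hydro_strips))
    carbon_strips = [box(0, int(y), W, int(y) + hh) for y in ys_hydro]
    dy = max(1, int(config.hydro_offregister_frac * hh))
    prodes_strips = [box(0, int(y) + dy, W, int(y) + hh + dy) for y in ys_hydro]
    carbon_hydro = shapely.union_all(carbon_strips)
    prodes_hydro = shapely.union_all(prodes_strips)

    settlement_rows, registry_rows = [], []
    def_pieces: list[tuple[str, int, BaseGeometry]] = []   # (sid, year, geom)
    cloud_pieces: list[tuple[str, BaseGeometry]] = []
    pmdbbs_pieces: list[tuple[str, BaseGeometry]] = []
    forest_patches: list[BaseGeometry] = []                # forest mapped inside savanna
    urban_rects: list[BaseGeometry] = []
    geoms: dict[str, BaseGeometry] = {}
    meta: dict[str, dict] = {}

    for n, (cell_idx, cat) in enumerate(zip(cells, cats)):
        sid = f"S{n:03d}"
        cx, cy = (int(cell_idx) % ncols) * cell, (int(cell_idx) // ncols) * cell
        sw = int(rng.integers(side_lo, side_hi + 1))
        sh = int(rng.integers(side_lo, side_hi + 1))
        x0, y0 = cx + 300, cy + 300
        x1, y1 = x0 + sw, y0 + sh
        geom = box(x0, y0, x1, y1)
        group = group_for_category(cat)
        creation = int(rng.integers(config.creation_year_range[0],
                                    config.creation_year_range[1] + 1))
        families = int(rng.integers(config.families_range[0], config.families_range[1] + 1))
        in_arc = bool(rng.random() < config.arc_probability)
        state = STATES[int(rng.integers(0, len(STATES)))]
        muni = f"mun_{sid}"
        zone = "forest" if (x0 + x1) / 2 < x_forest else "savanna"
        geoms[sid] = geom
        meta[sid] = dict(category=cat, group=group, creation=creation,
                         families=families, in_arc=in_arc, zone=zone,
                         bounds=(x0, y0, x1, y1))
        settlement_rows.append({
            "settlement_id": sid, "feature_id": f"{sid}#0", "name": f"Settlement {sid}",
            "category": cat, "municipality": muni, "geometry": geom,
        })
        families_out = families
        if rng.random() < config.missing_families_fraction:
            families_out = pd.NA
        registry_rows.append({
            "settlement_id": sid, "name": f"Settlement {sid}", "category": cat,
            "state": state, "municipality": muni, "creation_year": creation,
            "families": families_out, "reported_area_ha": area_ha(geom),
            "in_arc": in_arc,
        })

        schedule = config.clearing[group]
        if zone == "forest":
            # annual fishbone clearing
            targets = {}
            for year in range(FIRST_YEAR, LAST_YEAR + 1):
                if year <= creation:
                    a = schedule.pre_creation_km2_per_yr
                elif schedule.mode == "per_family":
                    if year <= creation + 5:
                        r = (schedule.ha_per_family_per_yr_in_arc if in_arc
                             else schedule.ha_per_family_per_yr_out_arc)
                        a = families * r / 100.0
                    else:
                        a = 0.0
                elif year <= 2005:
                    a = schedule.rate_to2005_km2_per_yr
                else:
                    a = schedule.rate_2006_2013_km2_per_yr
                targets[year] = a * 1e6
            try:
                fb = _Fishbone(x0, min(x1, x_forest), y0, y1, sum(targets.values()))
            except ValueError:
                fb = None   # too small to host a fishbone: stays uncleared
            if fb is not None:
                for year, tgt in targets.items():
                    for rect in fb.allocate(tgt):
                        piece = rect.difference(prodes_hydro)
                        for part in getattr(piece, "geoms", [piece]):
                            if part.area >= MMU_DEF_M2:
                                def_pieces.append((sid, year, part))
            if rng.random() < config.cloud_probability:
                cwm = config.cloud_patch_m
                cloud = box(x1 - cwm - 150, y1 - cwm - 150, x1 - 150, y1 - 150)
                cloud_pieces.append((sid, cloud.intersection(geom)))
        else:
            # savanna-biome settlement: un-dated clearing + injected overlaps
            sx0 = max(x0, x_forest - 100)          # may lap 100 m into the forest biome
            cw = int(config.pmdbbs_cleared_fraction * (x1 - sx0))
            if cw * (y1 - y0) >= MMU_CLEAR_M2:
                clearing = box(sx0, y0, sx0 + cw, y1)
                pmdbbs_pieces.append((sid, clearing))
                # forest patch straddling the clearing edge; dated deforestation
                # inside it overlapping the clearing
                fpw = 800
                fp = box(sx0 + cw - fpw // 2, y0 + 200, sx0 + cw + fpw // 2, y0 + 1200)
                fp = fp.intersection(geom)
                if not fp.is_empty:
                    forest_patches.append(fp)
                    dr = box(sx0 + cw - fpw // 2 + 50, y0 + 300,
                             sx0 + cw + fpw // 2 - 50, y0 + 700).intersection(geom)
                    dr = dr.difference(prodes_hydro)
                    year = int(rng.integers(2003, 2009))
                    for part in getattr(dr, "geoms", [dr]):
                        if part.area >= MMU_DEF_M2:
                            def_pieces.append((sid, year, part))
                # cloud patch lapping the clearing edge
                cl = box(sx0 + cw - 200, y1 - 700, sx0 + cw + 400, y1 - 200)
                cl = cl.intersection(geom)
                if not cl.is_empty:
                    cloud_pieces.append((sid, cl))

    # --- urban patches inside the first settlements ------------------------
    um = config.urban_patch_m
    for sid in list(geoms)[: config.urban_patches]:
        x0, y0, x1, y1 = meta[sid]["bounds"]
        urban_rects.append(box(x0 + 60, y0 + 60, x0 + 60 + um, y0 + 60 + um))
    urban_union = shapely.union_all(urban_rects) if urban_rects else shapely.Polygon()

    # --- assemble monitor layers (each a planar partition of its domain) ---
    def_union = shapely.union_all([g for _, _, g in def_pieces]) if def_pieces else shapely.Polygon()
    cloud_rows, cloud_final = [], []
    for sid, cl in cloud_pieces:
        c = cl.difference(prodes_hydro).difference(def_union)
        if not c.is_empty:
            cloud_rows.append({"prodes_class": "cloud", "prodes_year": None, "geometry": c})
            cloud_final.append(c)
    cloud_union = shapely.union_all(cloud_final) if cloud_final else shapely.Polygon()
    fp_union = shapely.union_all(forest_patches) if forest_patches else shapely.Polygon()

    forest_geom = (
        shapely.union_all([forest_zone, fp_union])
        .difference(prodes_hydro).difference(def_union).difference(cloud_union)
    )
    nonforest_geom = (
        savanna_zone.difference(fp_union)
        .difference(prodes_hydro).difference(def_union).difference(cloud_union)
    )
    prodes_rows = (
        [{"prodes_class": "hydro", "prodes_year": None, "geometry": g} for g in prodes_strips]
        + [{"prodes_class": "deforestation", "prodes_year": y, "geometry": g}
           for _, y, g in def_pieces]
        + cloud_rows
        + [{"prodes_class": "forest", "prodes_year": None, "geometry": forest_geom},
           {"prodes_class": "nonforest", "prodes_year": None, "geometry": nonforest_geom}]
    )
    prodes = pd.DataFrame(prodes_rows)
    pmdbbs = pd.DataFrame(
        [{"clearing": True, "geometry": g} for _, g in pmdbbs_pieces],
        columns=["clearing", "geometry"],
    )

    x_dense = x_forest // 2
    dense_box, open_box = box(0, 0, x_dense, H), box(x_dense, 0, x_forest, H)
    veg_rows = []
    for cid, zone_geom in ((1, dense_box), (2, open_box), (3, savanna_zone)):
        g = zone_geom.difference(carbon_hydro).difference(urban_union)
        veg_rows.append({"carbon_class": cid, "geometry": g})
    carbon_rows = (
        veg_rows
        + [{"carbon_class": HYDRO_CLASS, "geometry": carbon_hydro.difference(urban_union)}]
        + [{"carbon_class": URBAN_CLASS, "geometry": g} for g in urban_rects]
    )
    carbon = pd.DataFrame(carbon_rows)

    # --- exact ground truth ------------------------------------------------
    truth = _ground_truth(
        geoms, meta, def_pieces, cloud_union, fp_union,
        shapely.union_all([g for _, g in pmdbbs_pieces]) if pmdbbs_pieces else shapely.Polygon(),
        prodes_hydro, carbon_hydro, urban_union,
        dense_box, open_box, savanna_zone, default_carbon_table(),
    )

    settlements = pd.DataFrame(settlement_rows)
    settlements.attrs["crs"] = PlanarCrs()
    registry = pd.DataFrame(registry_rows)
    registry["families"] = registry["families"].astype("Int64")
    registry["creation_year"] = registry["creation_year"].astype("Int64")
    registry["group"] = registry["category"].map(group_for_category)
    return SyntheticDataset(
        settlements=settlements, registry=registry, prodes=prodes, pmdbbs=pmdbbs,
        carbon=carbon, carbon_table=default_carbon_table(), region_boundary=region,
        truth=truth, config=config,
    )


def _ground_truth(geoms, meta, def_pieces, cloud_union, fp_union, pmdbbs_union,
                  prodes_hydro, carbon_hydro, urban_union,
                  dense_box, open_box, savanna_zone, table) -> GroundTruth:
    """Direct set-algebra evaluation of the precedence rules, bypassing the
    overlay machinery entirely."""
    dens = {1: 150.0, 2: 120.0, 3: 30.0}
    forest_class_boxes = [dense_box, open_box]
    area_rows, carbon_rows = [], []
    annual, original_f, at_creation, family_rate = {}, {}, {}, {}

    def carbon_of(geom):
        total = 0.0
        for cid, zone in ((1, dense_box), (2, open_box), (3, savanna_zone)):
            total += dens[cid] * area_ha(geom.intersection(zone))
        return total

    for sid, S in geoms.items():
        urb = S.intersection(urban_union)
        wat = S.intersection(carbon_hydro).difference(urban_union)
        R = S.difference(urban_union).difference(carbon_hydro)
        ph = prodes_hydro.intersection(R)
        reclass = ph.intersection(pmdbbs_union)
        excl_hydro = ph.difference(pmdbbs_union)
        defs = {}
        for psid, year, g in def_pieces:
            if psid != sid:
                continue
            gg = g.intersection(R)
            if not gg.is_empty:
                defs[year] = shapely.union_all([defs[year], gg]) if year in defs else gg
        def_all = shapely.union_all(list(defs.values())) if defs else shapely.Polygon()
        clear = pmdbbs_union.intersection(R).difference(prodes_hydro).difference(def_all)
        cloud = cloud_union.intersection(R).difference(pmdbbs_union)
        veg = (R.difference(ph).difference(def_all)
               .difference(pmdbbs_union).difference(cloud_union))
        forest_area_geom = veg.intersection(
            shapely.union_all([dense_box.union(open_box), fp_union]))
        nonforest_geom = veg.difference(forest_area_geom)

        rec = {
            "settlement_id": sid,
            "DEF_PRODES": area_ha(def_all) + area_ha(reclass),
            "CLEAR_PMDBBS": area_ha(clear),
            "FOREST": area_ha(forest_area_geom),
            "NONFOREST": area_ha(nonforest_geom),
            "CLOUD": area_ha(cloud),
            "WATER": area_ha(wat),
            "EXCLUDED_HYDRO": area_ha(excl_hydro),
            "EXCLUDED_URBAN": area_ha(urb),
            "reclassified": area_ha(reclass),
        }
        area_rows.append(rec)

        cleared_geom = shapely.union_all([def_all, clear, reclass])
        remaining_geom = shapely.union_all([forest_area_geom, nonforest_geom, cloud])
        lost = carbon_of(cleared_geom)
        remaining = carbon_of(remaining_geom)
        carbon_rows.append({
            "settlement_id": sid, "lost_MgC": lost, "remaining_MgC": remaining,
            "premodern_MgC": lost + remaining,
        })

        annual[sid] = {int(y): area_ha(g) / 100.0 for y, g in sorted(defs.items())}
        def_forest = sum(
            area_ha(g.intersection(b)) for g in defs.values() for b in forest_class_boxes
        )
        orig = area_ha(forest_area_geom) / 100.0 + area_ha(cloud) / 100.0 + def_forest / 100.0
        original_f[sid] = orig
        cy = meta[sid]["creation"]
        cum_c = sum(a for y, a in annual[sid].items() if y <= cy)
        at_creation[sid] = orig - cum_c
        fam = meta[sid]["families"]
        cum5 = sum(a for y, a in annual[sid].items() if cy < y <= cy + 5)
        family_rate[sid] = cum5 * 100.0 / fam / 5.0 if fam else float("nan")

    return GroundTruth(
        class_areas=pd.DataFrame(area_rows),
        carbon=pd.DataFrame(carbon_rows),
        annual_km2=annual,
        original_forest_km2=original_f,
        forest_at_creation_km2=at_creation,
        family_rate=family_rate,
    )


# ---------------------------------------------------------------------------
# perturbations exercising the cleaning rules


def perturb(dataset: SyntheticDataset, mode: str, seed: int = 0):
    """Inject a settlement-map pathology; returns (corrupted dataset, expected
    cleaning actions by settlement)."""
    rng = np.random.default_rng(seed)
    ds = dataclasses.replace(dataset, settlements=dataset.settlements.copy())
    n_pick = min(3, len(ds.registry))
    picks = list(ds.registry["settlement_id"].iloc[
        rng.choice(len(ds.registry), size=n_pick, replace=False)
    ])
    expected = {}
    extra = []
    if mode == "duplicate_polygons":
        for sid in picks:
            row = ds.settlements[ds.settlements["settlement_id"] == sid].iloc[0].to_dict()
            row["feature_id"] = f"{sid}#dup"
            extra.append(row)
            expected[sid] = "polygon_deduplicated"
    elif mode == "wrong_municipality":
        for sid in picks:
            row = ds.settlements[ds.settlements["settlement_id"] == sid].iloc[0].to_dict()
            x0, y0, _, _ = row["geometry"].bounds
            sat = box(x0 - 250, y0 - 250, x0 - 50, y0 - 50)
            extra.append({**row, "feature_id": f"{sid}#sat",
                          "municipality": "mun_wrong", "geometry": sat})
            expected[sid] = "polygon_dropped_wrong_municipality"
    elif mode == "split_settlement":
        keep_rows = []
        for _, row in ds.settlements.iterrows():
            if row["settlement_id"] in picks:
                x0, y0, x1, y1 = row["geometry"].bounds
                xm = int((x0 + x1) // 2)
                for i, part in enumerate((box(x0, y0, xm, y1), box(xm, y0, x1, y1))):
                    r = row.to_dict()
                    r["feature_id"] = f"{row['settlement_id']}#p{i}"
                    r["geometry"] = part
                    keep_rows.append(r)
                expected[row["settlement_id"]] = "polygons_merged"
            else:
                keep_rows.append(row.to_dict())
        ds.settlements = pd.DataFrame(keep_rows)
        return ds, expected
    else:
        raise ValueError(f"unknown perturbation mode {mode!r}")
    ds.settlements = pd.concat(
        [ds.settlements, pd.DataFrame(extra)], ignore_index=True
    )
    return ds, expected
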