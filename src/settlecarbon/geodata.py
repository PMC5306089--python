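"""Domain types, vector/tabular I/O and planar area computation.

All geometry lives in a planar equal-area reference measured in metres
(:class:`PlanarCrs`); areas are kept internally in hectares and converted to
km² or Pg C only at report time.  Vector layers are plain :class:`pandas.DataFrame`
objects with a ``geometry`` column of shapely geometries — the lightweight
equivalent of a GeoDataFrame for the formats this project needs.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

log = logging.getLogger(__name__)

M2_PER_HA = 10_000.0

#: The 13 INCRA settlement category codes.
CATEGORIES = (
    "PA", "PAC", "PAD", "PAE", "PAF", "PAM", "PAR",
    "PCA", "PDS", "PE", "PEAEX", "PEAS", "PIC",
)

#: Categories managed for low-impact (agro-extractivist / sustainable) use.
ENV_DISTINCTIVE = frozenset({"PAE", "PAF", "PDS", "PEAEX", "PEAS"})

TRADITIONAL = frozenset(CATEGORIES) - ENV_DISTINCTIVE

REGISTRY_COLUMNS = (
    "settlement_id", "name", "category", "state", "municipality",
    "creation_year", "families", "reported_area_ha", "in_arc",
)

CARBON_TABLE_COLUMNS = ("class_id", "class_name", "carbon_density_MgC_per_ha")


class SchemaError(ValueError):
    """An input layer or table is missing a mandatory attribute."""


class GeometryError(ValueError):
    """A geometry is invalid and could not be repaired."""


def group_for_category(category: str) -> str:
    """Return ``"environmentally_distinctive"`` or ``"traditional"``.

    The category code fully determines the group: PAE, PAF, PDS, PEAEX and
    PEAS are environmentally distinctive, all other codes are traditional.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown settlement category {category!r}")
    return "environmentally_distinctive" if category in ENV_DISTINCTIVE else "traditional"


@dataclass(frozen=True)
class PlanarCrs:
    """A declared equal-area planar reference, unit metres.

    Synthetic data is generated directly in planar metres, so the only
    contract this type carries is the unit convention: a 1000 m × 1000 m
    square has an area of exactly 100 ha.
    """

    name: str = "local-planar-metres"
    unit: str = "m"

    def square_km_area_ha(self) -> float:
        return 1000.0 * 1000.0 / M2_PER_HA


@dataclass
class SettlementRecord:
    """One agrarian-reform settlement (registry attributes + geometry)."""

    settlement_id: str
    name: str
    category: str
    state: str
    municipality: str
    reported_area_ha: float
    creation_year: int | None = None
    families: int | None = None
    in_arc: bool = False
    geometry: BaseGeometry | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown settlement category {self.category!r}")
        if not self.reported_area_ha > 0:
            raise ValueError(f"reported_area_ha must be positive, got {self.reported_area_ha}")
        if self.families is not None and self.families < 0:
            raise ValueError("families must be non-negative")

    @property
    def group(self) -> str:
        return group_for_category(self.category)


@dataclass
class CarbonClassTable:
    """Vegetation class → carbon density lookup (Mg C / ha).

    ``hydro`` and ``urban`` rows carry density 0; ``is_forest`` marks the
    classes whose original cover counts as forest in the temporal analysis.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        missing = [c for c in CARBON_TABLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"carbon class table missing column(s): {', '.join(missing)}")
        if self.table["class_id"].duplicated().any():
            dupes = self.table.loc[self.table["class_id"].duplicated(), "class_id"].tolist()
            raise ValueError(f"duplicate carbon class id(s): {dupes}")
        if (self.table["carbon_density_MgC_per_ha"] < 0).any():
            raise ValueError("carbon densities must be non-negative")
        if "is_forest" not in self.table.columns:
            self.table = self.table.assign(
                is_forest=self.table["class_name"].str.contains("forest", case=False)
            )

    def density(self, class_id) -> float:
        row = self.table.loc[self.table["class_id"] == class_id]
        if row.empty:
            raise KeyError(f"unknown carbon class id {class_id!r}")
        return float(row["carbon_density_MgC_per_ha"].iloc[0])

    def is_forest(self, class_id) -> bool:
        row = self.table.loc[self.table["class_id"] == class_id]
        if row.empty:
            raise KeyError(f"unknown carbon class id {class_id!r}")
        return bool(row["is_forest"].iloc[0])

    @classmethod
    def read_csv(cls, path: str | Path) -> "CarbonClassTable":
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# geometry repair & area


def repair_geometry(geom: BaseGeometry, feature_id: str | None = None) -> BaseGeometry:
    """Return a valid geometry covering the same area (zero-buffer convention).

    Self-intersecting rings (e.g. bow-ties) become multipolygons of equal
    coverage.  A repair log line is emitted per repaired feature; an
    unrepairable geometry raises :class:`GeometryError`.
    """
    if geom is None or geom.is_empty:
        return geom
    if geom.is_valid:
        return geom
    fixed = shapely.make_valid(geom)
    # make_valid may return a collection with stray lines/points: keep area parts
    if fixed.geom_type == "GeometryCollection":
        polys = [g for g in fixed.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        fixed = shapely.union_all(polys) if polys else shapely.Polygon()
    if not fixed.is_valid or (geom.area > 0 and fixed.is_empty):
        raise GeometryError(f"geometry {feature_id or ''} could not be repaired")
    log.info("repaired invalid geometry %s", feature_id or "<unnamed>")
    return fixed


def area_ha(geom: BaseGeometry, crs: PlanarCrs | None = None) -> float:
    """Planar area of ``geom`` in hectares; additive over disjoint parts."""
    if geom is None or geom.is_empty:
        return 0.0
    if not geom.is_valid:
        raise GeometryError("area_ha requires a valid geometry; repair first")
    return geom.area / M2_PER_HA


def area_km2(geom: BaseGeometry, crs: PlanarCrs | None = None) -> float:
    return area_ha(geom, crs) / 100.0


# ---------------------------------------------------------------------------
# vector layer I/O (GeoJSON)


def read_vector_layer(
    path: str | Path,
    expected_schema: Sequence[str] = (),
    crs: PlanarCrs | None = None,
) -> pd.DataFrame:
    """Read a GeoJSON FeatureCollection into a DataFrame with a geometry column.

    Geometries are validated and repaired on ingest.  ``expected_schema``
    lists mandatory property names; a missing one raises :class:`SchemaError`
    naming the attribute.
    """
    path = Path(path)
    if path.suffix.lower() not in (".geojson", ".json"):
        raise NotImplementedError(
            f"unsupported vector container {path.suffix!r}: this build reads GeoJSON"
        )
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path} is not a GeoJSON FeatureCollection")
    rows = []
    for i, feat in enumerate(doc.get("features", [])):
        props = dict(feat.get("properties") or {})
        for attr in expected_schema:
            if attr not in props:
                raise SchemaError(f"feature {i} of {path.name} missing attribute {attr!r}")
        geom = repair_geometry(shape(feat["geometry"]), props.get("settlement_id", str(i)))
        props["geometry"] = geom
        rows.append(props)
    df = pd.DataFrame(rows)
    df.attrs["crs"] = crs or PlanarCrs()
    df.attrs["source"] = str(path)
    return df


def write_vector_layer(df: pd.DataFrame, path: str | Path) -> None:
    """Write a geometry-bearing DataFrame as a GeoJSON FeatureCollection."""
    feats = []
    for _, row in df.iterrows():
        props = {k: _jsonable(v) for k, v in row.items() if k != "geometry"}
        feats.append(
            {"type": "Feature", "properties": props, "geometry": mapping(row["geometry"])}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def _jsonable(v):
    if pd.isna(v):
        return None
    if hasattr(v, "item"):
        return v.item()
    return v


# ---------------------------------------------------------------------------
# registry I/O


def read_registry(path: str | Path) -> pd.DataFrame:
    """Parse the settlement registry CSV into one row per settlement.

    Empty ``families``/``creation_year`` cells become missing values (pandas
    ``NA``), never 0 — absence of a family count is information the
    per-family analysis must respect.
    """
    df = pd.read_csv(path, dtype={"settlement_id": str})
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"registry missing column(s): {', '.join(missing)}")
    df["creation_year"] = df["creation_year"].astype("Int64")
    df["families"] = df["families"].astype("Int64")
    df["in_arc"] = df["in_arc"].astype(bool)
    dup = df.loc[df["settlement_id"].duplicated(), "settlement_id"]
    if not dup.empty:
        raise ValueError(f"duplicate settlement_id(s) in registry: {sorted(set(dup))}")
    if (df["families"].dropna() < 0).any():
        raise ValueError("registry contains negative family counts")
    bad_cat = set(df["category"]) - set(CATEGORIES)
    if bad_cat:
        raise ValueError(f"registry contains unknown categories: {sorted(bad_cat)}")
    if (df["reported_area_ha"] <= 0).any():
        raise ValueError("reported_area_ha must be positive")
    df["group"] = df["category"].map(group_for_category)
    return df


def write_registry(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, [c for c in df.columns if c in REGISTRY_COLUMNS]].to_csv(
        path, index=False, quoting=csv.QUOTE_MINIMAL
    )
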