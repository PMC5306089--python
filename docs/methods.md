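# Methods

## Scope and model

`settlecarbon` reimplements a settlement-level deforestation and
carbon-stock accounting for Legal Amazonia as a five-stage pipeline:

1. **Cleaning** — the settlement vector map is filtered (features must be
   100 % inside the study region, of one of the 13 settlement categories,
   and present in the registry) and collapsed to one polygon per
   settlement.  Multi-polygon settlements are resolved in a fixed order:
   drop polygons whose declared municipality differs from the registry's,
   deduplicate congruent copies, then either merge all remaining polygons
   (when the summed area is at least as close to the registry's reported
   area as any single polygon) or keep the single polygon with the closest
   area.  Every input feature receives exactly one logged decision, so the
   log partitions the input and the operation is idempotent.
2. **Reconciliation** — the annual forest-biome clear-cut monitor, the
   savanna clearing monitor and the vegetation-carbon map are clipped to
   the settlements and unioned into a planar partition of each settlement
   (boundary arrangement → polygonization → point-in-polygon attribute
   stacking).  A first-match decision table assigns one final class per
   fragment: urban ≻ water ≻ monitor-hydrography (reclassified to clearing
   where the savanna monitor mapped clearing underneath, excluded
   otherwise) ≻ dated deforestation ≻ savanna clearing ≻ forest / cloud /
   non-forest.  Annual data win over the un-dated clearing class; the
   savanna monitor wins over static forest-biome classes because its 2 ha
   minimum mapping unit sees clearings the 6.25 ha monitor misses.  Cloud
   fragments stay carbon-bearing (they were mapped as forest in earlier
   years).
3. **Carbon accounting** — each fragment carries the density of the
   *original* vegetation class at its location, so cleared fragments
   contribute the stock that stood there.  Lost = cleared fragments,
   remaining = forest + non-forest + cloud, pre-modern = lost + remaining;
   the identity holds exactly at settlement, category and region level
   because both sides use the same densities.  Water and excluded classes
   carry zero carbon.  Densities are single per-class constants; no
   within-class spatial variation is modelled.
4. **Temporal dynamics** — nominal-year cumulative clearing (inclusive of
   the query year, matching the August→July observation window), original
   vs at-creation forest for settlements created 2000–2008, two-period mean
   rates (creation+1…2005 and 2006–2013; settlements created 2006–2008 use
   creation+1…2013; settlements created 2005 enter neither two-period
   comparison), and per-family clearing over calendar years
   creation+1…creation+5.  Settlements containing savanna-monitor clearing
   are excluded from all annual analyses (that product has no annual
   resolution); the family analysis additionally requires a family count
   and some forest left at creation.  Clearing mapped before the first
   annual map would carry the earliest nominal label and counts toward
   pre-creation clearing only.
5. **Reporting** — category tables (land-cover areas, exclusions,
   carbon), threshold censuses (settlements with 0 %, ≥ 50 % — inclusive —
   and 100 % of original vegetation cleared), and shares/ratios.  All
   percentages round half away from zero (the convention the published
   tables follow; banker's rounding reproduces several printed values
   wrongly).  "Original vegetation" is the analysed area minus water.
   Region-wide denominators (total clearing, total carbon loss, …) are
   configuration inputs to the report layer and are never consulted by any
   computation path.

## Geometry and units

All geometry lives in a declared equal-area planar frame in metres; a
1000 m × 1000 m square is 100 ha by construction.  Internal units are
hectares and Mg C; reports convert to km² (÷100) and Pg C (÷10⁹) at emission
time only.  Invalid geometries are repaired with `make_valid` (coverage
preserved; a log line per repair), never dropped.  Vector I/O is GeoJSON;
the registry and carbon-class table are CSV.  Overlay slivers below
10⁻⁴ ha (configurable) are dissolved into the neighbouring fragment with
the longest shared boundary.

## The synthetic landscape

The generator emulates the four proprietary inputs on integer-metre
axis-aligned rectangles, which makes the recorded ground truth exact and
lets a 1 m centre-sampled raster resolve the geometry without boundary
error.  A region (default 42 km × 35 km, 75 % forest biome — matching the
roughly three-quarters forest share of the real region) holds 20
non-overlapping rectangular settlements of 4–6 km side on a placement grid.
Categories are drawn from a mix approximating the registry's composition
(half the settlements are PA); creation years are uniform on 2000–2008,
family counts uniform on 80–150, with 5 % of registry rows missing the
family count; arc-of-deforestation membership is a per-municipality coin
flip.

Forest-biome settlements clear in a **fishbone**: perpendicular teeth
(280 m wide) grow outward from a central road, one integer-length extension
per mapped patch, each patch ≥ 6.25 ha; the last extension of a year
absorbs the remainder so the year's target is hit exactly whenever it
exceeds the minimum mapping unit, and sub-unit targets accumulate until
mappable.  Default intensities: traditional settlements clear
0.4 km²/yr before creation, 0.6 km²/yr through 2005 and 0.25 km²/yr after;
environmentally distinctive settlements 0.02 / 0.12 / 0.08 km²/yr.  A
per-family mode clears families × (1.7 / 1.6 / 1.0 / 0.2) ha per year —
the published group means by group and arc membership — for the five years
after creation.  Savanna-biome settlements instead receive one un-dated
clearing polygon covering 30 % of their savanna extent, plus deliberately
injected overlaps — a forest patch and a cloud patch straddling the
clearing edge and a dated deforestation rectangle inside the clearing — so
every branch of the precedence table is exercised.  Rivers are horizontal
strips (1.5 % of the region) present in both the carbon map and, shifted by
30 % of their width, in the forest monitor, producing the off-register
hydrography the exclusion rule handles; two 300 m urban squares sit inside
the first settlements.

The ground truth is computed by direct set algebra on the construction
rectangles (a different route than the polygonization overlay).  What the
generator does **not** emulate: georegistration error beyond the hydrography
offset, spectral/cloud-motion realism, irregular settlement shapes, spatial
density variation within vegetation classes, and clearing by external
actors as a separate process.  Passing recovery tests therefore demonstrate
the correctness of the overlay arithmetic, not robustness to real-sensor
noise.

## Study designs and problem sizes

* **End-to-end recovery** — 10 default landscapes (20 settlements each);
  the vector pipeline reproduces the truth's class areas, carbon triple and
  at-creation forest to ~10⁻¹² relative (the 1 % acceptance band is pure
  headroom for overlay slivers).
* **Raster oracle** — 20 small mixed-biome scenes (6 km × 4 km, two 1–1.4 km
  settlements) rasterized at 1 m; vector and raster class areas agree
  exactly on integer geometry, and within 0.5 % is the acceptance band.
  Cells whose centre falls in a numerical gap between adjacent polygons are
  tallied separately ("UNRESOLVED") and vanish with refinement; sample
  points sit at ¾-cell offsets so power-of-two resolutions never place one
  on the integer lattice.
* **Rate-ratio study** — 100 settlements (≈50 per group), creations
  2000–2004, clearing at the published two-period rates scaled 1:50 so the
  18.9× and 9.9× contrasts carry over while every annual target stays above
  the 6.25 ha mapping unit.  Recovered ratios land within a few percent of
  the design; the shortfall comes from patches clipped by river crossings.
* **Per-family study** — 80 settlements in per-family mode; group means
  recover the designed 1.7 / 1.6 / 1.0 / 0.2 ha family⁻¹ yr⁻¹ within ~5 %.

These sizes were chosen so each study is statistically stable at desk
scale; all are configuration, not constants.

## Numerical choices

* Rounding: half away from zero everywhere a report rounds.
* Congruence of duplicate polygons: symmetric-difference area ≤ 10⁻⁶ ha.
* Closest-area tie-break: larger polygon first, then lexicographic feature
  id — deterministic and order-independent.
* The merge decision for split settlements is driven purely by the
  area-sum criterion (no distance threshold: none is defined for "near each
  other", so proximity is not tested).
* Reclassified hydro-over-clearing fragments carry no nominal year; they
  are counted with the savanna clearing total in reports and never enter
  annual series.  Whether that area belongs in the annual or the savanna
  column of the land-cover table is ambiguous in the source accounting;
  both tallies are recoverable via the `reclassified` flag.
* Urban-before-water ordering in the decision table is arbitrary: the
  carbon map's classes partition space, so the two can only co-occur
  through topology error.
* Minimum-mapping-unit filters are applied by the generator, not
  re-imposed by the reconciler — monitoring products arrive already
  filtered.
* Family counts are assumed settled in the creation year; the registry
  does not say whether counts are as-of-creation or as-of-report.

## Known limitations

Degradation and regrowth fluxes, burn scars and secondary vegetation are
out of scope (the accounting is clear-cut only); carbon densities are
class-level means; the geodetic datum question (planar vs ellipsoidal
areas) is sidestepped by declaring a planar frame; Shapefile/GeoPackage
containers are not read — inputs are GeoJSON.
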