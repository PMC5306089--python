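"""Published per-category accounting tables for Legal Amazonia settlements.

The original study's category tables (areas by land-cover class, excluded
areas, and carbon stocks) are reproduced here as *inputs* to the reporting
layer: the study prints both the components and the derived totals, shares
and ratios, so the report arithmetic can be exercised end to end against
real published values without the proprietary source vectors.

Units follow the tables: km² for areas, Pg C for carbon.
"""

from __future__ import annotations

import pandas as pd

from .reporting import RegionReference

#: region-wide reference denominators (Legal Amazonia)
REGION = RegionReference()

_LANDCOVER_COLS = [
    "category", "prodes_deforestation_km2", "pmdbbs_clearing_km2",
    "total_deforestation_km2", "forest_km2", "nonforest_km2",
    "clouds_km2", "water_km2", "total_km2",
]

#: Land-cover area (km²) per settlement category: annual forest-biome
#: deforestation (through 2013), savanna clearing (through 2010), their sum,
#: then remaining forest / non-forest / clouds / water and the analysed total.
LANDCOVER_BY_CATEGORY = pd.DataFrame([
    ("PA",    108351.6, 7282.1, 115633.7, 56488.5, 17434.7, 14954.6, 685.6, 205197.0),
    ("PAC",     1638.0,    0.0,   1638.0,  1863.3,    22.4,   488.9,  17.5,   4030.0),
    ("PAD",    10241.0,    0.0,  10241.0,  4866.9,   123.9,   350.1,   8.7,  15590.6),
    ("PAE",     4859.9,    1.3,   4861.2, 70563.6,  5809.3, 18716.1, 5108.8, 105059.0),
    ("PAF",      272.6,    0.0,    272.6,  2739.6,     7.9,   157.7,   0.8,   3178.6),
    ("PAM",        0.0,    0.0,      0.0,    86.4,     0.0,     0.0,   0.6,     87.0),
    ("PAR",      349.8,    0.0,    349.8,   497.7,     0.0,     0.1,   2.4,    849.9),
    ("PCA",       26.9,    1.7,     28.6,    18.5,     0.5,     5.0,   0.0,     52.6),
    ("PDS",     3987.2,    7.0,   3994.2, 19977.2,   807.7,  6073.8, 150.5,  31003.5),
    ("PE",      2162.2,  728.5,   2890.7,   334.6,  1493.2,   115.9,  10.2,   4844.7),
    ("PEAEX",    489.7,    0.0,    489.7,   817.8,    48.6,   684.9,  23.9,   2064.9),
    ("PEAS",       2.3,    0.0,      2.3,    23.1,     0.0,     8.4,   0.0,     33.7),
    ("PIC",    19953.1,   55.2,  20008.3,  3046.1,  1098.8,   743.7, 366.0,  25262.9),
], columns=_LANDCOVER_COLS)

#: published Total row of the land-cover table
LANDCOVER_TOTAL = pd.Series({
    "prodes_deforestation_km2": 152334.2,
    "pmdbbs_clearing_km2": 8075.9,
    "total_deforestation_km2": 160410.1,
    "forest_km2": 161323.1,
    "nonforest_km2": 26847.1,
    "clouds_km2": 42299.2,
    "water_km2": 6374.9,
    "total_km2": 397254.3,
})

#: Initial area, excluded area (urban + off-register hydrography) and updated
#: (analysed) area per category, km².
EXCLUSIONS_BY_CATEGORY = pd.DataFrame([
    ("PA",    205449.5,  252.5, 205197.0),
    ("PAC",     4041.5,   11.5,   4030.0),
    ("PAD",    15603.4,   12.8,  15590.6),
    ("PAE",   106881.8, 1822.8, 105059.0),
    ("PAF",     3181.2,    2.6,   3178.6),
    ("PAM",       87.0,    0.0,     87.0),
    ("PAR",      851.1,    1.2,    849.9),
    ("PCA",       53.8,    1.2,     52.6),
    ("PDS",    31107.3,  103.8,  31003.5),
    ("PE",      4846.4,    1.8,   4844.7),
    ("PEAEX",   2093.6,   28.8,   2064.9),
    ("PEAS",      33.7,    0.0,     33.7),
    ("PIC",    25393.0,  130.1,  25262.9),
], columns=["category", "initial_km2", "excluded_km2", "updated_km2"])

#: Carbon (Pg C) per category: losses by the two monitoring sources, remaining
#: stock in forest / non-forest / cloud classes, pre-modern total, recent total.
CARBON_BY_CATEGORY = pd.DataFrame([
    ("PA",    1.82,       0.0412,    0.97, 0.11,    0.27, 3.21,   1.35),
    ("PAC",   0.028,      0.0,       0.03, 0.00011, 0.01, 0.07,   0.04),
    ("PAD",   0.18,       0.0,       0.08, 0.00218, 0.01, 0.27,   0.09),
    ("PAE",   0.081,      0.0000042, 1.24, 0.06,    0.34, 1.72,   1.64),
    ("PAF",   0.0046,     0.0,       0.05, 0.0,     0.0,  0.05,   0.05),
    ("PAM",   0.00000065, 0.0,       0.0,  0.0,     0.0,  0.0015, 0.0015),
    ("PAR",   0.0054,     0.0,       0.01, 0.0,     0.0,  0.01,   0.01),
    ("PCA",   0.0004,     0.000025,  0.0,  0.0,     0.0,  0.0009, 0.00044),
    ("PDS",   0.069,      0.00010,   0.36, 0.01,    0.11, 0.55,   0.48),
    ("PE",    0.038,      0.0031,    0.01, 0.01,    0.0,  0.06,   0.014),
    ("PEAEX", 0.0077,     0.0,       0.01, 0.0,     0.01, 0.03,   0.03),
    ("PEAS",  0.000042,   0.0,       0.0,  0.0,     0.0,  0.0006, 0.0006),
    ("PIC",   0.30,       0.00083,   0.05, 0.01,    0.01, 0.38,   0.073),
], columns=["category", "lost_prodes_PgC", "lost_pmdbbs_PgC", "forest_PgC",
            "nonforest_PgC", "clouds_PgC", "premodern_PgC", "recent_PgC"])

#: published Total row of the carbon table
CARBON_TOTAL = pd.Series({
    "lost_prodes_PgC": 2.53,
    "lost_pmdbbs_PgC": 0.0452,
    "forest_PgC": 2.82,
    "nonforest_PgC": 0.20,
    "clouds_PgC": 0.76,
    "premodern_PgC": 6.36,
    "recent_PgC": 3.78,
})

#: scalar results printed alongside the tables
RESULTS = {
    # mean annual clearing rates (km²/yr), settlements created 2000–2004
    "rate_traditional_pre2006_km2": 134.5,
    "rate_distinctive_pre2006_km2": 7.12,
    "rate_traditional_post2006_km2": 51.1,
    "rate_distinctive_post2006_km2": 5.16,
    # PA cohort created 2000–2008: forest before clearing and at creation
    "pa_original_forest_km2": 37582.2,
    "pa_forest_at_creation_km2": 21859.5,
    # original vegetation = analysed area − water
    "original_vegetation_km2": 390879.4,
    # mean annual settlement deforestation 2003–2013 vs region-wide mean rate
    "settlement_mean_annual_rate_km2": 3469.7,
    "region_mean_annual_rate_km2": 12943.0,
    # mean clearing per family (ha/family/yr), 5 yr after creation
    "family_rate_traditional_in_arc": 1.7,
    "family_rate_distinctive_in_arc": 1.6,
    "family_rate_traditional_out_arc": 1.0,
    "family_rate_distinctive_out_arc": 0.2,
}
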