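#!/usr/bin/env python
"""Reproduce the published accounting arithmetic.

The published per-category tables carry both the components and the derived
totals, shares and ratios; this script pushes the components through the
reporting layer and prints the derived values next to the published ones.
"""

import json
from pathlib import Path

from settlecarbon import published
from settlecarbon.reporting import ratio, round_half_away, share

RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    lc = published.LANDCOVER_BY_CATEGORY
    exc = published.EXCLUSIONS_BY_CATEGORY
    ct = published.CARBON_TOTAL
    ref = published.REGION
    res = published.RESULTS

    total_def = float((lc["prodes_deforestation_km2"] + lc["pmdbbs_clearing_km2"]).sum())
    updated = float((exc["initial_km2"] - exc["excluded_km2"]).sum())
    original_veg = updated - float(lc["water_km2"].sum())
    lost_pg = ct["lost_prodes_PgC"] + ct["lost_pmdbbs_PgC"]
    remaining_pg = ct["forest_PgC"] + ct["nonforest_PgC"] + ct["clouds_PgC"]

    checks = {
        "total deforestation (km²)": (round_half_away(total_def, 1), 160_410.1),
        "share of region clearing (%)": (share(total_def, ref.total_clearing_km2), 17),
        "cleared share of original vegetation (%)": (share(total_def, original_veg), 41),
        "settlement share of region area (%)": (share(updated, ref.region_area_km2), 8),
        "pre-modern carbon (Pg C)": (round_half_away(lost_pg + remaining_pg, 2), 6.36),
        "remaining carbon (Pg C)": (round_half_away(remaining_pg, 2), 3.78),
        "carbon-loss share (%)": (share(lost_pg, ref.total_C_loss_Pg), 20),
        "remaining-carbon share (%)": (share(remaining_pg, ref.remaining_C_Pg), 6),
        "rate ratio to 2005": (ratio(res["rate_traditional_pre2006_km2"],
                                     res["rate_distinctive_pre2006_km2"]), 18.9),
        "rate ratio 2006–2013": (ratio(res["rate_traditional_post2006_km2"],
                                       res["rate_distinctive_post2006_km2"]), 9.9),
        "PA forest left at creation (%)": (share(res["pa_forest_at_creation_km2"],
                                                 res["pa_original_forest_km2"]), 58),
    }
    out = {}
    for name, (got, want) in checks.items():
        ok = "ok" if got == want else f"MISMATCH (published {want})"
        print(f"{name:45s} {got:>12} {ok}")
        out[name] = {"computed": got, "published": want}
    (RESULTS / "published_checks.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
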