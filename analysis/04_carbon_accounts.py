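#!/usr/bin/env python
"""Carbon accounts and summary tables.

Attaches vegetation-class carbon densities to the reconciled fragments,
computes the per-settlement pre-modern / lost / remaining carbon triple, and
emits the per-category land-cover and exclusions tables plus the threshold
censuses.
"""

from pathlib import Path

from settlecarbon import carbon as carb
from settlecarbon import reporting
from settlecarbon.geodata import CarbonClassTable, read_registry, read_vector_layer

import pandas as pd

DATA, OUT, RESULTS = Path("scratch/data"), Path("scratch/out"), Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    frags = read_vector_layer(OUT / "fragments.geojson", ("final_class",))
    table = CarbonClassTable.read_csv(DATA / "carbon_classes.csv")
    registry = read_registry(DATA / "registry.csv")

    accounts = carb.settlement_accounts(carb.attach_density(frags, table))
    accounts = accounts.merge(
        registry[["settlement_id", "category", "state", "group"]], on="settlement_id")
    accounts.to_csv(RESULTS / "accounts.csv", index=False)

    lc = reporting.landcover_table(accounts)
    lc.to_csv(RESULTS / "landcover_by_category.csv", index=False)
    reporting.exclusions_table(accounts).to_csv(
        RESULTS / "exclusions_by_category.csv", index=False)
    census = reporting.threshold_census(accounts)
    pd.concat([df.assign(census=k) for k, df in census.items()]).to_csv(
        RESULTS / "census.csv", index=False)

    total = lc[lc["category"] == "Total"].iloc[0]
    lost = accounts["lost_MgC"].sum()
    pre = accounts["premodern_MgC"].sum()
    print(f"analysed area {total['total_km2']:.1f} km², "
          f"deforested {total['total_deforestation_km2']:.1f} km² "
          f"({reporting.share(total['total_deforestation_km2'], total['total_km2'])} %)")
    print(f"carbon: lost {lost / 1e6:.3f} Tg C of {pre / 1e6:.3f} Tg C pre-modern "
          f"({reporting.share(lost, pre)} %)")
    zero = census["census_zero"]["count"].iloc[-1]
    half = census["census_half"]["count"].iloc[-1]
    print(f"settlements with zero clearing: {zero}; with ≥50 % cleared: {half}")


if __name__ == "__main__":
    main()
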