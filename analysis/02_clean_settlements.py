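#!/usr/bin/env python
"""Clean the settlement vector map.

Filters the raw layer (region containment, allowed categories, registry
membership) and collapses every settlement to a single polygon, writing the
cleaned layer to scratch/out/ and the per-feature decision log to results/.
On the uncorrupted synthetic map every feature should simply be kept; rerun
after `settlecarbon simulate`-style perturbations to see the repair actions.
"""

from pathlib import Path

from settlecarbon import cleaning
from settlecarbon.geodata import read_registry, read_vector_layer, write_vector_layer

DATA, OUT, RESULTS = Path("scratch/data"), Path("scratch/out"), Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    layer = read_vector_layer(DATA / "settlements.geojson", ("settlement_id", "category"))
    registry = read_registry(DATA / "registry.csv")
    region = read_vector_layer(DATA / "region.geojson")["geometry"].iloc[0]
    cleaned, decisions = cleaning.clean_settlements(layer, registry, region)
    write_vector_layer(cleaned, OUT / "settlements_clean.geojson")
    log = cleaning.decisions_frame(decisions)
    log.to_csv(RESULTS / "cleaning_log.csv", index=False)
    print(f"kept {len(cleaned)} of {len(layer)} features; "
          f"actions: {log['action'].value_counts().to_dict() or 'none (clean map)'}")


if __name__ == "__main__":
    main()
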