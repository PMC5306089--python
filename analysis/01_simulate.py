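#!/usr/bin/env python
"""Generate the synthetic study landscape.

Builds the default mixed-biome landscape (20 settlements, forest + savanna
monitoring layers, carbon map, registry) and writes the four input layers
plus the exact ground truth under scratch/data/.  The printed summary shows
what the later stages should recover.
"""

from pathlib import Path

from settlecarbon import synth

OUT = Path("scratch/data")
SEED = 42


def main() -> None:
    ds = synth.generate(synth.SyntheticConfig(seed=SEED))
    ds.write(OUT)
    truth = ds.truth.class_areas
    cleared = truth["DEF_PRODES"] + truth["CLEAR_PMDBBS"]
    total = truth.drop(columns=["settlement_id", "reclassified"]).sum(axis=1)
    print(f"wrote {len(ds.settlements)} settlements to {OUT}")
    print(f"  biome mix: {len(ds.pmdbbs)} savanna clearing polygons, "
          f"{(ds.prodes['prodes_class'] == 'deforestation').sum()} dated clearings")
    print(f"  true cleared fraction: {cleared.sum() / total.sum():.3f}")
    print(f"  true carbon lost: {ds.truth.carbon['lost_MgC'].sum() / 1e6:.3f} Tg C "
          f"of {ds.truth.carbon['premodern_MgC'].sum() / 1e6:.3f} Tg C pre-modern")


if __name__ == "__main__":
    main()
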