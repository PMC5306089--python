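# settlecarbon

Deforestation and vegetation-carbon accounting for agrarian-reform
settlements in Brazil's Legal Amazonia.

Roughly 3,300 settlements administered by INCRA cover ~8 % of Legal
Amazonia, yet they concentrate a disproportionate share of forest clearing.
Quantifying that share — and the carbon it mobilised — requires reconciling
three vector products that disagree where they overlap: the annual
clear-cut monitor for forest vegetation (classes forest / non-forest /
hydrography / cloud / deforestation-by-nominal-year, minimum patch
> 6.25 ha), the savanna-biome clearing monitor (one un-dated clearing class,
minimum patch ≥ 2 ha), and a vegetation-carbon map (39 original-vegetation
classes plus hydrography and urban, each with a mean density in Mg C ha⁻¹).
`settlecarbon` implements that accounting as a tested pipeline over a
synthetic landscape generator with exact ground truth, standing in for the
proprietary source vectors.

## The accounting

For each settlement *s*, the overlay of the cleaned settlement polygon with
the three products yields atomic fragments *f* with area *a_f* and a single
final class decided by precedence: carbon-map urban (excluded) ≻ carbon-map
hydrography (water, zero carbon) ≻ monitor hydrography (excluded, or
reclassified as clearing where the savanna monitor saw clearing) ≻ dated
deforestation ≻ savanna clearing ≻ forest / cloud / non-forest.  With ρ(f)
the carbon density of the *original* vegetation class at *f*:

```
C_lost(s)      = Σ_{f cleared}   a_f · ρ(f)
C_remaining(s) = Σ_{f vegetated} a_f · ρ(f)      (forest + non-forest + cloud)
C_premodern(s) = C_lost(s) + C_remaining(s)       (conserved exactly)
```

Clearing dynamics use the nominal-year labels of the annual monitor
(an August→July window): cumulative clearing through year *y* is inclusive
of *y*; forest at official creation is original forest minus clearing
through the creation year; mean annual rates are compared between the
high-clearing period (through 2005) and the slowdown (2006–2013); and
per-family clearing is the area cleared in the five years after creation
divided by families and years.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
synthetic landscape (intermediates under `scratch/`, tables under
`results/`):

```
$ python analysis/01_simulate.py
wrote 20 settlements to scratch/data
  true cleared fraction: 0.176
  true carbon lost: 0.824 Tg C of 5.162 Tg C pre-modern
$ python analysis/02_clean_settlements.py
kept 20 of 20 features; actions: {'kept': 20}
$ python analysis/03_reconcile_landcover.py
796 fragments across 20 settlements
raster-oracle cross-check on S000: max class gap 0.000000 ha at 1 m
$ python analysis/04_carbon_accounts.py
analysed area 474.9 km², deforested 83.9 km² (18.0 %)
carbon: lost 0.824 Tg C of 5.162 Tg C pre-modern (16.0 %)
$ python analysis/05_temporal_dynamics.py
pre/post cohort: 16 settlements ({'pmdbbs_clearing_present': 4} excluded)
original forest 364.3 km², at creation 345.5 km² (95 % remained)
rate-ratio study (n=53+47): pre-2006 ratio 18.6 (design 18.9), 2006–2013 ratio 10.5 (design 9.9)
```

The recovered cleared fraction and carbon totals equal the generator's
ground truth (the 0.824 Tg C lost in step 04 is the number the generator
promised in step 01); the rate-ratio study recovers the designed 18.9× and
9.9× traditional-vs-distinctive clearing contrasts from the overlay alone.
`analysis/06_published_tables.py` re-derives the published category-table
arithmetic (17 % of region clearing, 41 % of original vegetation cleared,
6.36 Pg C pre-modern, 3.78 Pg C remaining, …) from the printed components.

A `settlecarbon` CLI exposes the same stages (`simulate`, `clean`,
`reconcile`, `carbon`, `temporal`, `report`, and a resumable
`pipeline run --config run.yaml`).

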