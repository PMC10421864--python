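# lucflux

Annual land-use mapping and net CO₂ flux accounting on gridded landscapes.

`lucflux` is for carbon-cycle and land-change scientists who need a tested,
reproducible implementation of emission bookkeeping for tropical
forest/peat landscapes: it maps land use every year from daily optical
reflectance, tracks conversions, fires and biomass, and prices the
resulting CO₂ fluxes with IPCC-style scaling factors carried as
min/central/max uncertainty envelopes.

## The model

For every grid cell *p* and year, the net flux is

```
E_T(p) = E_LUC(p) + E_BB(p) + E_PB(p) + E_PD(p) − Sink(p)
```

* **E_LUC** — land-use-change emissions,
  `CA · D_AGB · (CC_L + R_BGB·CC_L + R_WDL·CC_D) · 44/12`,
  where `D_AGB = AGB_pre − AGB_cur` is the aboveground-biomass drop on
  conversion (floored at 0), `R_BGB`/`R_WDL` scale it to the belowground
  and woody-debris-plus-litter pools, and `CC_L`/`CC_D` are live/dead
  carbon contents.
* **E_BB** — biomass burning,
  `BA · BD_AGB · BE · EF · (1 + R_BGB + R_WDL)`, with the fuel available
  over a year of *I* fires given by the geometric depletion sum
  `BD_AGB = Σ_{i=1..I} AGB_pre · (1 − BE)^(i−1)`
  (each fire combusts a burning-efficiency share of what the previous
  fires left).
* **E_PB** — peat burning per event,
  `BA · BurnD · DR · BulkD · BE · EF`, with the burned depth `BurnD`
  decaying by the rate schedule `DR` as the cell's cumulative fire ordinal
  grows.
* **E_PD** — oxidative decomposition of drained peat, `PA · EF(category)`.
  A peat cell counts as drained from the first year it is observed under
  shrub/grass, plantation or urban, and stays drained.
* **Sink** — growth uptake, `area · growth(category) · CC_L · 44/12`.

Land-use maps come from a five-fold voted random-forest classification of
228 features per cell (7 annual-composite band reflectances, 13 spectral
indices, 8 time-series statistics × 7 bands, and the 9×9-window mean and
SD of each of those 76), followed by post-processing: plantation is an
absorbing state, one-year urban/water→forest transitions become
shrub/grass, and cloud gaps are filled by neighbourhood majority. Fire
histories merge consecutive detection days into single ongoing fires under
a nominal-confidence (NCM) or all-confidence (LCM) regime. Every scaling
factor carries a (min, central, max) envelope, so each accounting run can
be repeated as Eavg/Emax/Emin; ensembles over fire regimes and biomass
sources are averaged arithmetically.

The package ships a synthetic-scene generator (scripted truth maps, fires,
peat, reflectance with clouds) and an independent brute-force oracle that
re-derives every flux by literal per-cell enumeration, so the entire
pipeline is testable without any satellite downloads.

## Worked example

```bash
lucflux report --config examples/demo.yaml --seed 1 --out runs/demo
```

The demo world is a 12×12 grid over 2000–2004 in which eight forest cells
convert to plantation in 2002 and one peat cell burns in 2002 and again in
2003. The command prints the island-total annual components (Tg CO₂ yr⁻¹):

```
         E_LUC      E_BB      E_PB      E_PD      Sink    E_Fire       E_T
year
2001  0.000000  0.000000  0.000000  0.000986  0.019097  0.000000 -0.018111
2002  0.095408  0.001056  0.006147  0.000986  0.019097  0.007204  0.084502
2003  0.000000  0.000739  0.003381  0.000986  0.020989  0.004121 -0.015883
2004  0.000000  0.000000  0.000000  0.000986  0.020989  0.000000 -0.020003
```

Reading it: the landscape is a small net sink (E_T < 0) except in 2002,
when the scripted deforestation (E_LUC) and the first, deepest peat burn
flip it to a net source. The 2003 repeat fire emits 0.55× the first burn's
peat emissions — exactly the second entry of the burn-depth decay
schedule — and the sink grows from 2003 onward because young plantation
grows faster than the forest it replaced. Maps, ledgers, regional
summaries and a run manifest are written under `runs/demo/`.

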