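# agbpot

Counterfactual reconstruction of potential above-ground biomass (AGB) over
a gridded forest domain, and of the human-driven biomass deficit it
implies.

## The problem

Deforested landscapes lose carbon twice: once when they are cleared, and
again — invisibly — when a changing climate erodes the stock they *could*
recover if left alone. Separating the two requires a counterfactual: the
potential biomass AGB_pot that each disturbed pixel would hold under the
current climate had clearing never occurred. With annual AGB_pot maps in
hand, the biomass deficit

    AGB_def = AGB_pot − AGB_obs

tracks the net, cumulative human imprint on the carbon stock: positive
where clearing has eroded biomass, negative where regrowth has overshot
the climatic potential, and its interannual change splits into a
climate-driven term (through AGB_pot) and a land-use term (through
AGB_obs).

## The method

AGB_pot is estimated by space-for-time substitution. Pixels inside intact
forest landscapes (IFL) are assumed to sit at their climatic potential, so
for each year a bagged ensemble of **model trees** — binary regression
trees whose terminal nodes hold multiple linear regressions — is trained
to predict that year's observed AGB inside IFL from a static monthly
climatology, latitude and an open-water flag, and then evaluated outside
IFL. Trees split greedily on sum-of-squares reduction over `⌈√p⌉` random
candidate features per node; predictions average over the ensemble
(n = 1 000 trees at full scale, 100 for routine runs). Observation
uncertainty propagates by re-running the whole pipeline on the 5th/95th
percentile observation maps. Basin totals are geodesic-area-weighted sums
in Pg C, restricted to the disturbed (basin-minus-IFL) region.

On top of the reconstruction the package provides the analysis statistics:
segment trends of the deficit series, detrended-anomaly correlation of
annual stock changes with a boreal-winter ENSO composite (MEI_w), spatial
and per-pixel temporal correlation maps, out-of-sample IFL validation, and
comparison of deficit dynamics with land-use series. A synthetic-world
generator with known ground truth (true potential surface, injected
disturbance history and ENSO coupling) makes every stage testable without
any external download.

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.

## Worked example

```sh
agbpot reproduce-synthetic --seed 1 --outdir demo_run
```

simulates a 40×40-pixel, 20-year world at the default study conditions and
runs the full pipeline — per-year training, potential prediction, deficit
accounting at three quantile levels, trend/ENSO statistics and holdout
validation. It prints:

```
AGB_obs 3.447 -> 3.210 Pg C
AGB_pot 4.142 -> 4.193 Pg C
deficit fraction 0.168 -> 0.235
```

Read: observed biomass in the disturbed region fell by 0.24 Pg C over the
period while the climatic potential stayed flat, so the deficit fraction
AGB_def/AGB_pot grew from 16.8% to 23.5% — continued clearing outpaced
regrowth. `demo_run/` then contains the full audit trail, e.g. in
`trend_report.json` the early-segment deficit trend (r = 0.92,
p ≈ 9×10⁻⁶), the ENSO correlation with the detrended potential increments
(r = −0.47, p = 0.044 — the injected negative coupling, recovered) versus
the observed increments (r = −0.44, p = 0.057), and in
`validation_report.json` the out-of-sample IFL biases (integrated −0.01%,
local mean relative 0.18%). `manifest.json` lists a SHA-256 per artifact;
re-running with the same seed reproduces every file byte for byte.

Library use mirrors the CLI:

```python
from agbpot import WorldConfig, generate_world, ForestParams, run_ensemble

world = generate_world(WorldConfig(seed=1))
runs, table = run_ensemble(world.agb_obs, world.climatology, world.masks,
                           ForestParams(n_trees=100), seed=1)
print(table.head())   # year, level, agb_obs_pg, agb_pot_pg, agb_def_pg, ...
```

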