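# Methods

`agbpot` reconstructs the *potential* above-ground biomass (AGB_pot) of a
gridded forest domain — the carbon stock that would exist under the current
climate had large-scale clearing never occurred — and from it the
human-driven biomass deficit

    AGB_def = AGB_pot − AGB_obs.

This note documents the model, the synthetic data that exercises it, the
numerical choices, and the limits of what the test suite demonstrates.

## The space-for-time reconstruction

The central assumption is a space-for-time substitution: pixels inside
intact forest landscapes (IFL) are at their climatic potential, so a model
trained to predict *observed* AGB from climate inside IFL can be evaluated
outside IFL to give the counterfactual potential there.

For every year (and every observation quantile level) a fresh ensemble of
`n_trees` model trees is fitted:

* **Features.** The 12 monthly layers of each climatology variable
  (precipitation in mm, mean temperature in °C, diurnal temperature range
  in °C by default — 36 continuous features), latitude in degrees (a proxy
  for photoperiod amplitude), and one categorical flag for large-scale
  open water, where passive-microwave biomass retrievals are unreliable
  and held constant in time.
* **Trees.** Greedy binary splitting that maximizes the reduction in the
  target sum of squares; `mtry = ⌈√p⌉` candidate features per node;
  thresholds at midpoints between adjacent sorted values, ties broken by
  (lowest feature id, lowest threshold); growth stops at `max_depth = 12`,
  at `min_leaf_rows = 2·(p_continuous + 1)` rows, or when no split reduces
  the criterion.
* **Leaves.** Each terminal node holds a multiple linear regression of the
  target on all continuous features (see *Numerical choices*), falling
  back to the leaf mean when the local design is exactly rank deficient or
  under-determined. This is what distinguishes a model tree from an
  ordinary regression tree: a forest of constant leaves approximates a
  smooth climate response by a staircase, while linear leaves track its
  local gradient and extrapolate sanely just outside the training
  envelope.
* **Bagging.** Each tree sees a with-replacement bootstrap resample of the
  training table, same size as the table; the ensemble prediction is the
  arithmetic mean over trees, clipped at zero. Per-tree randomness derives
  from `SeedSequence([master_seed, tree_index])`, so fits are independent
  of thread scheduling; training rows are canonically sorted by pixel id,
  so fits are invariant to input ordering.

The climatology is static; all interannual signal enters through the
yearly IFL training targets, which is exactly how the potential acquires
its climate-driven year-to-year variation. Inside IFL the potential *is*
the observation by definition, so the deficit is identically zero there
and every basin total is restricted to the disturbed (basin-minus-IFL)
region, weighted by geodesic pixel area on the mean-radius sphere
(R = 6 371 000 m) and converted as Mg C ha⁻¹ × ha × 10⁻⁹ = Pg C.

Uncertainty propagates by brute force: the whole pipeline runs
independently on the 5th-percentile, mean and 95th-percentile observation
maps with the same master seed, and the spread of the resulting deficit
tables is reported as the confidence range. Whether percentile runs should
re-train the forest (as done here, for symmetry) or reuse the mean-level
forest is an open choice; retraining treats every level as an equally
plausible observation history.

## Statistics

* Segment trends are OLS of the deficit-fraction series on year, reported
  with the Pearson r of value vs time; the break year (default 2005) is a
  fixed configuration choice, not an estimated change point.
* ENSO sensitivity correlates the boreal-winter composite of a bimonthly
  ENSO index (MEI_w: mean of Dec/Jan through Mar/Apr, with Dec/Jan assigned
  to the year containing the January) against *detrended* first differences
  of the potential and observed totals. The deltas isolate the annual sink;
  detrending removes the shared secular decline.
* All correlations are Pearson with the parametric two-sided p-value from
  t = r·√((n−2)/(1−r²)). The per-pixel primary-land vs deficit correlation
  map flags p < 0.05 with **no** multiple-testing correction — a
  deliberately liberal convention, appropriate for map display and kept
  for comparability, not for formal inference.
* Zero-variance inputs yield a flagged degenerate result in map contexts
  and an error in scalar contexts.
* Holdout validation splits IFL pixels ~50/50 at random, retrains on one
  half and predicts the other, reporting the integrated bias (bias of the
  area-weighted total) and the local mean relative bias (unweighted mean
  of per-pixel relative errors over pixels with at least 10 Mg C ha⁻¹
  observed, to keep near-zero denominators out of the average).

## The synthetic world

Because the real inputs are large external products, the package carries a
generator that emulates their statistical structure on a small grid
(default 40×40 at 0.25°, 1993–2012). Its defaults are the study
conditions, chosen once:

| parameter | default | why |
|---|---|---|
| `ifl_fraction` | 0.55 | intact share of the basin in the real domain |
| `initial_deficit` | 0.18 | deficit/potential ratio at the period start |
| `obs_spread` | 0.08 | relative half-width of the q05–q95 envelope |
| `obs_noise_sd` | 2 Mg C ha⁻¹ | pixel-scale retrieval noise |
| `enso_coupling` | −3 Mg C ha⁻¹ per MEI_w unit | produces detrended ΔAGB_pot vs MEI_w correlations near −0.6 for a unit-variance AR(1) index |
| `interannual_sd` | 1 Mg C ha⁻¹ | non-ENSO climate anomaly of the potential |
| `disturbance_intensity` | 0.015 yr⁻¹ | expected fractional loss in disturbed pixels |
| `clearing_loss_fraction` | 0.6 | biomass fraction lost per clearing event |
| `regrowth_rate` | 0.04 yr⁻¹ | exponential recovery toward potential |

The true potential surface is a linear-plus-saturating function of the
annual climate means and latitude (an amplitude-90 tanh response to
precipitation plus linear temperature, diurnal-range and latitude terms);
the saturation is deliberate, so a single global linear model cannot fit
it but a model-tree ensemble can. Monthly climatology layers carry
independent spatial structure around a shared base field — as real
monthly climatologies do — which keeps the training design away from
exact collinearity. The human-pressure surface that delineates IFL mixes a
broad gradient (an "arc" of clearing) with regional texture, so intact and
disturbed pixels interleave and share a climate envelope; clearing events
are Bernoulli per pixel per year with spatially clustered probability, and
the observation model adds iid pixel noise with a symmetric multiplicative
q05/q95 spread, so (q05+q95)/2 equals the mean by construction.

What the generator does **not** emulate: realistic geography or
seasonality phase-locking, spatially correlated observation error,
CO₂-fertilization trends, VOD retrieval physics, and any asymmetry in the
published percentile maps (their error distribution is uncharacterized, so
a symmetric spread is a modelling choice). Passing recovery tests
therefore demonstrates that the pipeline is correct and well-conditioned
under the stated data-generating assumptions — not that the real-world
reconstruction is unbiased.

## Numerical choices

* **Leaf regressions.** Features are centered in-leaf and the coefficient
  solve uses the SVD with a relative singular-value cutoff of 10⁻³;
  directions of the leaf design carrying less than 0.1% of the dominant
  singular value are excluded from the solve, and the intercept is
  recovered from the means. Monthly climate layers are strongly
  correlated, and coefficients estimated along near-null directions
  amplify target noise by an order of magnitude once a leaf extrapolates;
  the truncation bounds that amplification at a negligible cost in bias.
  Exactly rank-deficient designs (at machine-precision tolerance) fall
  back to the leaf mean.
* **Missing data** is NaN throughout, excluded from sums and regressions,
  never treated as zero. Rows with any missing feature are dropped from
  training and counted.
* **Orientation** is canonicalized at the I/O boundary: latitude
  south→north, longitude west→east, cell-center coordinates, half-open
  cells.
* **Determinism.** One master seed; every consumer derives a substream via
  `SeedSequence`. `run-all` with the same config and seed produces
  byte-identical artifacts (hash-verified in the manifest).
* Basin totals weight pixels by geodesic area. At 0.25° over a ~10°
  tropical domain the difference from equal-area weighting is below 1%,
  but the geodesic choice is physically correct and costs nothing.

## Problem sizes and run times

Routine runs and the test suite use 100-tree forests (the full-scale
analysis convention is 1 000 trees; ensemble error decays like 1/√n_trees,
and 100 trees leave the ensemble-sampling term well below the leaf-noise
term at these table sizes). The default synthetic study — 40×40 grid,
20 years, three quantile levels, plus a 20-year holdout validation — runs
in about a minute on one core. Monte-Carlo calibrations (ENSO sign
recovery, null rejection rates) use generator-only quantities on a 28×28
grid, 100 seeds.

## Known limitations

* The reconstruction inherits every bias of the space-for-time assumption:
  if disturbed pixels' climates fall outside the intact envelope, the
  forest extrapolates linearly from the nearest leaves, and nothing in the
  method can detect the resulting bias.
* The deficit is a small difference of two large totals; a persistent 2%
  bias in predicted potential moves the deficit by ~10%. Validation biases
  here are an order of magnitude smaller, but this sensitivity is why the
  deficit series, not the potential itself, is the recovery target.
* Trend significance ignores serial autocorrelation; the segment break is
  fixed, not estimated.
* Open-water pixels are predicted like any others but flagged; their
  observations are held constant in time, so their deficit dynamics are
  entirely model-driven.
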