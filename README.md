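# otogeo

Otolith-chemistry stock identification for long-lived fish: where did the
adults you sampled spend their first year of life, how many nursery areas
feed the population, and when did each fish leave shallow juvenile habitat?

Otoliths (fish ear stones) accrete material chronologically, so a radial
LA-ICPMS transect from the core to the edge is a chemical life history.
`otogeo` turns per-fish transects, region signatures (element:Ca ratios and
δ¹⁸O/δ¹³C of the nuclear and marginal otolith regions) and seawater-δ¹⁸O
observations into three linked results:

1. **Ontogenetic habitat shifts.**  Sr:Ca and Ba:Ca profiles are analysed
   with the Barry–Hartigan product-partition change-point model (Gibbs
   sampler, uniform priors p ∈ [0, 0.2] on the change probability and
   w ∈ [0, 0.2] on the signal-to-noise ratio).  A fish's shift age is the
   first ablation whose posterior change probability reaches 0.5, dated
   through an inverse von Bertalanffy growth model,
   t = t₀ − ln(1 − L/L∞)/k.  Juvenile-vs-adult signature differences are
   tested with paired within-fish contrasts (REML event random effect) and
   PERMANOVA on Mahalanobis distances with within-fish permutations.
2. **Number and mixing of nursery sources.**  Nuclear signatures are fitted
   with EM to Gaussian finite mixtures under the uneven-volume covariance
   family Σ_g = λ_g D_g A_g D_gᵀ (models VVV, VEV, VVE), selected by
   BIC = 2·loglik − m·ln n; mixing proportions get bootstrap standard
   errors.
3. **Geo-location of juvenile origin.**  A seawater-δ¹⁸O isoscape (additive
   splines on salinity/temperature/depth + per-stratum residual kriging with
   an exponential covariance) feeds the aragonite fractionation equation
   δ¹⁸O_oto = 4.64 − 0.21·T + δ¹⁸O_water.  Per grid cell and depth stratum,
   5000 Monte-Carlo draws propagate water, temperature and fractionation
   uncertainty; each fish's occurrence probability at a cell is the
   two-sided tail probability of its observed nuclear δ¹⁸O under that
   distribution.  Individual maps are averaged into synoptic maps, compared
   across sub-population polygons, and thresholded into top-5 % origin
   regions per mixture cluster.

A synthetic-data generator (`otogeo.simulate`) produces every input with the
statistical structure the analysis assumes — two-source mixtures, stepped
transects, and a water-δ¹⁸O field whose salinity/temperature/depth covariates
explain a calibrated 61 % of variance — so the whole pipeline is testable
end to end without external data.  See `docs/methods.md` for models,
assumptions and design decisions.

## Worked example

Simulate a study-sized dataset (45 fish, 16 fishing events, 500 water
observations) and run every stage:

```bash
otogeo run-all --seed 1 --out-dir demo
```

which prints (abridged):

```
simulated 45 fish into demo
wrote 90 region signatures for 45 fish
PERMANOVA pseudo-F = 11.229, p = 0.0010
Sr: median shift age 12.1 y (45/45 detected)
Ba: median shift age 12.1 y (45/45 detected)
best model: G=3 VVE (BIC -1122.9); proportions [0.408 0.326 0.265]
deviance explained by covariates: 0.619
synoptic mean probability: 0.259
```

Reading the output: nuclear and marginal chemistry separate strongly
(pseudo-F 11.2 with p at the permutation resolution), and the detected
habitat-shift ages centre on the generator's true shift age of 12 years.
The elemental mixture illustrates small-sample BIC noise: at n = 45 the
three-source fit edges the true two-source fit by ΔBIC = 0.34 (the grid is
in `demo/bic_grid_elemental.csv`); the isotopic signatures select the true
structure,

```
otogeo mixture --signatures demo/signatures.csv --kind isotopic --seed 1 --out-dir demo
best model: G=2 VVE (BIC -239.5); proportions [0.822 0.178]
```

with a dominant source near the generating 0.74/0.26 split.  The isoscape
covariates recover the generating 61 % deviance share (0.619), and the area
summary (`demo/area_summary.csv`) ranks the generating nursery area first:

```
area,mean_probability
C,0.234
A2,0.490    <- fish were seeded from nursery area A2
A1,0.335
B,0.094
```

Each stage is also callable on its own files (`otogeo simulate`,
`preprocess`, `ontogeny`, `changepoint`, `mixture`, `isoscape`,
`geolocate`), and everything the CLI does is a thin wrapper over library
functions (`otogeo.bcp`, `otogeo.bic_select`, `otogeo.fit_isoscape`,
`otogeo.occurrence_probability`, ...), which follow scikit-learn estimator
conventions where the method is fit/predict-shaped
(`ConstrainedGaussianMixture`, `BarryHartigan`, `ExponentialKriging`,
`IsoscapeModel`).

If you have the published per-fish data deposit, reshape it into the
signature-table layout and rerun the result stages with
`python scripts/reanalyze_deposit.py --signatures your_table.csv`.

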