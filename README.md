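# wqimap

Regional drinking-water monitoring programs collect large tables of
constituent concentrations — a dozen or more chemical, organoleptic and
microbial indicators per sample, over years of dry- and wet-season
campaigns — but the data are awkward to analyze directly: marginals are
right-skewed, values go missing, and every sample carries coordinates
that routine summaries ignore. `wqimap` condenses each sample into a
single **water quality index (WQI)**, interpolates the index over the
study region by **ordinary kriging**, and scores the interpolation by
**leave-one-out cross-validation**, so that a monitoring agency can turn
a raw records file into a quality map plus a defensible accuracy figure.

It is aimed at public-health and water-supply analysts working with
point-monitoring data (provincial networks, well surveys) and at anyone
who needs a compact, reproducible WQI-surface pipeline for teaching or
method comparison.

## The index

The WQI is the unweighted sum of per-indicator sub-indices,

```
I = Σᵢ Iᵢ
```

with three sub-index rules:

* **general constituents** (color, turbidity, odor, hardness, Fe, Mn,
  sulfate, chloride, TDS, COD, F, As, nitrate): `Iᵢ = Cᵢ / Sᵢ`, the
  measured concentration over the regulatory limit — exactly 1 at the
  standard;
* **pH**: `I_pH = (C_pH − 7) / 1.5`, a deviation score from neutrality
  (an `absolute` mode scores `|C_pH − 7| / 1.5`);
* **total and thermotolerant coliforms**: 0 for a non-detect, otherwise
  `ln(Cᵢ + 1) + 1`, so any detection jumps the score to ≥ 1 against the
  zero-tolerance microbial standard.

Limits Sᵢ are configuration, not code: a default table for the 16
routine indicators, populated from China's national drinking-water
standard, ships as editable JSON (`wqimap/data/standards_cn.json`).

## The surface and its accuracy

Scored WQIs are kriged with an isotropic variogram (spherical,
exponential or Gaussian; Matheron estimator + weighted least squares
fit with N(h)/h² weights), solving the standard ordinary-kriging system
with a Lagrange multiplier for unbiasedness. Leave-one-out
cross-validation yields paired observed/predicted WQIs summarized by

```
MAE  = (1/n) Σ |oᵢ − eᵢ|
MRE  = (1/n) Σ |oᵢ − eᵢ| / |oᵢ|
RMSE = √((1/n) Σ (oᵢ − eᵢ)²)
AC   = 1 − n·RMSE² / Σ (|oᵢ − ō| + |eᵢ − ō|)²
```

AC is algebraically Willmott's index of agreement: 1 for a perfect
surface, lower as predictions degrade. A synthetic-data module generates
full monitoring campaigns (spatially correlated latent quality,
lognormal concentrations, zero-inflated coliform counts, stratified
source/supply design, missing values) for testing and demonstration.

## Worked example

Generate a five-year, 128-point campaign, score it, compare strata,
krige, and cross-validate:

```sh
wqimap simulate --design paper_scale --seed 42 --out-dir data
wqimap score data/paper_scale_records.csv --out scored.csv
wqimap compare scored.csv --by source
wqimap krige scored.csv --nx 40 --ny 40
wqimap crossval scored.csv
wqimap map wqi_grid.csv --out map.png
```

Output (abridged):

```
{"n_scored": 1280, "n_issues": 0, "out": "scored.csv"}
{"factor": "source", "test": "welch_t", "statistic": -9.12, "p_value": 8.4e-18,
 "groups": [{"label": "groundwater", "n": 1010, "mean": 11.64, ...},
            {"label": "surface", "n": 270, "mean": 19.05, ...}]}
{"model": {"family": "spherical", "nugget": 7.76, "partial_sill": 48.8,
           "range": 196.7}, "outputs": {"csv": "wqi_grid.csv"}}
{"n": 128, "mae": 3.83, "mre": 0.310, "rmse": 5.15, "ac": 0.777, ...}
```

Reading it: all 1280 records scored cleanly; groundwater samples have a
markedly lower (better) mean WQI than surface water (11.6 vs 19.0,
Welch t, p ≈ 10⁻¹⁷) — the generator injects exactly such a penalty, and
the pipeline recovers it; the fitted spherical variogram has a ~197 km
range; and the leave-one-out agreement index of 0.78 says the kriged
surface reproduces the held-out site means reasonably well given the
deliberately noisy synthetic field. `map.png` is the blue-low/red-high
WQI heat map with the monitoring points overlaid.

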