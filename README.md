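# pestmap

Spatial-exposomics analysis tools for linking environmental pesticide
pressure to cancer incidence: a process-based multi-pesticide run-off risk
surface, developmental-lineage stratification of cancer registries,
standardized incidence ratios, a Bayesian disease-mapping model with
hotspot detection, and permutation-tested spatial autocorrelation. The
package is aimed at spatial epidemiologists and environmental-health
researchers who need the full chain — from raster hydrology to posterior
relative risks — in one tested Python library, exercisable end-to-end on
synthetic data with known ground truth.

## What it computes

**Run-off loss (per cell, month, active ingredient).** The OECD
lumped-parameter indicator

    L%_ro = (Q/P) · f · exp(−3·ln2 / DT50Soil) · 100/(1 + Kd),
    Kd = Koc · %OC/100

with monthly run-off Q and precipitation P (mm), a slope/interception/
buffer correction f ∈ [0, 1], the soil half-life DT50 (days; 3 days is the
assumed lag between application and the run-off event) and the sorption
coefficient Kd from Koc and soil organic carbon. Each factor is bounded, so
0 ≤ L%_ro ≤ 100 whenever Q ≤ P.

**Topographic transport.** Losses are routed cell-to-cell by D8 steepest
descent; at each step a configurable fraction of the mobile load moves
downstream and the rest deposits. Mass is conserved exactly, and routing is
linear in the input load.

**Risk surface.** All (AI, month) deposition layers are averaged, min–max
normalized to 0–100, optionally calibrated by district cultivated-land
fractions, and summarized per district (mean/median/min/max zonal
statistics). Two climate phases can be compared with a paired t test.

**Lineage stratification.** ICD-10 registry records (C00–C96) are curated
(duplicates, < 5 years residency, malformed codes — each drop carries a
reason) and grouped by embryonic germ-layer origin into six lineages
(surface vs parenchymal endoderm/ectoderm, mesenchyme, non-mesenchymal
mesoderm, neuroectoderm, primitive cells) plus explicit exclusion groups
(undetermined C76–C80, trophoblastic C58, odontogenic C75.2).

**SIR mapping.** Indirect standardization over six sex × age strata
(female/male × 0–39, 40–59, ≥60): E_i = Σ_j r_j η_ij, SIR_i = Y_i/E_i,
with the pooled study population as the internal standard.

**Bayesian spatial model.** The Besag–York–Mollié model
y_i ~ Poisson(E_i θ_i), log θ_i = β0 + β1 P_i + u_i + v_i with an ICAR
structured effect u on the queen-contiguity adjacency and an exchangeable
effect v, fitted by Metropolis-within-Gibbs MCMC (seeded, reproducible).
Hotspots are districts whose 95% credible interval for θ_i lies entirely
above 1; models are compared with DIC and WAIC; a zero-inflated Poisson
variant supports sensitivity analysis.

**Spatial statistics.** Global, local and bivariate Moran's I with Monte
Carlo permutation inference (two-sided, +1-corrected p values).

## Worked example

`examples/spatial_model.py` simulates counts for 100 districts from the
generative model with a known exposure effect β1 = 0.5, refits it, and
prints:

```
true beta1 = 0.5; posterior beta1 = 0.523 [0.441, 0.616]
DIC = 669.3, WAIC = 656.9
hotspots (RR credible interval entirely above 1): 29 of 100 districts
    rr_mean   rr_lo   rr_hi
9    10.539  10.077  11.007
66    3.681   3.103   4.317
...
```

The credible interval covers the simulated truth, and the flagged
districts are those whose combination of exposure and spatial random
effects puts their relative risk credibly above 1. The other scripts in
`examples/` walk through the fate equation (`fate_loss.py`), the full
raster-to-district risk chain (`route_and_risk.py`), registry curation and
stratification (`lineage_stratification.py`), SIR tables
(`sir_mapping.py`) and Moran inference on biomonitoring data
(`moran_tests.py`).

A thin CLI chains the stages on disk artifacts
(`pestmap demo --seed 3 --out run/` runs simulate → fate → route →
aggregate → zonal → stratify → sir → fit → hotspots → moran and writes a
summary report).

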