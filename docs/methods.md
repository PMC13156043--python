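# Methods

This note records the models implemented in `pestmap`, the defaults and
why, what the synthetic-data generator does and does not emulate, and the
numerical choices that an auditor of the pipeline would want stated.

## Environmental fate: the run-off loss indicator

For each cell, month and active ingredient (AI) the dissolved run-off loss
as a percentage of the applied amount is

    L%_ro = (Q/P) · f · exp(−3·ln2/DT50Soil) · 100/(1 + Kd).

- **Q, P** (mm/month): surface run-off and precipitation. `Q/P := 0` when
  both are zero (a dry month mobilizes nothing); `Q > 0` with `P = 0` is
  rejected as inconsistent input rather than clamped — the synthetic
  generator guarantees Q ≤ P, and real hydrology products that violate it
  should be fixed upstream, not silently masked.
- **The 3-day lag** in the exponent is the indicator's fixed assumption
  about the time between application and the first run-off event. It is a
  constant of the method (`LAG_DAYS`), exposed only for sensitivity use.
- **Kd = Koc · %OC/100**: the standard organic-carbon-fraction relation.
- **f = f_slope · (1 − interception) · (1 − buffer)** with the OECD
  polynomial in slope percent s = 100·tan(slope):
  f_slope = min(1, 0.001423·s² + 0.02153·s), saturating near s ≈ 20%. The
  exact field form of f varies by implementation; `f_override` lets a
  caller substitute any externally computed factor, cell-wise or globally.
- Application dose is deliberately not modelled: the output is a relative
  hazard score per AI, not a mass flux, so inventories without reliable
  dose data remain usable.

Bounds: each factor lies in [0, 1] (the sorption term in [0, 100]), hence
0 ≤ L%_ro ≤ 100 whenever Q ≤ P; monotone in every parameter in the
direction chemistry dictates. Both facts are property-tested.

## Routing

D8 single-flow-direction: each cell drains to the steepest-descent
neighbour (drop/distance, diagonals √2 longer), ties broken by the fixed
order N, NE, E, SE, S, SW, W, NW (first wins) so the field is
deterministic. Flats are resolved breadth-first from cells that already
drain, across equal elevation, which sends flat cells toward the nearest
descending edge; unresolvable flats and local minima are sinks. Depressions
are not filled: the generator produces landscapes with a regional gradient
that drains, and a pit would simply retain its arriving mass (conservation
still holds). Transport applies a scalar `transfer_frac` (default 0.5) at
every step: the deposited fraction stays, the rest continues downstream in
topological order. The split is a partition at every cell, so
Σ deposited = Σ input exactly; the operation is linear in the load. Both
are asserted against an independent per-packet simulation oracle.

The off-site extent diagnostic (distance from source cells at which
deposition still exceeds a threshold) is qualitative: without a transport
decay kernel the model cannot target a specific physical range, and none
is claimed.

## Risk surface

Per-cell mean over all (AI, month) deposition layers first, then a single
min–max normalization to 0–100 over the whole domain. A per-AI
pre-normalization (each AI's stack scaled to 0–100 before averaging) is
available behind a flag for intercompound-comparability sensitivity runs;
the plain order is the default because averaging raw losses preserves the
physical weighting between compounds. A constant field normalizes to
all-0 — a flat surface carries no relative risk signal, and raising an
error would make degenerate sensitivity runs needlessly fatal. Land-cover
calibration multiplies each cell by its district's cultivated fraction and
renormalizes; it is the simplest monotone scheme consistent with
"cultivated land scales exposure opportunity" and is isolated in one
function so alternatives can be swapped in. Zonal statistics use the
cell-centre rule for district membership; median of an even count is the
mean of the two central order statistics. Climate phases are compared with
a paired two-sided t test on cellwise differences; exactly-constant
differences are reported as degenerate rather than given a meaningless p.

## Lineage stratification

The shipped crosswalk maps every 3-character ICD-10 block C00–C96 to one
of six germ-layer groups or an explicit exclusion group, with 4-character
overrides (C22.0 hepatocellular → parenchymal; C75.2 → excluded
odontogenic). It is a compact, package-curated table: blocks with a
published group assignment follow it (GI tract, lung and skin as surface
epithelium; female genital organs and kidney as non-mesenchymal mesoderm;
C58 trophoblastic, C75.2 odontogenic and C76–C80 undetermined excluded);
the remaining blocks are assigned by standard histogenesis (e.g. C40–C41
bone → mesenchyme, C70–C72 CNS → neuroectoderm, C62 testis → primitive,
C81–C96 haematolymphoid → non-mesenchymal mesoderm). Melanoma (C43) is
carried under the neuroectoderm group: the schema has no separate
neural-crest class, and melanocytes are neuroectodermal in origin.

Curation drops, in order of precedence: malformed rows, non-C codes
(out_of_range), residency < 5 years, and duplicates (same record id or
identical field tuple — a deliberate simplification of clinical recurrence
linkage, which needs identifiers a registry export may not carry).
Curation is total and idempotent. Stratification reports the exclusion
groups as rows, so counts always sum to the curated total and percentages
(one decimal) are shares of that total.

## SIR

Six strata: sex × age {0–39, 40–59, ≥60}, left-inclusive band edges (40 is
in 40–59), age at diagnosis in integer years. The standard population is
the pooled study population (internal standardization) — no external
standard is assumed, and internal standardization makes the
population-weighted SIR equal 1 by construction, which the tests use as a
self-consistency oracle. The vectorized cluster flag (SIR > 1, strict)
carries a 1e-12 guard so float summation noise at exactly SIR = 1 cannot
flip it; the scalar API is exact. Raw SIRs are reported unsmoothed —
smoothing is the Bayesian model's job. Stratum rates are computed per
lineage group when lineages are mapped separately.

## Bayesian spatial model

Besag–York–Mollié with covariates: y_i ~ Poisson(E_i θ_i),
log θ_i = x_iᵀβ + u_i + v_i; u intrinsic CAR on queen contiguity with
precision τ_u and a sum-to-zero constraint, v iid Normal(0, 1/τ_v).
E_i enters as the multiplicative expectation — it already encodes
population structure through indirect standardization, so no separate
population offset is used by default (one can be added as a covariate).
The exposure covariate is z-scored by the caller before fitting for
sampler stability; β1 is reported on that standardized scale.

Priors: β ~ Normal(0, 10²), τ_u, τ_v ~ Gamma(1, 0.01) — common
disease-mapping defaults, all exposed in `SpatialModelSpec`. Inference is
Metropolis-within-Gibbs:

- β: per-coordinate random-walk Metropolis;
- u: updated one graph-colour class at a time (greedy colouring), so all
  mutually non-adjacent districts move as one vectorized block — valid
  because the ICAR full conditional of u_i depends only on neighbours and
  the likelihood is site-wise;
- v: all sites at once (conditionally independent);
- τ_u, τ_v: conjugate Gamma Gibbs, with the ICAR quadratic form
  Σ_edges (u_i − u_j)² and rank n_free − (#components with ≥ 2 nodes);
- proposal scales adapt toward 0.44 acceptance during burn-in only and are
  frozen afterwards, preserving detailed balance for retained draws;
- the sum-to-zero constraint is enforced every iteration by recentring u
  and absorbing the mean into the intercept, leaving the likelihood
  untouched;
- isolated districts have no ICAR prior and keep u_i = 0;
- ZIP variant: structural-zero indicators Gibbs-sampled at observed
  zeros, π ~ Beta(1, 1) updated conjugately.

Defaults: 4 chains × 5,000 iterations, 2,000 burn-in, thin 1; convergence
monitored by split-R̂ (warning above 1.1). Draws are bit-reproducible from
the seed (chain seeds spawned via `SeedSequence`).

Summaries: θ draws are the exponentiated linear predictor; RR mean and
percentile 95% CI per district; hotspot ⇔ CI lower bound > 1, strict.
DIC = D̄ + p_D with p_D = D̄ − D(θ̄) evaluated at the posterior-mean RR;
WAIC = −2(lppd − p_WAIC) with p_WAIC the sum of pointwise log-likelihood
variances; both match brute-force double-loop oracles to 1e-8 in tests.
Acceptance of the sampler is by frequentist calibration against the
generative model (interval coverage of β1, null false-positive rate of the
hotspot rule), not by numeric equality with any particular external
fitter.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, at
desk scale (default 64×64 cells, 12 months, 5 AIs, 100 districts):

- elevation = regional gradient + smoothed Gaussian random field (so
  drainage always exists); slope by central differences; SOC in
  [0.1, 8] %; monthly precipitation as a seasonal sinusoid with smooth
  spatial noise; Q = c(slope)·P with c ∈ (0.1, 0.9), so Q ≤ P cell-wise by
  construction;
- AI tables with log-uniform Koc ∈ [10, 1e5] L/kg and DT50 ∈ [1, 365] d;
  at the 31-AI inventory size the class labels follow the 19/7/5
  insecticide/fungicide/herbicide split;
- rectangular district tessellations with log-normal populations (≥ 100)
  split 50/50 by sex and by a young age pyramid (0.65/0.25/0.10),
  Dirichlet-jittered;
- counts drawn from the generative BYM model itself, with the ICAR effect
  sampled exactly via the spectral pseudo-inverse of the graph Laplacian
  (sum-to-zero per component) — feasible because n ≤ a few hundred;
- registry records with lineage mix, duplicates and short-residency rows
  injected at configurable rates; biomonitoring concentrations as a linear
  noisy proxy of local risk, truncated at 0.

What it does **not** emulate: real geography or climate teleconnections,
real AI chemistry, geocoding error, registry under-ascertainment, or
population migration. Passing tests therefore demonstrate the correctness
and calibration of the *methods* under their stated assumptions, not the
reproduction of any real-world risk map.

## Calibration experiments and problem sizes

The replicated experiments (`pestmap.experiments`) use a fixed scene of
100 districts on a 32×32 landscape with expected counts averaging ≈ 30 per
district — large enough for the asymptotics to be informative and small
enough that 40 MCMC fits complete in minutes:

- **β1 recovery**: 20 replicates at β1 = 0.5, τ_u = 4, τ_v = 16 (moderate
  spatial structure, random-effect sds 0.5 and 0.25); scored by 95%-CI
  coverage of the truth and posterior-mean bias.
- **Null hotspot calibration**: 20 replicates at θ ≡ 1 (β1 = 0 and both
  precisions infinite), so every flagged hotspot is a genuine false
  positive against the nominal one-sided 2.5%. Simulating a null with
  active random effects would make "false positive" ill-defined, since
  some districts would then truly have θ > 1.
- **Moran type-I error**: 200 iid replicates on a 7×7 rook grid with 999
  permutations, two-sided p by doubling the smaller +1-corrected tail.

## Numerical and interface choices

- Continuous rasters are written as float64 GeoTIFF so write→read
  round-trips are exact; label grids are int32. Georeferencing uses the
  standard ModelPixelScale/ModelTiepoint/GDAL_NODATA tags; a single
  projected plane is assumed throughout (no reprojection).
- Cells belong to the district containing their centre point; overlapping
  district polygons are rejected with the offending id pairs named.
- Nodata is a sentinel plus boolean mask; masked cells propagate as NaN
  through grid arithmetic and never enter statistics.
- The CLI derives per-stage seeds from the global seed by a stage-name
  hash, so any stage is independently reproducible.

## Known limitations

- The ICAR colour-class sampler mixes slowly for very strong spatial
  precision (τ_u ≫ 100); split-R̂ warnings surface this.
- The crosswalk is block-level; analyses needing 4-character resolution
  beyond the shipped overrides must supply their own table (validated on
  load).
- D8 routing cannot represent divergent flow on convex terrain; transport
  has no decay, so deposition patterns are upper bounds on reach.
- Raw SIR cluster flags carry no uncertainty; only the Bayesian hotspot
  rule should be interpreted inferentially.
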