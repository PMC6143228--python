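# Methods

This note documents the models implemented in `rangebridge`, the defaults
and units, what the synthetic generator does and does not emulate, and the
numerical and design choices made where the literature leaves them open.

## Coordinates, time, units

All coordinates are Euclidean eastings/northings in meters in a projected
CRS; the package never reprojects (inputs in lat/lon are out of scope).
Timestamps are UTC at second resolution. Time lags are measured in hours,
so the Brownian motion variance σ²m is in m²/h; published σ²m values are
often printed unitless, so any cross-study comparison must first fix the
time base. Areas are reported in hectares (1 ha = 10⁴ m²), perimeters in
meters, and shape complexity as perimeter/area in m/ha.

## Brownian bridge likelihood and σ²m estimation

For a fix triple (i−1, i, i+1) the interior fix is predicted by the bridge
spanning its neighbors: with α = (tᵢ − tᵢ₋₁)/(tᵢ₊₁ − tᵢ₋₁),

* mean: zᵢ₋₁ + α (zᵢ₊₁ − zᵢ₋₁)
* per-axis variance: v = (tᵢ₊₁ − tᵢ₋₁) α(1−α) σ²m
  + (1−α)² δ²ᵢ₋₁ + α² δ²ᵢ₊₁ + δ²ᵢ

The negative log likelihood sums the isotropic bivariate normal log
densities over **every second interior fix** (indices 1, 3, 5, …), so no
fix is simultaneously a predictor and a predictand. Two conventions in
this construction vary between implementations and are fixed here:

1. **The middle fix's own GPS error δ²ᵢ is added to v.** The observation
   is the bridge value plus independent positioning noise, so omitting it
   would attribute GPS jitter to movement. Tests with δ = 0 are unaffected
   by this choice.
2. σ²m is maximized by bounded scalar minimization of the NLL **in log
   space** (Brent, tolerance 1e-6 in log units) over a default bracket
   [1e-8, 10·max_step²/min_lag] m²/h. Optimizing log σ²m makes the search
   robust to the many-orders-of-magnitude range between stopover and
   movement variances. A solution at either bracket end is flagged
   (`at_bound`), which is how degenerate tracks (e.g. interior fixes lying
   exactly on interpolation lines) are surfaced rather than hidden.

## Dynamic variance profile (change-point windows)

A window of `window` consecutive fixes (default 11) slides along the track
one fix at a time. Within each window two models are compared:

* **null** — one σ²m for the window;
* **one breakpoint** — the window's fixes split at position b (each part
  keeping at least `margin` fixes, default 3), with σ²m estimated
  separately per part.

Both models are scored on the *same* set of likelihood terms — the
window's alternating interior fixes — with each part's σ²m maximized over
the terms whose center fix falls in that part. Scoring both models on
identical terms keeps −2·logL comparable; reconstructing leave-one-out
terms per part would change the data between models and bias selection
toward the model with fewer terms. Selection is by BIC with n = the
number of likelihood terms in the window (k = 1 vs 2 variance
parameters); ties within 1e-9 go to the null model (parsimony, and a
deterministic tie-break). A candidate breakpoint whose side contains no
likelihood term is skipped; when no candidate remains the null model wins
by construction, so a window that cannot split reproduces the plain
windowed estimate exactly.

Every non-margin fix of the window records the σ²m of its part under the
winning model; the final per-location σ²m is the mean over all windows
that scored that fix, and the first/last `margin` fixes of the track
inherit the nearest scored value. Per-interval σ²m is the mean of its two
endpoint values. At most one breakpoint is allowed per window; multiple
behavioral shifts emerge across overlapping windows. The default window
of 11 fixes corresponds to roughly two days at 4 fixes/day (10 gaps ≈ 40 h
of path; some field protocols quote 11 × 4 h = 44 h — both readings
describe the same window).

## Utilization distributions

* **Bridge UDs** (BBMM with constant σ²m, dBBMM with the profile): each
  interval's bridge density is averaged over `n_alpha` = 25 equally spaced
  α nodes with trapezoid weights, weighted by interval duration, summed,
  converted to cell masses, and renormalized. Node evaluation is truncated
  beyond 4.5 SD of the node mean (< 1e-5 of a node's mass), and a node
  with s(α) = 0 deposits its mass into the containing cell (point-mass
  convention; `bridge_density` itself returns 0 as a documented sentinel
  there, because a density value cannot represent a Dirac mass). By
  default all intervals are bridged (`max_lag_h = None`), matching field
  practice of bridging reduced cold-season sampling; an explicit
  `max_lag_h` excludes and logs long gaps.
* **KDE UDs**: product-Gaussian mixture evaluated at cell centers and
  renormalized. Bandwidths: h_ref = sqrt((var_x+var_y)/2)·n^(−1/6) (the
  ad hoc bivariate normal-reference rule; common h); h_LSCV minimizes the
  closed-form least-squares CV criterion on a 100-point log grid spanning
  [0.05, 2]×h_ref, with a boundary minimizer reported as non-convergence —
  the field-standard failure with heavily duplicated fixes is reproduced
  this way, operationalizing "did not converge" which otherwise has no
  agreed criterion; h_plug-in is a per-axis two-stage direct plug-in
  (normal-reference start for ψ₈, Gaussian kernels) — per-axis because the
  two-stage functional estimates are univariate, flagged in reports since
  some packages use a common h; h_100 is simply a manual bandwidth
  (default 100 m), named after the convention of hand-picking a round h to
  approximate a movement-model home range, with an optional helper that
  searches h to match a reference 95% isopleth area.
* **MCP**: the ceil(n·q/100) fixes closest to the arithmetic mean center
  (ties broken by earlier timestamp) and their convex hull; geometry only.

## Grids, isopleths, metrics

All estimators share one reference grid (origin snapped down to a multiple
of the cell size; the joint track bounding box plus a buffer, default
250 m). Isopleths are **cell sets**, not smoothed contours: cells are
ranked by mass (ties by row/col) and included until the cumulative mass
first reaches the level, so the region always holds at least the nominal
mass and nesting 50 ⊆ 95 ⊆ 99 holds by construction. Perimeter is the
rasterized boundary length under 4-neighborhood adjacency (grid edge
counts), hence complexity values are comparable only within this raster
convention — vector-GIS perimeters differ by a resolution-dependent
factor. The default cell size is 15 m: core-area contrasts between
methods hinge on stopover-scale bridge SDs (≈ the 5.5 m GPS error), which
coarser grids blur away. Isopleth areas converge under refinement once
cells resolve that scale (the suite checks < 5% change when halving 8 m to
4 m on a two-month fixture).

## Evaluation framework

* **AUC**: presence cells are grid cells containing ≥ 1 relocation (a cell
  with five fixes counts once — the classifier view is per pixel, and
  revisitation weighting would conflate intensity with classification);
  all other cells of the reference grid are pseudo-absences; the score is
  cell mass; AUC is the Mann–Whitney statistic with ties counted half.
  AUC is scale-dependent (it depends on grid and extent), which is why a
  single shared grid is mandatory. MCP and non-converged bandwidths are
  excluded.
* **Selection ratios**: used = 50% isopleth, available = 99% isopleth,
  u_i/a_i as cell-count proportions; w_i = u_i/a_i with the Manly
  classification (>1 selected, <1 avoided); a habitat present in the used
  region but absent from the available region yields an "undefined" flag
  rather than an infinite ratio.
* **Seasons**: cold = Dec–Feb, dry = Mar–Jun, rainy = Jul–Nov (the
  study-site convention; an equal 4-month splitter is provided since both
  conventions circulate). Seasonal reruns refit σ²m per season-contiguous
  block (gaps > 72 h split blocks) instead of slicing the global profile,
  so no estimation window spans a months-long gap between same-season
  blocks of different years; the cross-block intervals are excluded from
  seasonal UDs. Overlap between seasonal regions is reported as Jaccard
  plus both directed containment fractions, since no single overlap
  statistic is standard.
* σ²m summaries per habitat and per season use the per-location profile;
  fixes outside the habitat raster are binned as "unknown". The per-fix
  table (timestamp, σ²m, season, habitat) is exported as the
  analysis-ready input for downstream mixed-model work, which is outside
  this package's scope.

## Synthetic generator

The generator emulates a tropical VHF radio-tracking protocol: fixes at
0630/1100/1600/2000 (an evenly spaced subset, default 2/day, during
cold-season months), per-axis Gaussian GPS error with SD 5.5 m, and
roughly 17–19 months of tracking for two animals — comparable in scale to
1,400–1,900 locations per animal.

Movement is state-switching Brownian motion: a discretized Markov chain
over behavioral states (switches only at fix times; switch probability
1 − exp(−Δt/mean_dwell)), and, conditional on the state, independent
Gaussian increments with per-axis variance σ²m·Δt. This matches the
estimators' own generative model, so parameter recovery is well-posed.
Two optional departures from the pure law exist, both off in recovery
fixtures and on in the default study fixture:

* **Shelter anchoring**: on entering the most sedentary state the animal
  snaps to the nearest of a configured set of shelter sites and holds
  position — reproducing multi-day shelter stopovers and keeping the
  simulated range stationary despite the lack of an attraction term.
* **Diurnal rest** (`diurnal_rest`): the interval spanning the overnight
  gap has zero movement; the emulated species is strictly diurnal (the
  field protocol drops night checks for that reason), and without
  overnight stationarity a two-state chain at ~50% stopover time puts the
  tight-mass fraction of the UD on a knife edge at exactly the 50%
  isopleth level, which no real diurnal data set exhibits.

During held intervals (anchored or overnight) the recorded ground-truth
interval variance is 0, i.e. truth reflects what was generated, not the
nominal state parameter. Default states: stopover (σ²m = 1 m²/h) and
explore (σ²m = 2000 m²/h), mean dwell 72 h each, giving about half the
time at stopover sites and mean observed steps of tens of meters with
occasional ~1 km bursts. Habitat rasters are threshold-of-smoothed-noise
fields: white noise smoothed at a length scale (default 300 m) and cut at
the quantiles of the target category fractions (six categories loosely
mirroring a forest/plantation/agriculture/settlement/water mosaic).

What the generator does **not** emulate: home-range-center attraction,
terrain- or habitat-driven movement, missed fixes, heavy-tailed step
lengths, and autocorrelated GPS error. Consequently, passing tests show
that the estimators behave correctly *under their own model assumptions*
and reproduce the qualitative method orderings (bridge methods > KDE in
AUC, h_ref oversmoothing, LSCV collapse, smallest dBBMM cores) — they do
not certify performance on real telemetry with those unmodeled features.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical config + seed reproduce identical
CSV artifacts byte for byte. The test-suite and acceptance-script problem
sizes (1001-fix recovery tracks, 20 replicate seeds, ~1200-fix two-state
fixtures, the two-animal ~4000-fix study fixture on a 15 m grid) keep a
full run in the minutes range on a single CPU while leaving Monte Carlo
error well below the asserted tolerances.

## Known limitations

* The dBBMM window scheme estimates at most one change point per window;
  rapid alternation faster than the window (e.g. the day/night cycle at
  window 11 ≈ 2.5 days) is smoothed into intermediate σ²m values rather
  than resolved.
* LSCV is searched on a common-h grid only (the usual 1-D formulation);
  per-axis LSCV is not implemented.
* Isopleth perimeters are raster perimeters; complexity is not comparable
  across different cell sizes or with vector-based published values.
* The habitat generator produces quantile-banded categorical fields;
  category adjacency structure (e.g. settlements inside agriculture) is
  not modeled.
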