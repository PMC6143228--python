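# rangebridge

Home-range estimation and comparison for animal relocation data, built
around the **dynamic Brownian bridge movement model (dBBMM)** and the
classical estimators it is usually compared against: the standard BBMM,
fixed kernel density estimation (KDE) with four bandwidth selectors
(h_ref, h_LSCV, h_plug-in, and a manual h), and percent minimum convex
polygons (MCP). All utilization distributions (UDs) are computed on one
shared reference grid so that the evaluation framework — pixel-classification
AUC, isopleth area/perimeter/complexity, seasonal overlap, and Manly
habitat-selection ratios w_i = u_i/a_i — compares like with like.

The package targets movement ecologists working with VHF/GPS telemetry of
species that alternate multi-day shelter stopovers with exploratory bouts
(snakes and other reptiles being the motivating case). Because such field
data sets are rarely public, `rangebridge` ships a synthetic telemetry
generator with known ground truth (state-switching Brownian motion, shelter
anchoring, diurnal rest, a field sampling schedule, and GPS error), so the
whole pipeline is testable end to end.

## The model

A Brownian bridge between consecutive fixes `z_i, z_{i+1}` observed at
times `t_i, t_{i+1}` (lag `T = t_{i+1} - t_i`) places, at relative position
`α ∈ [0,1]`, an isotropic normal density with mean `z_i + α (z_{i+1} - z_i)`
and per-axis variance

    s(α) = T α(1-α) σ²_m + (1-α)² δ_i² + α² δ_{i+1}² ,

where `σ²_m` is the Brownian motion variance (m²/h, the animal's mobility)
and `δ` the per-fix GPS error SD. The UD is the duration-weighted average
of these bridge densities over all intervals. `σ²_m` is estimated by
maximum likelihood on a leave-one-out construction: every second interior
fix is predicted from the bridge spanning its neighbors. The BBMM uses one
`σ²_m` for the whole track; the dBBMM slides a window (default 11 fixes)
along the track and allows one behavioral change point per window (margin
3, BIC selection), yielding a per-location `σ²_m` profile that separates
stopovers from movement bouts.

## Worked example

```python
import rangebridge as rb
from rangebridge.simulate import default_study_configs, simulate_track

tracks = [simulate_track(c)[0] for c in default_study_configs(seed=1)]
grid = rb.make_reference_grid(tracks, cell_size=15.0, buffer=250.0)
result = rb.compare_estimators(tracks, grid)
full = result.table.query("season == 'all' and animal == 'SYN1'")
print(full.pivot(index="method", columns="metric", values="value")
          [["auc", "area_ha_50", "area_ha_99"]].round(3))
```

Output (seed 1; the LSCV row is absent because its bandwidth search ends on
the grid boundary and is flagged as non-converged):

```
metric        auc  area_ha_50  area_ha_99
method
bbmm        0.977      10.012     265.882
dbbmm       0.978       2.340     291.848
kde_h100    0.947      45.585     377.505
kde_href    0.942      91.980     502.695
kde_plugin  0.966      10.328     280.935
mcp           NaN         NaN         NaN
```

Reading: the two bridge methods classify presence/absence pixels best
(highest AUC); the dBBMM concentrates the 50% core on the true shelter
sites (smallest core area) while keeping a large 99% activity area; the
reference bandwidth h_ref oversmooths (largest areas, lowest AUC); the MCP
contributes geometry only (no UD), at the 95% level.

A YAML-driven CLI wraps the same pipeline:

```
rangebridge simulate --config config.yaml --out run/
rangebridge estimate --config config.yaml --out run/
rangebridge evaluate --config config.yaml --out run/
rangebridge report   --config config.yaml --out run/
```

writing tracks/truth CSVs, habitat and UD rasters (ESRI ASCII grid),
region GeoJSON, tidy evaluation tables, and a plain-text report.

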