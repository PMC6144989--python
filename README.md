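# wintrack

Winter-recreation intensity surfaces and wildlife space-use statistics.

Dispersed winter recreation (snowmobiling, backcountry and packed-trail
skiing, snowmobile-assisted "hybrid" skiing) and developed ski resorts
overlap the winter ranges of snow-adapted carnivores such as Canada
lynx (*Lynx canadensis*).  `wintrack` implements the full analysis
chain a movement ecologist needs to quantify that interaction from GPS
data:

* **Recreation pressure** — convert recreationist GPS tracks (5-s
  fixes) into circular-neighborhood point-density rasters
  (points/km² at 30 m–1 km radii), extract high-use *trail* skeletons
  from the 100-m surface (cells above the 25th percentile of nonzero
  density, morphologically thinned), and derive trail-proximity
  covariates (binary 250/500/1000 m; decay `exp(-α/d)` with
  α ∈ {50, 100, 250, 500, 2500}), plus trail-counter use indices
  (hits/day).
* **Behavior** — step lengths and turn angles from collar fixes;
  active/stationary classification calibrated on stationary test
  collars (stationary iff step ≤ 70th-percentile jitter step, 27.02 m
  at the default calibration, or turn angle in the near-reversal band
  [174°, 180°]); sunrise/sunset day/night periods (NOAA solar
  equations); 95% MCP home ranges; movement rate over active steps
  (km/hr) and path tortuosity (net/gross displacement).
* **Selection** — third-order used–available resource selection
  functions (1 used : 2 available inside the 95% MCP, available rows
  weighted 1/2 so both classes carry equal weight) fitted as
  random-intercept logistic GLMMs ranked by AICc, with five-fold
  cross-validated AUC; diel-activity GLMMs with area × period strata;
  functional responses (use vs. availability across individuals,
  linear vs. quadratic by exact likelihood-ratio/F test) and Manly
  selection ratios.
* **Developed-area avoidance** — a 1,000-iteration Monte-Carlo
  bootstrap comparing each animal's fix count inside a ski-area polygon
  with the 2.5–97.5 percentile band expected of a uniform user of its
  home range, and a GLMM of ski-area entry against month, weekend,
  night and canopy.
* **Synthetic scenarios** — a generator with known ground truth:
  autocorrelated canopy rasters, trail-following recreation tracks, and
  two-state animal trajectories from a Metropolis-corrected biased
  random walk whose stationary density is exactly
  `exp(Σ β·z)` — so every estimator above has a recoverable target.

The gaussian mixed models go through `statsmodels`; the weighted
random-intercept logistic GLMM is implemented here (Gauss–Hermite
quadrature, analytic gradients, optional cluster-robust/jackknife
standard errors) because no installed library provides one with
observation weights.

## Worked example

```python
import numpy as np
import wintrack as wt

cfg = wt.ScenarioConfig(seed=7, n_animals=4, n_days=7,
                        beta_avoid={"snowmobile": -1.0})
sc = wt.generate_scenario(cfg)

# recreation intensity at 1 km, trails from the 100-m surface
surf = sc.surfaces[("snowmobile", 1000.0)]
trails = wt.extract_trails(sc.surfaces[("snowmobile", 100.0)])

# classify activity with the default stationary-collar calibration
states = wt.classify_activity(sc.fixes)
print("fraction active:", (states == "active").mean().round(3))

# used-available RSF for snowmobile intensity
tab = wt.build_use_available_table(
    sc.fixes, {"snowmobile": surf}, canopy=sc.canopy, grid=cfg.grid,
    rng=np.random.default_rng(1),
)
out = wt.fit_rsf(tab, "snowmobile", cv=False)
print(out["ranking"][["label", "aicc", "delta_aicc"]].head(3))
print(out["best"].params.round(3))
```

prints (numbers from this exact seed):

```
fraction active: 0.618
                      label         aicc  delta_aicc
0  canopy+int+area+int:area  5054.235462    0.000000
1                canopy+int  5055.056035    0.820573
2                canopy*int  5056.953493    2.718031
Intercept                               0.083
C(area)[T.west]                        -0.139
canopy                                 -0.002
intensity_snowmobile                   -0.185
intensity_snowmobile:C(area)[T.west]    0.073
dtype: float64
```

The intensity-bearing models clearly beat the canopy-only base model,
and the snowmobile-intensity coefficient is negative in both study
areas (−0.185 in the reference area, −0.185 + 0.073 = −0.112 in the
other): animals generated to avoid snowmobile pressure are detected as
avoiding it.  The magnitude is attenuated relative to the generating
−1 because this quick example standardizes intensity over the sample
and estimates each availability domain with an MCP from only ~500
fixes; `docs/methods.md` discusses both effects, and the acceptance
experiments recover the coefficient to within a few percent under the
estimand-aligned design.

The bootstrap avoidance test follows the same pattern:

```python
mcp = wt.mcp_home_range(fixes_xy, 95)
res = wt.bootstrap_ski_test(fixes_xy, mcp, ski_polygon,
                            iterations=1000, rng=np.random.default_rng(2))
print(res.n_inside, res.lower, res.upper, res.classification)
```

An observed count below the lower bound is classed `avoidance`, above
the upper bound `preference`, otherwise `no_difference`.

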