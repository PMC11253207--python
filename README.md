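# nocmig

Analysis of nocturnal bird migration from vertical-looking and weather
radar: nightly **migration traffic rates** (MTR), Rayleigh-test
directionality filtering, atmospheric covariates interpolated to flight
altitude, **tailwind/airspeed decomposition**, **boosted-regression-tree
weather-selectivity models** with staged cross-validated tree selection,
and seasonal contrasts via linear mixed models — plus a synthetic
radar-night generator so every stage can be verified against known ground
truth without any radar or reanalysis download.

Intended users: radar aeroecologists and movement ecologists who have
echo-level bird detections (timestamp, altitude, ground velocity, class
label) from BirdScan-type vertical-looking radars or bird profiles from
weather radars, and who want a reproducible night-by-night pipeline from
raw echoes to weather-selectivity inference.

## The quantities it computes

* **MTR** — birds crossing a 1 km transect perpendicular to the movement
  per hour: per elevation bin, `MTR = n / (w_km · Δt_h)`; summed over bins
  per sunset-anchored hour and averaged per night, discounted by the
  **directional proportion** (mean resultant length R̄, gated by the
  Rayleigh test `p = exp(√(1+4n+4(n²−R²)) − (1+2n))` at α = 0.05).
* **Wind decomposition** — with wind (u, v), wind bearing
  `αwind = atan2(u, v)` (toward-convention) and seasonal mean migration
  direction `αmig`, the tailwind component is
  `TW = s·cos(αwind − αmig)` and `airspeed = groundspeed − TW`
  (nights with ≥ 5 bird tracks).
* **Weather selectivity** — Gaussian boosted regression trees of
  log(directional MTR + 1) on 15 covariates (weather at 500 m above the
  radar, night-over-night deltas, geography, ordinal date, radar type),
  learning rate 0.001, tree complexity 10, bag fraction 0.5, 10-fold CV
  with 25-tree steps; relative importances scaled to 100 and marginal
  (partial-dependence) response curves.
* **Seasonal contrasts** — mixed models with a random radar-location
  intercept for speed differences, Welch t-tests at a Bonferroni-adjusted
  level (0.0125 for four weather variables), and derived percentage
  contrasts of the seasonal mean speeds.

See `docs/methods.md` for the full model description and conventions.

## Worked example

```python
from nocmig import SimWorld, SiteConfig, speed_contrasts
from nocmig.pipeline import run_pipeline, save_config

world = SimWorld(
    sites=[SiteConfig("hula", 33.1, 35.6, 70.0, "vertical-looking"),
           SiteConfig("negev", 30.6, 34.8, 470.0, "weather")],
    seasons=[("spring", 2018), ("autumn", 2018)],
    max_nights_per_season=30,
    rng_seed=11,
)
save_config(world, {"learning_rate": 0.01, "max_trees": 2000}, "run.yaml")
run_pipeline("run.yaml", "results")
print(open("results/contrasts_summary.txt").read())
```

prints

```
Seasonal contrasts
==================

groundspeed: spring 10.83 vs autumn 17.83 (lmm, stat=-23.88, p=2.19e-46, alpha_adj=0.05: significant)
airspeed: spring 16.04 vs autumn 13.08 (lmm, stat=32.02, p=4.08e-59, alpha_adj=0.05: significant)
temperature: spring 9.38 vs autumn 15.57 (t, stat=-13.01, p=1.58e-24, alpha_adj=0.0125: significant)
u: spring 1.84 vs autumn 1.86 (t, stat=-0.06, p=0.948, alpha_adj=0.0125: not significant)
v_raw: spring -5.87 vs autumn -4.57 (t, stat=-4.01, p=0.000109, alpha_adj=0.0125: significant)
wind_speed: spring 6.53 vs autumn 5.43 (t, stat=3.54, p=0.000585, alpha_adj=0.0125: significant)

airspeed: 23% lower in autumn (difference 3.0 m/s)
groundspeed: 65% higher in autumn (difference 7.0 m/s)
```

Reading this: the generator gave the synthetic spring migrants a true mean
airspeed of 16.0 m s⁻¹ and the autumn migrants 13.5 m s⁻¹; the pipeline
recovers 16.04 and 13.08 from the echoes alone.  Spring nights are
headwind-dominated (negative raw v, higher wind speed), so spring
groundspeeds are much lower than autumn ones in this two-site world — the
mixed-model season effects and the Welch tests quantify exactly that.  The
model stage also writes `model_spring.json` / `model_autumn.json` (selected
tree count, CV correlation, importance table summing to 100) and
`marginal_responses.csv` with the partial-dependence curves.

Applied to printed seasonal speed means rather than simulation output, the
same contrast routine gives the familiar headline numbers:

```python
>>> speed_contrasts(15.1, 15.7, 16.06, 13.6)
{'airspeed_diff_ms': 2.5, 'airspeed_pct_of_autumn': 18,
 'groundspeed_diff_ms': 0.6, 'groundspeed_pct_of_spring': 4}
```

— an airspeed 18 % lower in autumn (2.5 m s⁻¹) against a 4 % (0.6 m s⁻¹)
groundspeed difference.

The same pipeline is available from the shell:

```bash
nocmig all --config run.yaml --out results
nocmig simulate --config run.yaml --out results   # single stage
```

Re-running with the same configuration and seed reproduces byte-identical
CSV outputs; `results/manifest.json` records the config hash, per-stage row
counts and file hashes.

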