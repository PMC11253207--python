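# Methods

`nocmig` implements a complete nocturnal-bird-migration analysis chain for
vertical-looking (BirdScan-type) and weather radar deployments, together
with a synthetic radar-night generator that supplies data with known ground
truth.  This note documents the models, the conventions, the generator's
assumptions and the places where a design choice was genuinely open.

## 1. Migration traffic rate

MTR is the number of birds crossing a theoretical 1 km transect
perpendicular to the direction of movement per hour (birds km⁻¹ h⁻¹).  With
a zenith-pointing radar every detected echo is one transect crossing, so
within an elevation bin

    MTR_bin = n_bin / (w_km · Δt_h)

where `w_km` is the bin's effective transect width and `Δt_h` the
observation window in hours.  Per night, bin MTRs are summed over elevation
bins within each clock hour anchored at sunset and averaged over the
night's hours.  Hours fully covered by a rain interval are excluded from
the average; a night with no rain-free hours yields a missing value.
Default bins are 50 m wide from 50 to 1500 m AGL; the cap reflects the
analysis band, the width is configurable (the bin width only matters
through the per-bin transect widths).

Filtering conventions, fixed because the procedure itself does not pin
boundaries: the night window is closed `[sunset, sunrise]`; short-pulse
altitudes are half-open `[50, 800)` m AGL and long-pulse closed
`[800, 1500]` m (their union is the full band with empty intersection);
rain intervals are half-open `[start, end)`.  Sunset and sunrise are
computed with the NOAA solar-position algorithm at solar elevation −0.833°
(refraction-corrected disk edge); geometric sunset rather than civil
twilight is an explicit choice.  Nights are keyed to the evening's calendar
date in longitude-based local time, since a night spans two UTC dates.

### Directional proportion

Local non-directional movements (foraging, display flights) inflate MTR.
The night's track directions are tested for circular uniformity with the
Rayleigh test: with mean resultant length R̄ and R = nR̄, the p-value uses
the standard approximation

    p = exp( √(1 + 4n + 4(n² − R²)) − (1 + 2n) ).

The directional proportion is R̄ when uniformity is rejected at α = 0.05
and 0 otherwise, and the analysis uses `directional MTR = proportion ×
nightly MTR`.  R̄ is the natural estimator of the directional mixture
weight — a mixture of a tightly concentrated component of weight f with a
uniform background has R̄ → f — and the p-value gate keeps pure-noise
nights from passing through.  A night with no echoes at all has directional
MTR 0 (no traffic), while its proportion is left undefined.

## 2. Atmospheric covariates

Pressure-level fields (temperature, u, v, relative humidity, vertical
velocity, cloud cover, geopotential height on 1000–550 hPa) are
interpolated linearly in geopotential height to 500 m above each radar's
elevation, averaged over the night, and assembled into 15 covariates:
the six interpolated variables, the overall wind speed s = √(u²+v²),
night-over-night changes of temperature, u and v, latitude, longitude,
elevation, ordinal date (Jan 1 = 1) and radar type.  Choices:

* **v sign convention.**  v is flipped in autumn so positive always means
  wind blowing in the seasonal migration direction (north in spring, south
  in autumn); the unrotated components are kept alongside (`u_raw`,
  `v_raw`) for the flight trigonometry and the seasonal weather tests.
* **Nightly wind speed** is the mean of hourly speeds, not the magnitude of
  the mean vector (the alternative understates speed when direction varies
  within a night).  Computed from the unrotated components.
* **Deltas** are current night minus the immediately preceding night and are
  missing — never zero — on a season's first night or after a gap.
* Below the lowest model level values are clamped to that level (logged).

A pairwise Pearson screen flags |r| ≥ 0.7 among numeric predictors but
drops nothing; constant columns are reported as undefined.

## 3. Wind decomposition of flight speeds

Wind is stored as (u east, v north); bearings are degrees clockwise from
geographic north in the *toward* sense.  The wind bearing is
αwind = atan2(u, v) and the tailwind component along the seasonal mean
migration direction αmig is

    TW = s · cos(αwind − αmig),

so TW = +s for wind blowing along the migration direction.  (Quoting the
same atan2 expression as a *from*-bearing — as some sources do — makes a
perfect tailwind negative under the identical cosine formula; the toward
convention is therefore the default and `strict_from_convention=True`
flips the sign for auditing.)  αmig is the circular mean of all of a
site-season's filtered track directions, held fixed for every night of
that site-season.  Per night with ≥ 5 bird tracks, airspeed is estimated
as the scalar difference

    airspeed = mean groundspeed − TW,

using the night-mean wind interpolated to the 500 m flight level.  The
scalar estimate is the field's standard procedure and is reproduced as
such: under pure tailwind with no heading spread it is exact; under pure
crosswind it overestimates airspeed by roughly w⊥² / (2·gs) because mean
groundspeed contains the crosswind magnitude.  The property suite asserts
the sign of this known bias rather than hiding it.

## 4. Boosted regression trees

Nightly selectivity is modelled as log(directional MTR + 1) — the +1 keeps
zero-traffic nights finite and the log symmetrises the heavy right tail —
on the 15 covariates, with Gaussian (squared-error) stagewise boosting:

* learning rate 0.001, tree complexity 10 (splits per tree, implemented as
  best-first growth to 11 leaves), bag fraction 0.5, 10-fold CV, trees
  added in steps of 25, spring and autumn fitted separately.
* **Staged tree selection.**  Ten fold models are grown in parallel; after
  each 25-tree step the mean held-out squared error is recorded.  Growth
  stops once the minimum has not improved for 3 consecutive steps (the
  exact stopping tolerance of the classic stepwise procedure is not
  published; a 3-step plateau is used and recorded here), capped at 10 000
  trees.  The selected tree count minimises held-out deviance; the final
  ensemble is refit on all data with that count.  The CV correlation is the
  Pearson r between out-of-fold predictions at the selected count and the
  response.
* **Relative importance** follows the classic definition: per variable, the
  squared-error improvement of every split it makes, summed over all trees
  and scaled so the total is 100.  A fit with no informative splits returns
  all zeros with a warning.
* **Marginal (partial-dependence) responses** average the ensemble
  prediction over the data with one covariate pinned to grid values; points
  outside the observed range are computed but flagged as extrapolation, and
  an optional back-transform exp(·)−1 returns to the MTR scale.
* The base learner is scikit-learn's regression tree; the ensemble loop,
  CV selection, importance and partial dependence are implemented in this
  package (they are the reported quantities).  Missing covariate values
  (first-night deltas) are kept as NaN and routed by the tree splitter to
  the side that improves the split — no imputation.  The two-level radar
  type is ordinal-encoded, which is lossless for a binary factor.
* Determinism: all randomness (fold assignment, bagging, tie-breaks) flows
  from one seed; identical seed and data give identical fits.

## 5. Seasonal contrasts

Seasonal differences in nightly groundspeed and airspeed use a linear
mixed model with a fixed season effect and a random radar-location
intercept, REML-estimated via statsmodels MixedLM.  statsmodels provides no
Satterthwaite denominator df; the reported df is the residual-style n − p,
which at the night counts involved is indistinguishable from any df
approximation.  With a single site the model degrades to an ordinary
two-sample comparison (logged).  Four weather variables (temperature, u,
raw v, wind speed) are compared between seasons with Welch t-tests —
pooling is not specified by convention, and unequal variances are the safe
default — judged at the Bonferroni level α/4 = 0.0125.

The derived ratio statistics express the airspeed difference
(spring − autumn) relative to the *autumn* mean and the groundspeed
difference (autumn − spring) relative to the *spring* mean; these are the
references under which the conventional phrasings "X % lower in autumn" /
"small difference of Y %" reproduce from the printed seasonal means.
Differences are rounded to one decimal, percentages to the nearest integer
(computed from unrounded differences).

## 6. The synthetic radar world

The generator emulates the statistical structure the analysis assumes, for
the Levant system: two migration seasons (spring March–May, peak
mid-April, northward; autumn August–November, peak early September,
southward), winds predominantly from the N/NW (toward ~SSE) and stronger
in spring, so spring migrants face headwinds and autumn migrants
tailwinds.

**Weather.**  Hourly pressure-level stacks on 1000–550 hPa with ICAO
standard-atmosphere geopotential heights.  Sea-level temperature = seasonal
mean (16.7 °C spring, 21 °C autumn) + linear seasonal drift + a 4 °C
diurnal cycle peaking at 14:00 local + a night-to-night AR(1) anomaly
(sd 2.5 °C, ρ 0.7); a 6.5 °C km⁻¹ lapse rate maps it to altitude.  Wind =
seasonal mean vector (6 m s⁻¹ spring / 4 m s⁻¹ autumn toward 157.5°) +
AR(1) component anomalies (sd 2 m s⁻¹, ρ 0.7), with ~10 % km⁻¹ shear.
Weather is keyed to coordinates, not site identity, so co-located radars
of different types observe the same atmosphere.

**Nightly intensity.**

    λ = base · exp(−(doy−peak)²/2σ²) · exp(k·(min(T,Tsat) − Tref)) · W(u,v)

with base 800 migrants per night, phenology widths σ = 20/25 days,
temperature slope k = 0.15 °C⁻¹ saturating at 25 °C (spring) / 15 °C
(autumn) above a 15 °C reference, and wind selectivity
W = exp(g·TW) for tailwind, exp(h·TW) for headwind, × exp(−c·|CW|), with a
hard zero above 10 m s⁻¹ total wind speed.  Autumn is more selective
(g,h,c = 0.10/0.15/0.06) than spring (0.05/0.08/0.03).  All multipliers
equal 1 at the phenology peak, reference temperature and calm wind.  The
magnitudes of phenology width, temperature slope and selectivity gains are
free parameters of the generator — the source system constrains their
shapes and thresholds, not their sizes — and are fixed at these
field-plausible values.

**Echoes.**  Detected migrants per night ~ Poisson(λ · detection
efficiency), with efficiency 1.0 for vertical-looking and 0.1 for weather
radars.  Headings are wrapped-normal around the seasonal direction
(sd 10°), airspeeds normal (16.0 / 13.5 m s⁻¹, sd 2.5) truncated at zero,
altitudes a two-mode truncated-normal mixture on 0–1500 m AGL, and ground
velocity is the vector sum of air velocity and the wind interpolated to
the echo's altitude and hour.  A 5 % contaminant share adds bird-classified
targets with uniform directions and slow airspeeds (local movements), 2 %
non-bird clutter exercises the class filter, and ~1 % "twilight" echoes
just outside the night window exercise the sunset–sunrise filter.  Rain
occurs on 10 % of nights (1–4 h).  Hidden truth (heading, airspeed,
migrant flag, nightly λ) goes to sidecar files no pipeline stage reads.

Two deliberate realism mismatches: echoes experience wind at their own
altitude while the analysis uses the fixed 500 m level, and groundspeed
means include the contaminant share — together they produce the small
(~0.2 m s⁻¹, direction depending on the wind regime) airspeed biases the
recovery tests quantify.

**What the generator does not emulate:** radar beam-pattern physics and
range-dependent detectability, insect contamination gradients, topographic
wind fields, spatially correlated multi-site weather beyond exact
co-location, drift compensation or airspeed adjustment by the birds, and
observation gaps.  Passing recovery tests therefore demonstrate that the
pipeline's estimators are consistent under the stated stochastic model,
not that field data meet that model.

## 7. Numerical and engineering choices

* All timestamps UTC; one bearing↔(u,v) conversion pair used everywhere.
* CSVs are written with `%.17g` floats and read with round-trip parsing, so
  re-running a configuration reproduces byte-identical files and the
  nightly MTR equals an independent recount exactly.
* Scaled problem sizes: the shipped tests and the acceptance script use one
  or two sites and one year per season (≈60–430 nights per experiment) —
  enough for every tolerance they assert while keeping runs to minutes.
* Degenerate inputs: empty direction samples give missing Rayleigh results;
  a perfectly balanced direction sample has an undefined circular mean;
  constant responses fit to the constant with zero importances; zero-width
  bins, non-monotone height stacks, unknown seasons and polar latitudes
  raise immediately.
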