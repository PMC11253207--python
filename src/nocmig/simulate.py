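"""Synthetic radar-night generator.

Produces site-seasons of hourly pressure-level weather, nightly "true"
migration intensities, echo-level radar observations and rain logs with
known ground truth, emulating the statistical structure the analysis
pipeline assumes:

* a bell-shaped date (phenology) effect on migration intensity;
* a positive, saturating temperature effect;
* season-specific wind selectivity (tailwind gain, headwind and crosswind
  penalties, and a hard cutoff wind speed above which no migration occurs);
* migrant headings wrapped-normal around the seasonal migration direction,
  airspeeds normal (truncated at zero), and ground velocity the vector sum
  of air velocity and the wind at the echo's altitude;
* a contaminant share of non-directional bird-classified targets, a small
  non-bird clutter share, and rain events;
* radar-type detection efficiency (weather radars see ~10% of what a
  vertical-looking radar records) applied as binomial thinning of the
  Poisson counts.

Weather is keyed to the site's coordinates, not its identity, so co-located
radars of different types observe the same atmosphere.  Hidden ground-truth
fields (true heading, true airspeed, migrant flag, nightly intensity) are
written to sidecar files that no downstream pipeline stage reads.
"""

from __future__ import annotations

import datetime as dt
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    SimWorld,
    SiteConfig,
    bearing_to_uv,
    season_dates,
    uv_to_bearing,
)
from .covariates import FLIGHT_LEVEL_AGL_M, AtmosProfile, interp_to_height
from .solar import NightWindow, solar_night

__all__ = [
    "generate_weather",
    "true_intensity",
    "generate_night_echoes",
    "simulate_world",
    "simulated_dates",
    "seasonal_temperature_trend",
    "PRESSURE_LEVELS_HPA",
]

#: ERA5-like pressure levels, hPa, surface upward.
PRESSURE_LEVELS_HPA = np.array([1000, 950, 900, 850, 800, 750, 700, 650, 600, 550], float)


def _standard_height_m(p_hpa: np.ndarray) -> np.ndarray:
    """ICAO standard-atmosphere geopotential height of a pressure level."""
    return 44330.77 * (1.0 - (np.asarray(p_hpa, float) / 1013.25) ** 0.190263)


PRESSURE_LEVEL_HEIGHTS_M = _standard_height_m(PRESSURE_LEVELS_HPA)


def _location_key(site: SiteConfig) -> int:
    """Weather is a property of the place, not the instrument."""
    return zlib.crc32(f"{site.latitude:.4f}:{site.longitude:.4f}".encode()) & 0x7FFFFFFF


def _site_key(site_id: str) -> int:
    return zlib.crc32(site_id.encode()) & 0x7FFFFFFF


_SEASON_INDEX = {"spring": 1, "autumn": 2}


def simulated_dates(world: SimWorld, season: str, year: int) -> list[dt.date]:
    """Evening dates generated for a season: the full calendar season, or a
    contiguous block centred on the phenology peak when
    ``max_nights_per_season`` caps it."""
    dates = season_dates(season, year)
    cap = world.max_nights_per_season
    if cap is None or cap >= len(dates):
        return dates
    peak = world.season(season).phenology_peak_doy
    doys = np.array([d.timetuple().tm_yday for d in dates])
    centre = int(np.argmin(np.abs(doys - peak)))
    lo = max(0, min(centre - cap // 2, len(dates) - cap))
    return dates[lo : lo + cap]


def _mid_doy(season: str, year: int) -> float:
    dates = season_dates(season, year)
    return float(np.mean([d.timetuple().tm_yday for d in dates]))


def seasonal_temperature_trend(
    world: SimWorld, season: str, year: int, timestamps: pd.DatetimeIndex, lon: float
) -> np.ndarray:
    """Deterministic sea-level temperature curve: seasonal mean + linear
    drift across the season + a diurnal cycle peaking at 14:00 local mean
    solar time.  The stochastic generator adds an AR(1) anomaly on top; with
    zero anomaly variance the generated temperature equals this curve."""
    params = world.season(season)
    doy = timestamps.dayofyear.to_numpy(float)
    hour_local = (
        timestamps.hour.to_numpy(float) + timestamps.minute.to_numpy(float) / 60.0 + lon / 15.0
    ) % 24.0
    trend = params.temp_mean_c + params.temp_trend_c_per_day * (doy - _mid_doy(season, year))
    diurnal = world.temp_diurnal_amp_c * np.cos(2 * np.pi * (hour_local - 14.0) / 24.0)
    return trend + diurnal


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    x = np.empty(n)
    innov_sd = sd * np.sqrt(max(0.0, 1.0 - rho * rho))
    x[0] = rng.normal(0.0, sd) if sd > 0 else 0.0
    for i in range(1, n):
        x[i] = rho * x[i - 1] + (rng.normal(0.0, innov_sd) if sd > 0 else 0.0)
    return x


def generate_weather(
    world: SimWorld, site: SiteConfig, season: str, year: int
) -> pd.DataFrame:
    """Hourly pressure-level weather for one site-season, long format:
    (site_id, timestamp, pressure_hpa, t_c, u_ms, v_ms, rh_pct, w_pas, cc, z_m).

    Covers 00:00 UTC of the first simulated evening through 12:00 UTC the day
    after the last one, so every biological night is fully bracketed.
    """
    params = world.season(season)  # validates the season label
    dates = simulated_dates(world, season, year)
    start = pd.Timestamp(dates[0], tz="UTC")
    end = pd.Timestamp(dates[-1] + dt.timedelta(days=1), tz="UTC") + pd.Timedelta(hours=12)
    hours = pd.date_range(start, end, freq="1h")
    n_days = (dates[-1] - dates[0]).days + 2

    rng = np.random.default_rng(
        [world.rng_seed, _location_key(site), year, _SEASON_INDEX[season]]
    )
    day_idx = ((hours - start).days).to_numpy()

    t_anom = _ar1(rng, n_days, world.temp_anomaly_sd_c, world.temp_ar1)
    u_anom = _ar1(rng, n_days, world.wind_component_sd_ms, world.wind_ar1)
    v_anom = _ar1(rng, n_days, world.wind_component_sd_ms, world.wind_ar1)
    rh_anom = _ar1(rng, n_days, 15.0, 0.6)
    w_anom = _ar1(rng, n_days, 0.12, 0.5)

    t_sl = seasonal_temperature_trend(world, season, year, hours, site.longitude)
    t_sl = t_sl + t_anom[day_idx]
    u0, v0 = bearing_to_uv(params.wind_toward_deg, params.wind_mean_speed_ms)
    u_sfc = u0 + u_anom[day_idx]
    v_sfc = v0 + v_anom[day_idx]
    rh_sfc = np.clip(60.0 + rh_anom[day_idx], 5.0, 100.0)
    w_day = w_anom[day_idx]
    cc_day = np.clip((rh_sfc - 40.0) / 60.0 + rng.normal(0.0, 0.1, len(hours)), 0.0, 1.0)

    z = PRESSURE_LEVEL_HEIGHTS_M
    # mild shear: winds strengthen ~10% per km above the 500 m reference
    shear = 1.0 + 0.10 * (z - 500.0) / 1000.0
    nlev = len(z)
    nh = len(hours)

    frame = pd.DataFrame(
        {
            "site_id": np.repeat(site.site_id, nh * nlev),
            "timestamp": np.repeat(hours.values, nlev),
            "pressure_hpa": np.tile(PRESSURE_LEVELS_HPA, nh),
            "t_c": (t_sl[:, None] - world.lapse_rate_c_per_km * z[None, :] / 1000.0).ravel(),
            "u_ms": (u_sfc[:, None] * shear[None, :]).ravel(),
            "v_ms": (v_sfc[:, None] * shear[None, :]).ravel(),
            "rh_pct": np.clip(rh_sfc[:, None] - 2.0 * (z[None, :] / 1000.0), 5.0, 100.0).ravel(),
            "w_pas": np.repeat(w_day, nlev),
            "cc": np.repeat(cc_day, nlev),
            "z_m": np.tile(z, nh),
        }
    )
    frame["timestamp"] = pd.to_datetime(frame["timestamp"], utc=True)
    return frame


def true_intensity(
    world: SimWorld,
    site: SiteConfig,
    season: str,
    night_date: dt.date,
    temp_c: float,
    u_ms: float,
    v_ms: float,
) -> float:
    """Expected migrant count aloft for one night (before detection).

    intensity = base_rate x date effect x temperature multiplier x wind
    selectivity, with the date effect Gaussian around the phenology peak, the
    temperature multiplier saturating above the season's threshold, and a
    hard zero above the cutoff wind speed.  At the phenology peak, the
    reference temperature and calm wind all multipliers equal one.
    """
    p = world.season(season)
    doy = night_date.timetuple().tm_yday
    date_eff = np.exp(-0.5 * ((doy - p.phenology_peak_doy) / p.phenology_width_days) ** 2)
    temp_eff = np.exp(
        world.temp_slope_per_c
        * (min(temp_c, p.temp_saturation_c) - min(world.temp_ref_c, p.temp_saturation_c))
    )
    s = float(np.hypot(u_ms, v_ms))
    if s > p.wind_cutoff_ms:
        return 0.0
    mu, mv = bearing_to_uv(p.migration_direction_deg, 1.0)
    tw = u_ms * mu + v_ms * mv  # along-track wind component
    cw = u_ms * mv - v_ms * mu  # signed cross-track component
    wind_eff = np.exp(
        (p.tailwind_gain * tw if tw >= 0 else p.headwind_penalty * tw)
        - p.crosswind_penalty * abs(cw)
    )
    return float(p.base_rate * date_eff * temp_eff * wind_eff)


def _truncated_normal(rng, mean, sd, size, lower=0.0):
    if sd == 0:
        return np.full(size, float(mean))
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_altitudes(rng: np.random.Generator, world: SimWorld, n: int) -> np.ndarray:
    modes = world.altitude_modes_m
    weights = np.array([m[2] for m in modes], float)
    weights /= weights.sum()
    which = rng.choice(len(modes), size=n, p=weights)
    out = np.empty(n)
    for i, (mean, sd, _) in enumerate(modes):
        m = which == i
        if m.any():
            a, b = (0.0 - mean) / sd, (1500.0 - mean) / sd
            out[m] = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=m.sum(), random_state=rng)
    return out


def _wind_at(profile_by_hour: dict, ts: pd.Timestamp, z_asl: float) -> tuple[float, float]:
    hour = ts.floor("1h") if ts.minute < 30 else ts.ceil("1h")
    prof = profile_by_hour.get(hour)
    if prof is None:  # edge of the generated range
        prof = profile_by_hour[min(profile_by_hour, key=lambda h: abs(h - ts))]
    vals = interp_to_height(prof, z_asl)
    return vals["u_ms"], vals["v_ms"]


def generate_night_echoes(
    world: SimWorld,
    site: SiteConfig,
    night: NightWindow,
    profiles: list[AtmosProfile],
    season: str,
) -> tuple[pd.DataFrame, list[tuple], dict]:
    """Echoes and rain events for one site-night.

    Returns (echo table with hidden-truth columns, rain events as
    (site_id, start, end) tuples, night-truth record).  Echo counts are
    Poisson with mean ``true_intensity x detection_efficiency``; the
    contaminant share adds non-directional bird targets and the clutter
    share non-bird echoes.  A sprinkle of twilight echoes just outside the
    night window exercises the sunset-sunrise filter downstream.
    """
    if not profiles:
        raise ValueError(f"no atmospheric profiles supplied for night {night.night_id}")
    in_night = [p for p in profiles if night.sunset <= p.timestamp.to_pydatetime() <= night.sunrise]
    if not in_night:
        raise ValueError(f"no profiles inside the night window {night.night_id}")
    target = site.elevation + FLIGHT_LEVEL_AGL_M
    mean_vals = pd.DataFrame([interp_to_height(p, target) for p in in_night]).mean()
    lam = true_intensity(
        world, site, season, night.night_id,
        mean_vals["t_c"], mean_vals["u_ms"], mean_vals["v_ms"],
    )

    p = world.season(season)
    rng = np.random.default_rng(
        [world.rng_seed, _site_key(site.site_id), night.night_id.year,
         night.night_id.timetuple().tm_yday, 7]
    )
    lam_det = lam * site.detection_efficiency
    n_mig = rng.poisson(lam_det)
    c = world.contaminant_fraction
    n_con = rng.poisson(lam_det * c / (1.0 - c)) if c < 1.0 else rng.poisson(lam_det)
    if c >= 1.0:
        n_mig = 0
    n_clu = rng.poisson(lam_det * world.clutter_fraction)
    n_twi = rng.poisson(0.01 * lam_det)

    profile_by_hour = {prof.timestamp: prof for prof in profiles}
    night_sec = (night.sunrise - night.sunset).total_seconds()

    def make(n, kind):
        if n == 0:
            return pd.DataFrame()
        if kind == "twilight":
            # up to an hour before sunset or after sunrise
            off = rng.uniform(0, 3600.0, n)
            before = rng.random(n) < 0.5
            ts = [
                (night.sunset - dt.timedelta(seconds=o)) if b
                else (night.sunrise + dt.timedelta(seconds=o))
                for o, b in zip(off, before)
            ]
        else:
            ts = [night.sunset + dt.timedelta(seconds=s)
                  for s in rng.uniform(0.0, night_sec, n)]
        alt = _sample_altitudes(rng, world, n)
        if kind in ("migrant", "twilight"):
            heading = np.mod(rng.normal(p.migration_direction_deg, world.heading_sd_deg, n), 360.0)
            airspeed = _truncated_normal(rng, p.airspeed_mean, world.airspeed_sd, n)
        else:
            heading = rng.uniform(0.0, 360.0, n)
            airspeed = _truncated_normal(rng, 8.0, 3.0, n)
        ua, va = bearing_to_uv(heading, airspeed)
        uw = np.empty(n)
        vw = np.empty(n)
        for i in range(n):
            uw[i], vw[i] = _wind_at(profile_by_hour, pd.Timestamp(ts[i]), alt[i] + site.elevation)
        ug, vg = ua + uw, va + vw
        return pd.DataFrame(
            {
                "site_id": site.site_id,
                "timestamp": pd.to_datetime(ts, utc=True),
                "altitude_agl_m": alt,
                "ground_speed_ms": np.hypot(ug, vg),
                "track_direction_deg": uv_to_bearing(ug, vg),
                "pulse_mode": np.where(alt < 800.0, "short", "long"),
                "is_bird": kind != "clutter",
                "true_heading_deg": heading,
                "true_airspeed_ms": airspeed,
                "is_migrant": kind == "migrant",
            }
        )

    echoes = pd.concat(
        [make(n_mig, "migrant"), make(n_con, "contaminant"),
         make(n_clu, "clutter"), make(n_twi, "twilight")],
        ignore_index=True,
    )
    if len(echoes):
        echoes = echoes.sort_values("timestamp", kind="stable").reset_index(drop=True)

    rain: list[tuple] = []
    if rng.random() < world.rain_prob_per_night:
        length = rng.uniform(1.0, 4.0) * 3600.0
        start_off = rng.uniform(0.0, max(night_sec - length, 1.0))
        start = night.sunset + dt.timedelta(seconds=start_off)
        end = min(start + dt.timedelta(seconds=length), night.sunrise)
        rain.append((site.site_id, start, end))

    truth = {
        "site_id": site.site_id,
        "night_id": night.night_id,
        "season": season,
        "true_intensity": lam,
        "expected_detected": lam_det,
        "n_migrants": int(n_mig),
        "mean_true_airspeed_ms": float(
            echoes.loc[echoes["is_migrant"], "true_airspeed_ms"].mean()
        ) if n_mig else np.nan,
    }
    return echoes, rain, truth


PUBLIC_ECHO_COLUMNS = [
    "echo_id", "site_id", "timestamp", "altitude_agl_m", "ground_speed_ms",
    "track_direction_deg", "pulse_mode", "is_bird",
]
TRUTH_ECHO_COLUMNS = ["echo_id", "site_id", "true_heading_deg", "true_airspeed_ms", "is_migrant"]


def simulate_world(world: SimWorld, outdir: str | Path) -> dict:
    """Run the full generator and write the external CSV interfaces.

    Writes sites.csv, atmos.csv, echoes.csv, rain.csv plus the hidden-truth
    sidecars echoes_truth.csv and truth_nights.csv (read only by tests,
    never by pipeline stages).  Returns a small summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    all_echoes, all_atmos, all_rain, all_truth = [], [], [], []
    for site in world.sites:
        for season, year in world.seasons:
            weather = generate_weather(world, site, season, year)
            all_atmos.append(weather)
            profiles = _profiles_by_hour_list(weather)
            for date in simulated_dates(world, season, year):
                night = solar_night(site.latitude, site.longitude, date, site.site_id)
                prof_night = [
                    pr for pr in profiles
                    if night.sunset - dt.timedelta(hours=2)
                    <= pr.timestamp.to_pydatetime()
                    <= night.sunrise + dt.timedelta(hours=2)
                ]
                echoes, rain, truth = generate_night_echoes(world, site, night, prof_night, season)
                all_echoes.append(echoes)
                all_rain.extend(rain)
                all_truth.append(truth)

    echoes = pd.concat([e for e in all_echoes if len(e)], ignore_index=True)
    echoes.insert(0, "echo_id", np.arange(len(echoes)))

    sites = pd.DataFrame(
        [
            {
                "site_id": s.site_id, "latitude": s.latitude, "longitude": s.longitude,
                "elevation": s.elevation, "radar_type": s.radar_type,
                "detection_efficiency": s.detection_efficiency,
                "effective_transect_width_km": s.effective_transect_width_km,
            }
            for s in world.sites
        ]
    )
    atmos = pd.concat(all_atmos, ignore_index=True)
    rain = pd.DataFrame(all_rain, columns=["site_id", "start", "end"])
    truth_nights = pd.DataFrame(all_truth)

    sites.to_csv(outdir / "sites.csv", index=False, float_format="%.17g")
    atmos.to_csv(outdir / "atmos.csv", index=False, float_format="%.17g")
    echoes[PUBLIC_ECHO_COLUMNS].to_csv(outdir / "echoes.csv", index=False, float_format="%.17g")
    echoes[TRUTH_ECHO_COLUMNS].to_csv(outdir / "echoes_truth.csv", index=False, float_format="%.17g")
    rain.to_csv(outdir / "rain.csv", index=False, float_format="%.17g")
    truth_nights.to_csv(outdir / "truth_nights.csv", index=False, float_format="%.17g")
    return {
        "n_echoes": len(echoes),
        "n_nights": len(truth_nights),
        "n_rain_events": len(rain),
        "files": [
            "sites.csv", "atmos.csv", "echoes.csv", "echoes_truth.csv",
            "rain.csv", "truth_nights.csv",
        ],
    }


def _profiles_by_hour_list(weather: pd.DataFrame) -> list[AtmosProfile]:
    from .covariates import profiles_from_frame

    return profiles_from_frame(weather)
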