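"""Simulation-world configuration.

A :class:`SimWorld` holds everything the synthetic radar-night generator
needs: sites, seasons, phenology, temperature and wind selectivity,
airspeed distributions, instrument models and the master seed.  The
defaults encode the study system the package targets — autumn and spring
passerine migration through the Levant, observed by vertical-looking
(BirdScan-type) and weather radars — with magnitudes anchored to values the
underlying study prints (seasonal mean temperatures, migration directions,
seasonal airspeed means, the 10 m s⁻¹ wind-speed cutoff, the roughly 10:1
detection-efficiency contrast between radar types).

Conventions used throughout the package:

* directions are bearings in degrees clockwise from geographic north, in the
  "toward" sense (the direction a bird flies toward / the wind blows toward);
* wind vectors are stored as (u eastward, v northward) components in m s⁻¹;
* :func:`bearing_to_uv` / :func:`uv_to_bearing` are the single conversion
  used everywhere.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SiteConfig",
    "SeasonParams",
    "SimWorld",
    "bearing_to_uv",
    "uv_to_bearing",
    "load_world",
    "save_world",
    "config_hash",
]

#: Calendar months of the two migration seasons (inclusive).
SEASON_MONTHS = {"spring": (3, 5), "autumn": (8, 11)}


def bearing_to_uv(bearing_deg, speed):
    """(u east, v north) components of a vector of magnitude ``speed``
    pointing toward compass ``bearing_deg``."""
    rad = np.deg2rad(bearing_deg)
    return speed * np.sin(rad), speed * np.cos(rad)


def uv_to_bearing(u, v):
    """Toward-bearing in [0, 360) of the vector (u east, v north)."""
    return np.mod(np.degrees(np.arctan2(u, v)), 360.0)


@dataclass
class SiteConfig:
    site_id: str
    latitude: float  # decimal degrees
    longitude: float
    elevation: float  # m ASL
    radar_type: str = "vertical-looking"  # or "weather"
    detection_efficiency: float | None = None  # default by radar type
    effective_transect_width_km: float = 0.5  # per altitude bin

    def __post_init__(self) -> None:
        if self.radar_type not in ("weather", "vertical-looking"):
            raise ValueError(f"unknown radar_type {self.radar_type!r}")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if self.detection_efficiency is None:
            # weather radars high above terrain see ~10% of what a
            # vertical-looking radar records
            self.detection_efficiency = 0.1 if self.radar_type == "weather" else 1.0
        if not 0.0 < self.detection_efficiency <= 1.0:
            raise ValueError("detection_efficiency must be in (0, 1]")
        if self.effective_transect_width_km <= 0:
            raise ValueError("effective_transect_width_km must be positive")


@dataclass
class SeasonParams:
    """Season-specific migration and weather parameters."""

    migration_direction_deg: float  # toward-bearing: 0 spring, 180 autumn
    phenology_peak_doy: int  # ordinal day of peak passage
    phenology_width_days: float  # Gaussian sd of the date effect
    base_rate: float  # expected migrants per night at peak, neutral weather
    airspeed_mean: float  # m s^-1
    temp_mean_c: float  # seasonal mean temperature at flight level
    temp_trend_c_per_day: float  # linear drift across the season
    temp_saturation_c: float  # intensity response flattens above this
    tailwind_gain: float  # per m s^-1 of tailwind, log-intensity
    headwind_penalty: float  # per m s^-1 of headwind, log-intensity
    crosswind_penalty: float  # per |m s^-1| of crosswind, log-intensity
    wind_cutoff_ms: float  # hard cutoff: no migration above this wind speed
    wind_mean_speed_ms: float  # climatological mean wind speed at ~500 m
    wind_toward_deg: float  # climatological mean wind toward-bearing

    def __post_init__(self) -> None:
        if self.phenology_width_days <= 0:
            raise ValueError("phenology_width_days must be > 0")


def _default_seasons() -> dict[str, SeasonParams]:
    return {
        # Spring: northward passage peaking mid-April; winds predominantly
        # from the NNW (toward ~SSE) and stronger — mostly headwinds.
        "spring": SeasonParams(
            migration_direction_deg=0.0,
            phenology_peak_doy=105,
            phenology_width_days=20.0,
            base_rate=800.0,
            airspeed_mean=16.0,
            temp_mean_c=16.7,
            temp_trend_c_per_day=0.12,
            temp_saturation_c=25.0,
            tailwind_gain=0.05,
            headwind_penalty=0.08,
            crosswind_penalty=0.03,
            wind_cutoff_ms=10.0,
            wind_mean_speed_ms=6.0,
            wind_toward_deg=157.5,
        ),
        # Autumn: southward passage peaking early September; weaker winds
        # from the N/NW (toward ~SSE) — mostly tailwinds; birds more
        # selective.
        "autumn": SeasonParams(
            migration_direction_deg=180.0,
            phenology_peak_doy=248,
            phenology_width_days=25.0,
            base_rate=800.0,
            airspeed_mean=13.5,
            temp_mean_c=21.0,
            temp_trend_c_per_day=-0.10,
            temp_saturation_c=15.0,
            tailwind_gain=0.10,
            headwind_penalty=0.15,
            crosswind_penalty=0.06,
            wind_cutoff_ms=10.0,
            wind_mean_speed_ms=4.0,
            wind_toward_deg=157.5,
        ),
    }


@dataclass
class SimWorld:
    sites: list[SiteConfig] = field(default_factory=list)
    seasons: list[tuple[str, int]] = field(default_factory=list)  # ("spring", 2018)
    season_params: dict[str, SeasonParams] = field(default_factory=_default_seasons)

    # temperature response: multiplier exp(slope * (min(T, sat) - ref));
    # equals 1 at the reference temperature, saturates per season
    temp_slope_per_c: float = 0.15
    temp_ref_c: float = 15.0

    airspeed_sd: float = 2.5  # m s^-1
    heading_sd_deg: float = 10.0  # wrapped-normal spread of headings
    contaminant_fraction: float = 0.05  # non-directional bird-classified targets
    clutter_fraction: float = 0.02  # non-bird echoes (insects, clutter)
    rain_prob_per_night: float = 0.10

    #: Optional cap on nights generated per season (contiguous block centred
    #: on the phenology peak, so deltas still chain night over night).
    max_nights_per_season: int | None = None

    # hourly weather-generation knobs
    wind_component_sd_ms: float = 2.0  # AR(1) stationary sd per component
    wind_ar1: float = 0.7  # night-to-night anomaly persistence
    temp_anomaly_sd_c: float = 2.5
    temp_ar1: float = 0.7
    temp_diurnal_amp_c: float = 4.0
    lapse_rate_c_per_km: float = 6.5

    # altitude mixture (m AGL): two truncated normals on [0, 1500]
    altitude_modes_m: tuple = ((350.0, 180.0, 0.65), (950.0, 250.0, 0.35))

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contaminant_fraction <= 1.0:
            raise ValueError("contaminant_fraction must be in [0, 1]")
        if self.airspeed_sd < 0:
            raise ValueError("airspeed_sd must be >= 0")
        if not 0.0 <= self.rain_prob_per_night <= 1.0:
            raise ValueError("rain_prob_per_night must be in [0, 1]")

    def season(self, name: str) -> SeasonParams:
        try:
            return self.season_params[name]
        except KeyError:
            raise ValueError(
                f"unknown season {name!r}: expected one of {sorted(self.season_params)}"
            ) from None

    def site(self, site_id: str) -> SiteConfig:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)


# ---------------------------------------------------------------------------
# YAML serialisation

def _world_to_dict(world: SimWorld) -> dict:
    d = dataclasses.asdict(world)
    d["seasons"] = [list(s) for s in world.seasons]
    d["altitude_modes_m"] = [list(m) for m in world.altitude_modes_m]
    return d


def save_world(world: SimWorld, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_world_to_dict(world), sort_keys=True))


def load_world(path: str | Path) -> SimWorld:
    d = yaml.safe_load(Path(path).read_text())
    sites = [SiteConfig(**s) for s in d.pop("sites")]
    seasons = [tuple(s) for s in d.pop("seasons")]
    sp = {k: SeasonParams(**v) for k, v in d.pop("season_params").items()}
    d["altitude_modes_m"] = tuple(tuple(m) for m in d["altitude_modes_m"])
    return SimWorld(sites=sites, seasons=seasons, season_params=sp, **d)


def config_hash(world: SimWorld) -> str:
    """Stable SHA-256 of the canonicalised configuration."""
    text = yaml.safe_dump(_world_to_dict(world), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()


def season_dates(season: str, year: int):
    """All evening calendar dates of a season (site-local)."""
    import datetime as dt

    if season not in SEASON_MONTHS:
        raise ValueError(f"unknown season {season!r}: expected 'spring' or 'autumn'")
    m0, m1 = SEASON_MONTHS[season]
    start = dt.date(year, m0, 1)
    if m1 == 12:
        end = dt.date(year, 12, 31)
    else:
        end = dt.date(year, m1 + 1, 1) - dt.timedelta(days=1)
    out = []
    d = start
    while d <= end:
        out.append(d)
        d += dt.timedelta(days=1)
    return out
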