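"""Per-night atmospheric covariates at flight altitude.

Gridded pressure-level weather is interpolated linearly in geopotential
height to a reference flight level of 500 m above each radar, averaged over
the biological night, and assembled into the modelling covariate set:

1. temperature (deg C)
2. u — east-west wind component (m s^-1, positive eastward)
3. v — north-south wind component, sign-flipped in autumn so that positive
   always means wind blowing in the seasonal migration direction
4. relative humidity (%)
5. vertical velocity (Pa s^-1)
6. cloud cover (0-1)
7. overall wind speed s = sqrt(u_raw^2 + v_raw^2)
8-10. night-over-night change of temperature, u and v
11-13. latitude, longitude, elevation
14. ordinal date (day of year, Jan 1 = 1)
15. radar type (weather / vertical-looking)

The nightly wind speed is the mean of the hourly speeds (not the magnitude
of the mean wind vector); the unrotated components are also retained
(``u_raw``, ``v_raw``) because the flight-decomposition stage does its
trigonometry in the plain geographic frame.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .config import SiteConfig
from .solar import NightWindow

logger = logging.getLogger(__name__)

__all__ = [
    "AtmosProfile",
    "interp_to_height",
    "nightly_covariates",
    "build_covariate_table",
    "correlation_screen",
    "FLIGHT_LEVEL_AGL_M",
    "PREDICTOR_COLUMNS",
]

#: Reference flight level above radar elevation (m).
FLIGHT_LEVEL_AGL_M = 500.0

#: The model covariate columns, in the conventional order.
PREDICTOR_COLUMNS = [
    "temperature",
    "u",
    "v",
    "relative_humidity",
    "vertical_velocity",
    "cloud_cover",
    "wind_speed",
    "d_temperature",
    "d_u",
    "d_v",
    "latitude",
    "longitude",
    "elevation",
    "ordinal_date",
    "radar_type",
]

#: Variables carried on each pressure level of a profile.
PROFILE_VARS = ("t_c", "u_ms", "v_ms", "rh_pct", "w_pas", "cc")


@dataclass(frozen=True)
class AtmosProfile:
    """Pressure-level stack of weather variables at one site and hour."""

    site_id: str
    timestamp: pd.Timestamp
    pressure_hpa: np.ndarray  # descending (1000 -> 550)
    z_m: np.ndarray  # geopotential height, m ASL, ascending
    variables: dict  # name -> ndarray aligned with pressure_hpa

    def __post_init__(self):
        z = np.asarray(self.z_m, dtype=float)
        if len(z) >= 2 and not np.all(np.diff(z) > 0):
            raise ValueError(
                f"geopotential heights must increase strictly with decreasing "
                f"pressure (site {self.site_id}, {self.timestamp})"
            )


def profiles_from_frame(df: pd.DataFrame) -> list[AtmosProfile]:
    """Build profiles from the long-format atmospheric table
    (site_id, timestamp, pressure_hpa, t_c, u_ms, v_ms, rh_pct, w_pas, cc, z_m)."""
    out = []
    for (site, ts), g in df.groupby(["site_id", "timestamp"], sort=True):
        g = g.sort_values("pressure_hpa", ascending=False)
        out.append(
            AtmosProfile(
                site_id=site,
                timestamp=pd.Timestamp(ts),
                pressure_hpa=g["pressure_hpa"].to_numpy(float),
                z_m=g["z_m"].to_numpy(float),
                variables={v: g[v].to_numpy(float) for v in PROFILE_VARS},
            )
        )
    return out


def interp_to_height(profile: AtmosProfile, target_m_asl: float) -> dict:
    """Linear interpolation of every profile variable to ``target_m_asl``,
    in geopotential height.

    Below the lowest level the lowest level's value is used (clamped, and
    logged); likewise above the top level.
    """
    z = np.asarray(profile.z_m, dtype=float)
    if len(z) < 2:
        raise ValueError("profile needs at least 2 levels to interpolate")
    if not np.all(np.diff(z) > 0):
        raise ValueError("non-monotone geopotential heights")
    if target_m_asl < z[0]:
        logger.debug(
            "target %.0f m below lowest level %.0f m at %s %s: clamped",
            target_m_asl, z[0], profile.site_id, profile.timestamp,
        )
    return {
        name: float(np.interp(target_m_asl, z, vals))
        for name, vals in profile.variables.items()
    }


def nightly_covariates(
    profiles: list[AtmosProfile],
    window: NightWindow,
    site: SiteConfig,
    season: str,
    previous: dict | None = None,
) -> dict:
    """Night-mean covariates for one site-night.

    ``previous`` is the previous night's covariate dict (unrotated values are
    read back from it for the deltas); when it is None — a season's first
    night — the deltas are missing (NaN), never zero.
    """
    target = site.elevation + FLIGHT_LEVEL_AGL_M
    rows = [
        interp_to_height(p, target)
        for p in profiles
        if window.sunset <= p.timestamp.to_pydatetime() <= window.sunrise
    ]
    if not rows:
        raise ValueError(
            f"no hourly profiles inside night window {window.site_id} {window.night_id}"
        )
    hourly = pd.DataFrame(rows)
    mean = hourly.mean()
    u_raw = float(mean["u_ms"])
    v_raw = float(mean["v_ms"])
    # wind speed: mean of hourly speeds, from the unrotated components
    s = float(np.hypot(hourly["u_ms"], hourly["v_ms"]).mean())
    v_signed = -v_raw if season == "autumn" else v_raw

    cov = {
        "site_id": site.site_id,
        "night_id": window.night_id,
        "season": season,
        "temperature": float(mean["t_c"]),
        "u": u_raw,
        "v": v_signed,
        "relative_humidity": float(mean["rh_pct"]),
        "vertical_velocity": float(mean["w_pas"]),
        "cloud_cover": float(mean["cc"]),
        "wind_speed": s,
        "u_raw": u_raw,
        "v_raw": v_raw,
        "latitude": site.latitude,
        "longitude": site.longitude,
        "elevation": site.elevation,
        "ordinal_date": window.night_id.timetuple().tm_yday,
        "radar_type": site.radar_type,
    }
    if previous is None:
        cov["d_temperature"] = np.nan
        cov["d_u"] = np.nan
        cov["d_v"] = np.nan
    else:
        cov["d_temperature"] = cov["temperature"] - previous["temperature"]
        cov["d_u"] = cov["u"] - previous["u"]
        cov["d_v"] = cov["v"] - previous["v"]
    return cov


def build_covariate_table(
    atmos: pd.DataFrame,
    windows: list[NightWindow],
    sites: dict[str, SiteConfig],
    seasons: dict[tuple[str, dt.date], str],
) -> pd.DataFrame:
    """One row per site-night.

    ``seasons`` maps (site_id, night_id) to the season label; nights are
    processed in date order per site so deltas chain night over night (a
    season's first night gets missing deltas).
    """
    profiles_by_site: dict[str, list[AtmosProfile]] = {}
    for p in profiles_from_frame(atmos):
        profiles_by_site.setdefault(p.site_id, []).append(p)

    rows = []
    windows = sorted(windows, key=lambda w: (w.site_id, w.night_id))
    prev_by_site: dict[tuple[str, str], dict] = {}
    for w in windows:
        season = seasons[(w.site_id, w.night_id)]
        key = (w.site_id, season)
        prev = prev_by_site.get(key)
        if prev is not None and (w.night_id - prev["night_id"]).days != 1:
            prev = None  # gap: not the preceding night
        cov = nightly_covariates(
            profiles_by_site.get(w.site_id, []), w, sites[w.site_id], season, prev
        )
        prev_by_site[key] = cov
        rows.append(cov)
    return pd.DataFrame(rows)


def correlation_screen(table: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Pairwise Pearson correlations among the numeric predictors.

    Flags |r| >= threshold but drops nothing (all covariates stay in the
    model regardless).  Constant columns have undefined correlations and are
    reported as such (r = NaN, flagged 'undefined').
    """
    num = table.select_dtypes(include=[np.number])
    if len(num.dropna(how="any")) < 3:
        raise ValueError("need at least 3 complete rows for a correlation screen")
    recs = []
    for a, b in combinations(num.columns, 2):
        pair = num[[a, b]].dropna()
        if pair[a].nunique() <= 1 or pair[b].nunique() <= 1:
            recs.append({"var_a": a, "var_b": b, "r": np.nan, "flag": "undefined"})
            continue
        r = float(np.corrcoef(pair[a], pair[b])[0, 1])
        recs.append(
            {"var_a": a, "var_b": b, "r": r,
             "flag": "high" if abs(r) >= threshold else ""}
        )
    return pd.DataFrame(recs)
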