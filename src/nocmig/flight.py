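"""Wind decomposition of flight speeds.

Per site and season, the mean migration direction is the circular mean of
all that season's filtered track directions.  Per night (with at least five
bird tracks), the mean groundspeed is decomposed with the night's wind at
flight level into a tailwind component

    TW = s * cos(alpha_wind - alpha_migration)

and the airspeed estimate ``airspeed = groundspeed - TW``.  ``alpha_wind``
is ``atan2(u, v)`` of the (u east, v north) wind vector — the bearing the
wind blows TOWARD — so a wind blowing along the migration direction gives
TW = +s (a tailwind).  Some texts quote the same atan2 expression as the
direction the wind blows *from*; under that reading the identical formula
makes a perfect tailwind negative, so the toward convention is the default
here and ``strict_from_convention=True`` flips the sign for auditing
against such sources.

The decomposition is deliberately scalar (mean speed minus wind
projection), reproducing the field's standard procedure: under pure
crosswind it overestimates airspeed slightly because the mean groundspeed
contains the crosswind magnitude.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import uv_to_bearing

logger = logging.getLogger(__name__)

__all__ = [
    "WindVector",
    "circular_mean_direction",
    "tailwind_component",
    "nightly_airspeed",
    "season_flight_table",
    "MIN_TRACKS_PER_NIGHT",
]

MIN_TRACKS_PER_NIGHT = 5


@dataclass(frozen=True)
class WindVector:
    """Horizontal wind as (u eastward, v northward) components, m s^-1."""

    u: float
    v: float

    @property
    def s(self) -> float:
        return math.hypot(self.u, self.v)

    @property
    def alpha_wind(self) -> float:
        """Toward-bearing in [0, 360): atan2(u, v)."""
        return float(uv_to_bearing(self.u, self.v))

    @classmethod
    def from_speed_bearing(cls, s: float, toward_deg: float) -> "WindVector":
        rad = math.radians(toward_deg)
        return cls(u=s * math.sin(rad), v=s * math.cos(rad))


def circular_mean_direction(directions_deg) -> float:
    """Circular mean bearing in [0, 360); NaN for a perfectly balanced
    sample (zero resultant)."""
    d = np.deg2rad(np.asarray(directions_deg, float))
    if d.size == 0:
        raise ValueError("need at least one direction")
    s, c = np.sin(d).mean(), np.cos(d).mean()
    if math.hypot(s, c) < 1e-12:
        return math.nan
    return float(np.mod(math.degrees(math.atan2(s, c)), 360.0))


def tailwind_component(
    wind: WindVector, alpha_migration_deg: float, strict_from_convention: bool = False
) -> float:
    """TW = s * cos(alpha_wind - alpha_migration); positive = tailwind.

    With ``strict_from_convention`` the atan2 bearing is read as the
    direction the wind blows from, which negates the result.
    """
    alpha = wind.alpha_wind
    tw = wind.s * math.cos(math.radians(alpha - alpha_migration_deg))
    return -tw if strict_from_convention else tw


def nightly_airspeed(
    ground_speeds,
    wind: WindVector | None,
    alpha_migration_deg: float,
    min_tracks: int = MIN_TRACKS_PER_NIGHT,
) -> dict | None:
    """Nightly mean groundspeed, tailwind component and airspeed.

    Returns None when fewer than ``min_tracks`` tracks are available (the
    night is excluded).  A missing wind yields a row with missing TW and
    airspeed, logged."""
    gs = np.asarray(ground_speeds, float)
    gs = gs[np.isfinite(gs)]
    if gs.size < min_tracks:
        return None
    groundspeed = float(gs.mean())
    if wind is None or not (np.isfinite(wind.u) and np.isfinite(wind.v)):
        logger.info("night with %d tracks has no wind: TW/airspeed missing", gs.size)
        tw = airspeed = math.nan
    else:
        tw = tailwind_component(wind, alpha_migration_deg)
        airspeed = groundspeed - tw
    return {
        "n_tracks": int(gs.size),
        "groundspeed": groundspeed,
        "alpha_migration": alpha_migration_deg,
        "TW": tw,
        "airspeed": airspeed,
    }


def season_flight_table(
    echoes: pd.DataFrame,
    covariates: pd.DataFrame,
    min_tracks: int = MIN_TRACKS_PER_NIGHT,
) -> pd.DataFrame:
    """Per-night flight rows for all site-seasons.

    ``echoes`` are filtered echoes carrying a ``night_id`` and ``season``
    column; ``covariates`` supplies the night's unrotated flight-level wind
    (``u_raw``, ``v_raw``).  The seasonal migration direction per site is
    the circular mean over all that site-season's tracks and is held fixed
    for each of its nights.
    """
    wind_lookup = covariates.set_index(["site_id", "night_id"])[["u_raw", "v_raw"]]
    rows = []
    for (site, season), grp in echoes.groupby(["site_id", "season"], sort=True):
        alpha_mig = circular_mean_direction(grp["track_direction_deg"].to_numpy())
        for night_id, g in grp.groupby("night_id", sort=True):
            try:
                u, v = wind_lookup.loc[(site, night_id)]
                wind = WindVector(float(u), float(v))
            except KeyError:
                wind = None
            row = nightly_airspeed(
                g["ground_speed_ms"].to_numpy(), wind, alpha_mig, min_tracks
            )
            if row is None:
                continue
            rows.append({"site_id": site, "night_id": night_id, "season": season, **row})
    return pd.DataFrame(rows)
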