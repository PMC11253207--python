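"""Biological-night segmentation and echo filtering.

Retains, for each site-night, exactly the echoes the analysis uses:
bird-classified targets between sunset and sunrise, outside rain events,
inside the pulse-mode altitude windows — 50-800 m AGL for short pulse
(the radar cannot properly detect targets below 50 m and short-pulse
detection of small birds does not exceed 800 m), 800-1500 m AGL for long
pulse.

Interval conventions (the analysis is silent on boundaries, so they are
fixed here and documented): the night window is closed [sunset, sunrise];
altitude windows are half-open [50, 800) for short pulse and closed
[800, 1500] for long pulse; rain intervals are half-open [start, end).
"""

from __future__ import annotations

import logging

import pandas as pd

from .solar import NightWindow, solar_night  # noqa: F401  (re-exported)

logger = logging.getLogger(__name__)

__all__ = ["filter_echoes", "merge_rain_intervals", "NightWindow", "solar_night"]

SHORT_PULSE_WINDOW_M = (50.0, 800.0)  # [lo, hi)
LONG_PULSE_WINDOW_M = (800.0, 1500.0)  # [lo, hi]


def merge_rain_intervals(rain: list[tuple]) -> list[tuple]:
    """Merge overlapping or touching [start, end) rain intervals."""
    if not rain:
        return []
    ordered = sorted(rain, key=lambda r: r[0])
    merged = [list(ordered[0])]
    for start, end in ordered[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(m) for m in merged]


def filter_echoes(
    echoes: pd.DataFrame,
    night: NightWindow,
    rain: list[tuple] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Apply the night, rain, class and altitude-window filters.

    ``rain`` holds (start, end) pairs (site-filtered by the caller; any
    extra leading site_id element is tolerated and ignored).  Returns the
    retained subset (no field mutated) and a QC dict of per-filter removal
    counts.  Echoes with missing altitude are dropped and counted.
    """
    qc = {"site_id": night.site_id, "night_id": str(night.night_id), "n_in": len(echoes)}
    e = echoes

    ts = pd.to_datetime(e["timestamp"], utc=True)
    sunset = pd.Timestamp(night.sunset)
    sunrise = pd.Timestamp(night.sunrise)
    keep = (ts >= sunset) & (ts <= sunrise)  # closed [sunset, sunrise]
    qc["removed_outside_night"] = int((~keep).sum())
    e, ts = e[keep], ts[keep]

    intervals = merge_rain_intervals(
        [(r[-2], r[-1]) for r in (rain or [])]
    )
    in_rain = pd.Series(False, index=e.index)
    for start, end in intervals:
        in_rain |= (ts >= pd.Timestamp(start)) & (ts < pd.Timestamp(end))
    qc["removed_rain"] = int(in_rain.sum())
    e, ts = e[~in_rain], ts[~in_rain]

    is_bird = e["is_bird"].astype(bool)
    qc["removed_nonbird"] = int((~is_bird).sum())
    e = e[is_bird]

    alt = pd.to_numeric(e["altitude_agl_m"], errors="coerce")
    missing = alt.isna()
    if missing.any():
        logger.info(
            "%s %s: dropped %d echoes with missing altitude",
            night.site_id, night.night_id, int(missing.sum()),
        )
    qc["removed_missing_altitude"] = int(missing.sum())
    e, alt = e[~missing], alt[~missing]

    short = e["pulse_mode"] == "short"
    ok_alt = (
        short & (alt >= SHORT_PULSE_WINDOW_M[0]) & (alt < SHORT_PULSE_WINDOW_M[1])
    ) | (
        ~short & (alt >= LONG_PULSE_WINDOW_M[0]) & (alt <= LONG_PULSE_WINDOW_M[1])
    )
    qc["removed_altitude_window"] = int((~ok_alt).sum())
    e = e[ok_alt]

    qc["n_out"] = len(e)
    return e.copy(), qc
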