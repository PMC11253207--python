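"""Properties of the synthetic radar-night generator."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from nocmig.config import SimWorld, SiteConfig, bearing_to_uv, load_world, save_world
from nocmig.covariates import profiles_from_frame
from nocmig.simulate import (
    generate_night_echoes,
    generate_weather,
    seasonal_temperature_trend,
    simulated_dates,
    true_intensity,
)
from nocmig.solar import solar_night


def tiny_world(**kw):
    defaults = dict(
        sites=[SiteConfig("s1", 32.0, 35.0, 100.0)],
        seasons=[("spring", 2018)],
        max_nights_per_season=6,
        rng_seed=1,
    )
    defaults.update(kw)
    return SimWorld(**defaults)


def night_profiles(world, site, date, season="spring", year=2018):
    weather = generate_weather(world, site, season, year)
    night = solar_night(site.latitude, site.longitude, date, site.site_id)
    profs = [
        p for p in profiles_from_frame(weather)
        if night.sunset - dt.timedelta(hours=2)
        <= p.timestamp.to_pydatetime()
        <= night.sunrise + dt.timedelta(hours=2)
    ]
    return night, profs


# -- weather ---------------------------------------------------------------

def test_zero_anomaly_variance_gives_exact_seasonal_trend():
    w = tiny_world(temp_anomaly_sd_c=0.0)
    site = w.sites[0]
    weather = generate_weather(w, site, "spring", 2018)
    sfc = weather[weather.pressure_hpa == 1000.0]
    expected = seasonal_temperature_trend(
        w, "spring", 2018, pd.DatetimeIndex(sfc.timestamp), site.longitude
    ) - w.lapse_rate_c_per_km * sfc.z_m.to_numpy() / 1000.0
    np.testing.assert_allclose(sfc.t_c.to_numpy(), expected, rtol=0, atol=1e-12)


def test_same_seed_gives_identical_weather_and_echoes():
    results = []
    for _ in range(2):
        w = tiny_world()
        site = w.sites[0]
        night, profs = night_profiles(w, site, simulated_dates(w, "spring", 2018)[2])
        echoes, rain, truth = generate_night_echoes(w, site, night, profs, "spring")
        results.append((echoes, truth))
    pd.testing.assert_frame_equal(results[0][0], results[1][0])
    assert results[0][1] == results[1][1]


def test_weather_invariants_hold():
    w = tiny_world()
    weather = generate_weather(w, w.sites[0], "spring", 2018)
    assert weather.cc.between(0, 1).all()
    assert weather.rh_pct.between(0, 100).all()
    for _, g in weather.groupby("timestamp"):
        z = g.sort_values("pressure_hpa", ascending=False).z_m.to_numpy()
        assert np.all(np.diff(z) > 0)


def test_spring_windier_than_autumn_as_configured():
    # configured seasonal mean wind speeds: spring 6, autumn 4 m/s
    w = tiny_world(seasons=[("spring", 2018), ("autumn", 2018)],
                   max_nights_per_season=60)
    means = {}
    for season in ("spring", "autumn"):
        wx = generate_weather(w, w.sites[0], season, 2018)
        lvl = wx[wx.z_m.between(400, 800)]
        means[season] = np.hypot(lvl.u_ms, lvl.v_ms).mean()
    # ~60 nights of AR(1) anomalies: 3 SE of the nightly mean speed
    se = w.wind_component_sd_ms / np.sqrt(60 / 3.0)
    assert means["spring"] - means["autumn"] > (6.0 - 4.0) - 3 * se


def test_unknown_season_rejected():
    w = tiny_world()
    with pytest.raises(ValueError, match="unknown season"):
        generate_weather(w, w.sites[0], "winter", 2018)


# -- intensity model -------------------------------------------------------

class TestTrueIntensity:
    def world(self):
        return tiny_world()

    def test_neutral_conditions_give_base_rate(self):
        w = self.world()
        p = w.season("spring")
        peak = dt.date(2018, 1, 1) + dt.timedelta(days=p.phenology_peak_doy - 1)
        lam = true_intensity(w, w.sites[0], "spring", peak, w.temp_ref_c, 0.0, 0.0)
        assert lam == pytest.approx(p.base_rate)

    def test_hard_cutoff_zeroes_intensity(self):
        w = self.world()
        p = w.season("spring")
        peak = dt.date(2018, 1, 1) + dt.timedelta(days=p.phenology_peak_doy - 1)
        # 12 m/s of pure headwind against a 10 m/s cutoff
        u, v = bearing_to_uv((p.migration_direction_deg + 180) % 360, 12.0)
        assert true_intensity(w, w.sites[0], "spring", peak, w.temp_ref_c, u, v) == 0.0

    def test_monotone_in_tailwind_below_cutoff(self):
        w = self.world()
        p = w.season("spring")
        peak = dt.date(2018, 1, 1) + dt.timedelta(days=p.phenology_peak_doy - 1)
        tailwinds = np.linspace(-9.5, 9.5, 39)
        lams = []
        for tw in tailwinds:
            u, v = bearing_to_uv(
                p.migration_direction_deg if tw >= 0
                else (p.migration_direction_deg + 180) % 360,
                abs(tw),
            )
            lams.append(true_intensity(w, w.sites[0], "spring", peak, w.temp_ref_c, u, v))
        assert np.all(np.diff(lams) >= 0)


# -- echoes ----------------------------------------------------------------

def test_zero_wind_groundspeed_equals_true_airspeed():
    w = tiny_world(wind_component_sd_ms=0.0)
    w.season("spring").wind_mean_speed_ms = 0.0
    site = w.sites[0]
    night, profs = night_profiles(w, site, simulated_dates(w, "spring", 2018)[3])
    echoes, _, _ = generate_night_echoes(w, site, night, profs, "spring")
    assert len(echoes) > 10
    np.testing.assert_allclose(
        echoes.ground_speed_ms.to_numpy(), echoes.true_airspeed_ms.to_numpy(), atol=1e-9
    )


def test_no_spread_constant_wind_gives_identical_tracks():
    w = tiny_world(
        wind_component_sd_ms=0.0, heading_sd_deg=0.0, airspeed_sd=0.0,
        contaminant_fraction=0.0, clutter_fraction=0.0,
        temp_anomaly_sd_c=0.0,
    )
    site = w.sites[0]
    night, profs = night_profiles(w, site, simulated_dates(w, "spring", 2018)[3])
    echoes, _, _ = generate_night_echoes(w, site, night, profs, "spring")
    migrants = echoes[echoes.is_migrant]
    assert len(migrants) > 10
    # constant (in time) wind still varies with altitude via shear, so
    # compare echoes within one narrow altitude slice
    slice_ = migrants[migrants.altitude_agl_m.between(400, 420)]
    if len(slice_) >= 2:
        assert slice_.track_direction_deg.std() < 0.2


def test_vector_closure_ground_minus_air_is_wind():
    from nocmig.covariates import interp_to_height

    w = tiny_world()
    site = w.sites[0]
    night, profs = night_profiles(w, site, simulated_dates(w, "spring", 2018)[3])
    echoes, _, _ = generate_night_echoes(w, site, night, profs, "spring")
    by_hour = {p.timestamp: p for p in profs}
    mig = echoes[echoes.is_migrant].head(50)
    for _, e in mig.iterrows():
        ua, va = bearing_to_uv(e.true_heading_deg, e.true_airspeed_ms)
        ug, vg = bearing_to_uv(e.track_direction_deg, e.ground_speed_ms)
        ts = pd.Timestamp(e.timestamp)
        hour = ts.floor("1h") if ts.minute < 30 else ts.ceil("1h")
        wind = interp_to_height(by_hour[hour], e.altitude_agl_m + site.elevation)
        assert ug - ua == pytest.approx(wind["u_ms"], abs=1e-6)
        assert vg - va == pytest.approx(wind["v_ms"], abs=1e-6)


def test_detection_efficiency_thins_counts_linearly():
    # binomial thinning: expected echo count scales with detection efficiency
    counts = {}
    for eff in (1.0, 0.1):
        w = tiny_world(max_nights_per_season=50, rain_prob_per_night=0.0)
        site = SiteConfig("s_eff", 32.0, 35.0, 100.0,
                          detection_efficiency=eff)
        w.sites = [site]
        weather = generate_weather(w, site, "spring", 2018)
        profs = profiles_from_frame(weather)
        total = 0
        lam_total = 0.0
        for date in simulated_dates(w, "spring", 2018):
            night = solar_night(site.latitude, site.longitude, date, site.site_id)
            pn = [p for p in profs
                  if night.sunset - dt.timedelta(hours=2)
                  <= p.timestamp.to_pydatetime() <= night.sunrise + dt.timedelta(hours=2)]
            echoes, _, truth = generate_night_echoes(w, site, night, pn, "spring")
            total += truth["n_migrants"]
            lam_total += truth["expected_detected"]
        counts[eff] = (total, lam_total)
    ratio = counts[0.1][0] / counts[1.0][0]
    # Poisson SE of the ratio, both sites sharing the same weather
    se = ratio * np.sqrt(1.0 / counts[0.1][0] + 1.0 / counts[1.0][0])
    assert abs(ratio - 0.1) < 3 * se + 0.01


def test_phenology_peak_location():
    w = tiny_world(max_nights_per_season=None, rain_prob_per_night=0.0,
                   rng_seed=4)
    site = w.sites[0]
    weather = generate_weather(w, site, "spring", 2018)
    profs = profiles_from_frame(weather)
    p = w.season("spring")
    days, counts = [], []
    for date in simulated_dates(w, "spring", 2018):
        night = solar_night(site.latitude, site.longitude, date, site.site_id)
        pn = [pr for pr in profs
              if night.sunset - dt.timedelta(hours=2)
              <= pr.timestamp.to_pydatetime() <= night.sunrise + dt.timedelta(hours=2)]
        _, _, truth = generate_night_echoes(w, site, night, pn, "spring")
        days.append(date.timetuple().tm_yday)
        counts.append(truth["n_migrants"])
    days, counts = np.array(days), np.array(counts, float)
    # smooth over a week to suppress night-to-night weather variation
    kernel = np.ones(7) / 7.0
    smooth = np.convolve(counts, kernel, mode="same")
    peak_day = days[np.argmax(smooth)]
    assert abs(peak_day - p.phenology_peak_doy) <= p.phenology_width_days / 2


def test_empty_profiles_rejected():
    w = tiny_world()
    site = w.sites[0]
    night = solar_night(site.latitude, site.longitude, dt.date(2018, 4, 10), "s1")
    with pytest.raises(ValueError, match="profiles"):
        generate_night_echoes(w, site, night, [], "spring")


# -- config plumbing -------------------------------------------------------

def test_world_yaml_round_trip(tmp_path):
    w = tiny_world(seasons=[("spring", 2018), ("autumn", 2019)])
    path = tmp_path / "world.yaml"
    save_world(w, path)
    w2 = load_world(path)
    assert w2 == w


@pytest.mark.parametrize(
    "kw", [dict(contaminant_fraction=1.5), dict(airspeed_sd=-1.0),
           dict(rain_prob_per_night=2.0)]
)
def test_invalid_world_parameters_rejected(kw):
    with pytest.raises(ValueError):
        tiny_world(**kw)


def test_invalid_site_parameters_rejected():
    with pytest.raises(ValueError):
        SiteConfig("x", 95.0, 35.0, 0.0)
    with pytest.raises(ValueError):
        SiteConfig("x", 32.0, 35.0, 0.0, radar_type="sodar")
    with pytest.raises(ValueError):
        SiteConfig("x", 32.0, 35.0, 0.0, detection_efficiency=0.0)
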