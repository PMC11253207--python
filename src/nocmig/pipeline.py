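"""End-to-end pipeline: simulate -> preprocess -> mtr -> covariates ->
flight -> model -> contrasts.

Each stage reads only the CSV outputs of its upstream stages plus the run
configuration, writes its own outputs into the run directory, and reports
row counts into a run manifest.  Re-running with the same configuration and
seed reproduces byte-identical data files.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .brt import DEFAULT_HYPERPARAMS, BoostedTreesModel
from .config import SimWorld, config_hash, load_world, _world_to_dict
from .covariates import PREDICTOR_COLUMNS, build_covariate_table, correlation_screen
from .flight import season_flight_table
from .inference import lmm_season_effect, seasonal_weather_tests, speed_contrasts
from .mtr import night_mtr_profile
from .nights import filter_echoes
from .simulate import simulate_world, simulated_dates
from .solar import solar_night

logger = logging.getLogger(__name__)

__all__ = ["STAGES", "run_pipeline", "load_config", "night_windows"]

STAGES = ["simulate", "preprocess", "mtr", "covariates", "flight", "model", "contrasts"]

#: Upstream files each stage requires, and the stage that makes them.
_REQUIRES = {
    "simulate": {},
    "preprocess": {"echoes.csv": "simulate", "rain.csv": "simulate", "sites.csv": "simulate"},
    "mtr": {"filtered_echoes.csv": "preprocess", "rain.csv": "simulate", "sites.csv": "simulate"},
    "covariates": {"atmos.csv": "simulate", "sites.csv": "simulate"},
    "flight": {"filtered_echoes.csv": "preprocess", "covariates.csv": "covariates"},
    "model": {"mtr_nights.csv": "mtr", "covariates.csv": "covariates"},
    "contrasts": {"night_flight.csv": "flight", "covariates.csv": "covariates"},
}


def load_config(path: str | Path) -> tuple[SimWorld, dict]:
    """A run configuration: a ``world`` block (every simulation field plus
    the master seed) and an optional ``model`` block of boosting
    hyperparameter overrides."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "world" not in raw:
        raise ValueError("config must be a mapping with a 'world' block")
    tmp = Path(path).with_suffix(".world.tmp.yaml")
    try:
        tmp.write_text(yaml.safe_dump(raw["world"]))
        world = load_world(tmp)
    finally:
        tmp.unlink(missing_ok=True)
    model_params = dict(raw.get("model") or {})
    unknown = set(model_params) - set(DEFAULT_HYPERPARAMS)
    if unknown:
        raise ValueError(f"unknown model hyperparameters in config: {sorted(unknown)}")
    return world, model_params


def save_config(world: SimWorld, model_params: dict, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump({"world": _world_to_dict(world), "model": model_params}, sort_keys=True)
    )


def night_windows(world: SimWorld):
    """All (NightWindow, season) pairs of the configured world, plus the
    (site_id, night_id) -> season map."""
    windows, seasons = [], {}
    for site in world.sites:
        for season, year in world.seasons:
            for date in simulated_dates(world, season, year):
                w = solar_night(site.latitude, site.longitude, date, site.site_id)
                windows.append(w)
                seasons[(site.site_id, date)] = season
    return windows, seasons


def _read_csv(path: Path, **kw) -> pd.DataFrame:
    # round_trip: the default float parser loses the last ulp, which would
    # break the byte-identity and exact-recount guarantees
    df = pd.read_csv(path, float_precision="round_trip", **kw)
    for c in ("timestamp", "start", "end"):
        if c in df.columns:
            # ISO8601: sub-second digits are absent when they are exactly 0
            df[c] = pd.to_datetime(df[c], utc=True, format="ISO8601")
    if "night_id" in df.columns:
        df["night_id"] = pd.to_datetime(df["night_id"]).dt.date
    return df


def _rain_for_site(rain: pd.DataFrame, site_id: str) -> list[tuple]:
    r = rain[rain["site_id"] == site_id]
    return list(zip(r["start"], r["end"]))


# --------------------------------------------------------------------------
# stages

def _stage_simulate(world, params, outdir, counts):
    info = simulate_world(world, outdir)
    counts["rows_out"] = info["n_echoes"]
    return info["files"]


def _stage_preprocess(world, params, outdir, counts):
    echoes = _read_csv(outdir / "echoes.csv")
    rain = _read_csv(outdir / "rain.csv")
    counts["rows_in"] = len(echoes)
    windows, seasons = night_windows(world)
    kept, qc_lines = [], []
    for w in windows:
        site_e = echoes[echoes["site_id"] == w.site_id]
        pad = pd.Timedelta(hours=3)
        near = site_e[
            (site_e["timestamp"] >= pd.Timestamp(w.sunset) - pad)
            & (site_e["timestamp"] <= pd.Timestamp(w.sunrise) + pad)
        ]
        filt, qc = filter_echoes(near, w, _rain_for_site(rain, w.site_id))
        qc_lines.append(qc)
        if len(filt):
            filt = filt.copy()
            filt["night_id"] = w.night_id
            filt["season"] = seasons[(w.site_id, w.night_id)]
            kept.append(filt)
    out = (
        pd.concat(kept, ignore_index=True)
        if kept
        else pd.DataFrame(columns=list(echoes.columns) + ["night_id", "season"])
    )
    out.to_csv(outdir / "filtered_echoes.csv", index=False, float_format="%.17g")
    with open(outdir / "qc_report.jsonl", "w") as fh:
        for line in qc_lines:
            fh.write(json.dumps(line) + "\n")
    counts["rows_out"] = len(out)
    return ["filtered_echoes.csv", "qc_report.jsonl"]


def _stage_mtr(world, params, outdir, counts):
    echoes = _read_csv(outdir / "filtered_echoes.csv")
    rain = _read_csv(outdir / "rain.csv")
    counts["rows_in"] = len(echoes)
    windows, _ = night_windows(world)
    rows = []
    for w in windows:
        site = world.site(w.site_id)
        e = echoes[(echoes["site_id"] == w.site_id) & (echoes["night_id"] == w.night_id)]
        rows.append(
            night_mtr_profile(
                e, w,
                transect_width_km=site.effective_transect_width_km,
                rain=_rain_for_site(rain, w.site_id),
            )
        )
    out = pd.DataFrame(rows)
    out.to_csv(outdir / "mtr_nights.csv", index=False, float_format="%.17g")
    counts["rows_out"] = len(out)
    return ["mtr_nights.csv"]


def _stage_covariates(world, params, outdir, counts):
    atmos = _read_csv(outdir / "atmos.csv")
    counts["rows_in"] = len(atmos)
    windows, seasons = night_windows(world)
    sites = {s.site_id: s for s in world.sites}
    table = build_covariate_table(atmos, windows, sites, seasons)
    table.to_csv(outdir / "covariates.csv", index=False, float_format="%.17g")
    screen = correlation_screen(table[[c for c in PREDICTOR_COLUMNS if c != "radar_type"]])
    screen.to_csv(outdir / "correlation_screen.csv", index=False, float_format="%.17g")
    counts["rows_out"] = len(table)
    return ["covariates.csv", "correlation_screen.csv"]


def _stage_flight(world, params, outdir, counts):
    echoes = _read_csv(outdir / "filtered_echoes.csv")
    cov = _read_csv(outdir / "covariates.csv")
    counts["rows_in"] = len(echoes)
    table = season_flight_table(echoes, cov)
    table.to_csv(outdir / "night_flight.csv", index=False, float_format="%.17g")
    counts["rows_out"] = len(table)
    return ["night_flight.csv"]


def _stage_model(world, params, outdir, counts, seed):
    mtr = _read_csv(outdir / "mtr_nights.csv")
    cov = _read_csv(outdir / "covariates.csv")
    table = cov.merge(
        mtr[["site_id", "night_id", "directional_mtr", "nightly_mtr", "n_echoes"]],
        on=["site_id", "night_id"],
        how="inner",
    )
    table["log_mtr"] = np.log1p(table["directional_mtr"])
    table.to_csv(outdir / "modelling_table.csv", index=False, float_format="%.17g")
    counts["rows_in"] = len(table)

    hyper = {**DEFAULT_HYPERPARAMS, **params}
    files = ["modelling_table.csv"]
    marginals = []
    fitted_rows: dict[str, set] = {}
    for season in ("spring", "autumn"):
        sub = table[(table["season"] == season) & np.isfinite(table["log_mtr"])]
        fitted_rows[season] = set(zip(sub["site_id"], sub["night_id"]))
        if len(sub) < 2 * hyper["cv_folds"]:
            logger.warning("season %s: too few rows (%d) to fit, skipped", season, len(sub))
            continue
        model = BoostedTreesModel.from_dataframe(
            sub, response="log_mtr", covariates=PREDICTOR_COLUMNS, **hyper
        )
        res = model.fit(seed=seed)
        (outdir / f"model_{season}.json").write_text(json.dumps(res.to_dict(), indent=2))
        files.append(f"model_{season}.json")
        for covname in PREDICTOR_COLUMNS:
            if covname == "radar_type":
                continue
            m = res.marginal_response(covname, n_grid=25)
            m.insert(0, "season", season)
            marginals.append(m)
    assert not (fitted_rows.get("spring", set()) & fitted_rows.get("autumn", set())), (
        "a site-night leaked into both seasonal fits"
    )
    if marginals:
        pd.concat(marginals, ignore_index=True).to_csv(
            outdir / "marginal_responses.csv", index=False, float_format="%.17g"
        )
        files.append("marginal_responses.csv")
    counts["rows_out"] = len(table)
    return files


def _stage_contrasts(world, params, outdir, counts):
    nf = _read_csv(outdir / "night_flight.csv")
    cov = _read_csv(outdir / "covariates.csv")
    counts["rows_in"] = len(nf)
    contrasts = []
    for response in ("groundspeed", "airspeed"):
        contrasts.append(lmm_season_effect(nf, response))
    contrasts.extend(seasonal_weather_tests(cov))
    rows = pd.DataFrame([c.as_dict() for c in contrasts])
    rows.to_csv(outdir / "contrasts.csv", index=False, float_format="%.17g")

    means = nf.groupby("season")[["groundspeed", "airspeed"]].mean()
    derived = speed_contrasts(
        means.loc["spring", "groundspeed"], means.loc["autumn", "groundspeed"],
        means.loc["spring", "airspeed"], means.loc["autumn", "airspeed"],
    )
    lines = ["Seasonal contrasts", "==================", ""]
    for c in contrasts:
        sig = "significant" if c.p < c.alpha_adjusted else "not significant"
        lines.append(
            f"{c.variable}: spring {c.spring_mean:.2f} vs autumn {c.autumn_mean:.2f} "
            f"({c.test}, stat={c.statistic:.2f}, p={c.p:.3g}, "
            f"alpha_adj={c.alpha_adjusted:.4g}: {sig})"
        )
    lines.append("")
    lines.append(
        f"airspeed: {derived['airspeed_pct_of_autumn']}% lower in autumn "
        f"(difference {derived['airspeed_diff_ms']} m/s)"
    )
    lines.append(
        f"groundspeed: {derived['groundspeed_pct_of_spring']}% higher in autumn "
        f"(difference {derived['groundspeed_diff_ms']} m/s)"
    )
    (outdir / "contrasts_summary.txt").write_text("\n".join(lines) + "\n")
    counts["rows_out"] = len(rows)
    return ["contrasts.csv", "contrasts_summary.txt"]


_RUNNERS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "mtr": _stage_mtr,
    "covariates": _stage_covariates,
    "flight": _stage_flight,
    "model": _stage_model,
    "contrasts": _stage_contrasts,
}


def run_pipeline(
    config_path: str | Path,
    output_dir: str | Path,
    stages: list[str] | None = None,
    seed: int | None = None,
) -> dict:
    """Run the requested stages in dependency order and write
    ``manifest.json``.

    Missing upstream artifacts raise an error naming the stage that produces
    them; an unknown stage name or an invalid configuration raises
    ValueError before anything runs.
    """
    world, model_params = load_config(config_path)
    if seed is not None:
        world.rng_seed = seed
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    requested = list(STAGES) if stages is None else list(stages)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}; valid: {STAGES}")
    requested = [s for s in STAGES if s in requested]

    manifest = {
        "config_hash": config_hash(world),
        "master_seed": world.rng_seed,
        "software_version": __version__,
        "started_utc": dt.datetime.now(dt.timezone.utc).isoformat(),
        "stages": {},
    }
    for stage in requested:
        for fname, producer in _REQUIRES[stage].items():
            if producer in requested and STAGES.index(producer) < STAGES.index(stage):
                continue  # will be produced earlier in this very run
            if not (outdir / fname).exists():
                raise FileNotFoundError(
                    f"stage '{stage}' needs {fname}, which is produced by stage "
                    f"'{producer}'; run that stage first"
                )

    for stage in requested:
        logger.info("stage=%s status=start", stage)
        counts: dict = {"rows_in": None, "rows_out": None}
        if stage == "model":
            files = _RUNNERS[stage](world, model_params, outdir, counts, world.rng_seed)
        else:
            files = _RUNNERS[stage](world, model_params, outdir, counts)
        for f in files:
            assert (outdir / f).exists(), f"stage {stage} did not write {f}"
        manifest["stages"][stage] = {
            **counts,
            "outputs": files,
            "sha256": {f: _file_hash(outdir / f) for f in files},
        }
        logger.info(
            "stage=%s status=done rows_in=%s rows_out=%s",
            stage, counts["rows_in"], counts["rows_out"],
        )

    manifest["finished_utc"] = dt.datetime.now(dt.timezone.utc).isoformat()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
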