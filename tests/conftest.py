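import datetime as dt

import numpy as np
import pandas as pd
import pytest

from nocmig.config import SimWorld, SiteConfig
from nocmig.pipeline import run_pipeline, save_config
from nocmig.solar import solar_night


def make_world(**overrides) -> SimWorld:
    """A compact two-site, two-season world for integration tests."""
    defaults = dict(
        sites=[
            SiteConfig("hula", 33.1, 35.6, 70.0, "vertical-looking"),
            SiteConfig("negev", 30.6, 34.8, 470.0, "weather"),
        ],
        seasons=[("spring", 2018), ("autumn", 2018)],
        max_nights_per_season=30,
        rng_seed=11,
    )
    defaults.update(overrides)
    return SimWorld(**defaults)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run (all stages) on the demo configuration,
    shared across tests.  The boosting hyperparameters are scaled down so
    the run stays light; the staged-CV machinery is exercised regardless."""
    outdir = tmp_path_factory.mktemp("demo_run")
    config = outdir / "config.yaml"
    save_config(
        make_world(),
        {"learning_rate": 0.05, "max_trees": 750, "cv_folds": 5, "step_size": 25},
        config,
    )
    manifest = run_pipeline(config, outdir)
    return outdir, manifest


@pytest.fixture()
def one_night():
    """A fixed night window at a mid-latitude site."""
    return solar_night(32.0, 35.0, dt.date(2018, 4, 20), "site1")


def make_echoes(night, times_s, altitudes, directions=None, speeds=None,
                pulse=None, is_bird=True, site_id="site1"):
    """Hand-built echo table: times in seconds after sunset."""
    n = len(times_s)
    ts = [night.sunset + dt.timedelta(seconds=float(s)) for s in times_s]
    return pd.DataFrame(
        {
            "site_id": site_id,
            "timestamp": pd.to_datetime(ts, utc=True),
            "altitude_agl_m": np.asarray(altitudes, float),
            "ground_speed_ms": np.asarray(speeds if speeds is not None else np.full(n, 10.0)),
            "track_direction_deg": np.asarray(
                directions if directions is not None else np.zeros(n)
            ),
            "pulse_mode": pulse if pulse is not None
            else np.where(np.asarray(altitudes, float) < 800, "short", "long"),
            "is_bird": is_bird,
        }
    )
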