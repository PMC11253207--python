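"""Seasonal contrasts: mixed models, Welch t-tests and speed-ratio
statistics.

Seasonal differences in nightly groundspeed and airspeed are tested with a
linear mixed model (fixed season effect, random radar-location intercept,
REML).  Four meteorological variables (temperature, u, v, overall wind
speed) are compared between seasons with independent-samples Welch t-tests
at a Bonferroni-adjusted level (alpha / 4 = 0.0125 for alpha = 0.05).
Finally, the derived ratio statistics contrast the seasonal mean speeds:
the airspeed difference is expressed relative to the autumn mean and the
groundspeed difference relative to the spring mean (the references that the
conventional "X% lower in autumn" / "small difference of Y%" phrasings
imply).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = [
    "SeasonContrast",
    "lmm_season_effect",
    "seasonal_weather_tests",
    "bonferroni_alpha",
    "speed_contrasts",
    "WEATHER_TEST_VARIABLES",
]

WEATHER_TEST_VARIABLES = ("temperature", "u", "v_raw", "wind_speed")


@dataclass
class SeasonContrast:
    variable: str
    spring_mean: float
    autumn_mean: float
    absolute_difference: float  # spring - autumn
    relative_difference_pct: float
    reference: str  # which mean the percentage refers to
    test: str  # "lmm" | "t"
    statistic: float
    df: float
    p: float
    alpha_adjusted: float

    def as_dict(self) -> dict:
        return asdict(self)


def bonferroni_alpha(alpha: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted significance level alpha / m."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons


def lmm_season_effect(
    night_flight: pd.DataFrame,
    response: str,
    alpha: float = 0.05,
) -> SeasonContrast:
    """Season effect on a nightly speed, with radar location as a random
    intercept (REML).

    The reported df is the residual-style n - p (statsmodels does not
    provide a Satterthwaite approximation); with the night counts involved
    here the t and z references are indistinguishable.  With a single site
    the model degrades to an ordinary Welch comparison (logged).
    """
    df = night_flight.dropna(subset=[response, "season", "site_id"])
    spring = df.loc[df["season"] == "spring", response].to_numpy()
    autumn = df.loc[df["season"] == "autumn", response].to_numpy()
    if len(spring) == 0 or len(autumn) == 0:
        raise ValueError("both seasons must be present")

    if df["site_id"].nunique() < 2:
        logger.warning(
            "single radar location: falling back to an ordinary two-sample test"
        )
        return _welch_contrast(response, spring, autumn, alpha, alpha)

    data = df.copy()
    data["is_spring"] = (data["season"] == "spring").astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm(
            f"{response} ~ is_spring", data, groups=data["site_id"]
        ).fit(reml=True)
    est = float(fit.params["is_spring"])  # spring minus autumn
    se = float(fit.bse["is_spring"])
    dof = float(len(data) - 2)
    tstat = est / se
    p = 2.0 * stats.t.sf(abs(tstat), dof)
    autumn_mean = float(autumn.mean())
    spring_mean = float(spring.mean())
    return SeasonContrast(
        variable=response,
        spring_mean=spring_mean,
        autumn_mean=autumn_mean,
        absolute_difference=est,
        relative_difference_pct=100.0 * est / autumn_mean,
        reference="autumn_mean",
        test="lmm",
        statistic=tstat,
        df=dof,
        p=float(p),
        alpha_adjusted=alpha,
    )


def _welch_contrast(variable, spring, autumn, alpha, alpha_adjusted) -> SeasonContrast:
    res = stats.ttest_ind(spring, autumn, equal_var=False)
    diff = float(spring.mean() - autumn.mean())
    autumn_mean = float(autumn.mean())
    return SeasonContrast(
        variable=variable,
        spring_mean=float(spring.mean()),
        autumn_mean=autumn_mean,
        absolute_difference=diff,
        relative_difference_pct=(100.0 * diff / autumn_mean) if autumn_mean != 0 else np.nan,
        reference="autumn_mean",
        test="t",
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        alpha_adjusted=alpha_adjusted,
    )


def seasonal_weather_tests(
    covariate_table: pd.DataFrame,
    variables=WEATHER_TEST_VARIABLES,
    alpha: float = 0.05,
) -> list[SeasonContrast]:
    """Independent-samples Welch t-tests comparing nightly weather between
    the seasons, judged at the Bonferroni level alpha / m."""
    present = [v for v in variables if v in covariate_table.columns]
    for v in variables:
        if v not in present:
            warnings.warn(f"variable {v!r} absent from the covariate table; skipped")
    if not present:
        return []
    adj = bonferroni_alpha(alpha, len(present))
    out = []
    for v in present:
        d = covariate_table.dropna(subset=[v, "season"])
        spring = d.loc[d["season"] == "spring", v].to_numpy(float)
        autumn = d.loc[d["season"] == "autumn", v].to_numpy(float)
        if len(spring) == 0 or len(autumn) == 0:
            raise ValueError(f"both seasons must be present for {v!r}")
        out.append(_welch_contrast(v, spring, autumn, alpha, adj))
    return out


def speed_contrasts(
    spring_mean_groundspeed: float,
    autumn_mean_groundspeed: float,
    spring_mean_airspeed: float,
    autumn_mean_airspeed: float,
) -> dict:
    """Derived seasonal speed statistics.

    airspeed: spring minus autumn, expressed as a percentage of the autumn
    mean ("X% lower in autumn"); groundspeed: autumn minus spring, as a
    percentage of the spring mean.  Differences are rounded to one decimal
    and percentages to the nearest integer; the percentages are computed
    from the unrounded differences.
    """
    for name, v in {
        "spring groundspeed": spring_mean_groundspeed,
        "autumn groundspeed": autumn_mean_groundspeed,
        "spring airspeed": spring_mean_airspeed,
        "autumn airspeed": autumn_mean_airspeed,
    }.items():
        if not np.isfinite(v):
            raise ValueError(f"{name} mean is not finite")
    if autumn_mean_airspeed <= 0 or spring_mean_groundspeed <= 0:
        raise ValueError("non-positive reference mean")
    airspeed_diff = spring_mean_airspeed - autumn_mean_airspeed
    groundspeed_diff = autumn_mean_groundspeed - spring_mean_groundspeed
    return {
        "airspeed_diff_ms": round(airspeed_diff, 1),
        "airspeed_pct_of_autumn": round(100.0 * airspeed_diff / autumn_mean_airspeed),
        "groundspeed_diff_ms": round(groundspeed_diff, 1),
        "groundspeed_pct_of_spring": round(100.0 * groundspeed_diff / spring_mean_groundspeed),
    }
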