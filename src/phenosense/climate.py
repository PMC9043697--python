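"""Site temperature surfaces and temperature-trend analyses.

Monthly site temperatures are built from a station table in two steps:
a multiple linear regression of each month's temperatures on geographic
predictors (altitude, latitude, continentality, solar radiation), followed
by an inverse-distance-weighted (IDW) interpolation of the station
residuals, which makes the combined surface an exact interpolator at the
stations.

Trend analyses operate on the resulting per-site monthly series: a
random-intercept mixed model across sites for the regional trend, per-site
ordinary regressions, and a one-way Gaussian GLM of site slopes on climate
region.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .trends import TrendEstimate, fit_random_intercept_lmm

PREDICTORS = ["altitude", "latitude", "continentality", "solar_radiation"]
ELEMENTS = ["tmin", "tmean", "tmax"]
CLIMATE_REGIONS = ["alpine_subalpine", "mediterranean_mesic", "mediterranean_xeric"]

__all__ = [
    "fit_monthly_regression",
    "idw_residual_correction",
    "site_temperature_table",
    "annual_means",
    "temperature_trend_lmm",
    "per_site_trends",
    "region_slope_glm",
]


def fit_monthly_regression(stations: pd.DataFrame, month: int, element: str):
    """OLS of one month's station temperatures on the geographic predictors.

    ``stations`` holds one row per station with columns ``station_id``,
    the four predictors, ``month`` and the temperature elements.  Returns
    ``(coefs, residuals)`` where coefs is a Series (Intercept + predictors)
    and residuals a Series indexed by station_id.
    """
    sub = stations[stations["month"] == month]
    if len(sub) < len(PREDICTORS) + 2:
        raise ValueError(
            f"need at least {len(PREDICTORS) + 2} stations, got {len(sub)}"
        )
    # constant predictors are absorbed by the intercept: drop them (their
    # coefficient is reported as 0) instead of flagging them as collinear
    active = [
        p for p in PREDICTORS if sub[p].nunique() > 1
    ]
    X = sm.add_constant(sub[active].to_numpy(dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        for j, name in enumerate(active):
            Xdrop = np.delete(X, j + 1, axis=1)
            if np.linalg.matrix_rank(Xdrop) == rank:
                raise ValueError(f"rank-deficient design: predictor '{name}' is collinear")
        raise ValueError("rank-deficient design")
    y = sub[element].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    coefs = pd.Series(0.0, index=["Intercept"] + PREDICTORS)
    coefs[["Intercept"] + active] = fit.params
    residuals = pd.Series(fit.resid, index=sub["station_id"].to_numpy())
    return coefs, residuals


def idw_residual_correction(
    station_xy: np.ndarray,
    residuals: np.ndarray,
    target_xy: np.ndarray,
    power: float = 2.0,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation of station residuals.

    Weights are d^(-power); a target that coincides with a station returns
    that station's residual exactly, for any positive power.
    """
    station_xy = np.atleast_2d(np.asarray(station_xy, dtype=float))
    target_xy = np.atleast_2d(np.asarray(target_xy, dtype=float))
    residuals = np.asarray(residuals, dtype=float)
    if station_xy.shape[0] == 0:
        raise ValueError("no stations to interpolate from")
    if power <= 0:
        raise ValueError("IDW power must be positive")
    d = np.sqrt(
        ((target_xy[:, None, :] - station_xy[None, :, :]) ** 2).sum(axis=2)
    )
    out = np.empty(len(target_xy))
    for i, row in enumerate(d):
        hit = row == 0.0
        if hit.any():
            out[i] = residuals[hit][0]
            continue
        w = row ** (-power)
        out[i] = (w * residuals).sum() / w.sum()
    return out


def site_temperature_table(
    stations: pd.DataFrame,
    sites: pd.DataFrame,
    power: float = 2.0,
    elements: list[str] | None = None,
) -> pd.DataFrame:
    """Predict monthly site temperatures: regression surface + IDW residuals.

    ``stations`` carries one row per station x (year x) month with the
    geographic predictors and temperature elements; ``sites`` one row per
    site with ``site_id``, ``x``, ``y`` and the same predictors.  When the
    station table has a ``year`` column the regression is refitted per
    (year, month); otherwise a single climatology per month is used.

    Returns a long table (site_id, [year,] month, element, value).
    """
    elements = elements or [e for e in ELEMENTS if e in stations.columns]
    has_year = "year" in stations.columns
    group_cols = ["year", "month"] if has_year else ["month"]
    target_xy = sites[["x", "y"]].to_numpy(dtype=float)
    Xs = sm.add_constant(
        sites[PREDICTORS].to_numpy(dtype=float), has_constant="add"
    )
    rows = []
    for keys, sub in stations.groupby(group_cols):
        keys = keys if isinstance(keys, tuple) else (keys,)
        month = keys[-1]
        for element in elements:
            if sub[element].isna().all():
                raise ValueError(
                    f"no station data for month={month}, element={element}"
                )
            use = sub.dropna(subset=[element])
            coefs, resid = fit_monthly_regression(
                use.assign(month=month), month, element
            )
            pred = Xs @ coefs.to_numpy()
            corr = idw_residual_correction(
                use[["x", "y"]].to_numpy(dtype=float),
                resid.to_numpy(),
                target_xy,
                power=power,
            )
            for site_id, v in zip(sites["site_id"], pred + corr):
                rows.append((site_id, *keys, element, v))
    cols = ["site_id", *group_cols, "element", "value"]
    long = pd.DataFrame(rows, columns=cols)
    wide = long.pivot_table(
        index=["site_id"] + group_cols, columns="element", values="value"
    ).reset_index()
    wide.columns.name = None
    return wide


def annual_means(series: pd.DataFrame, element: str = "tmean") -> pd.DataFrame:
    """Per site x year annual mean = unweighted mean of the 12 monthly means."""
    grp = series.groupby(["site_id", "year"])
    out = grp[element].mean().rename("value").reset_index()
    n = grp["month"].nunique()
    incomplete = n[n < 12]
    if len(incomplete):
        warnings.warn(
            f"{len(incomplete)} site-years have fewer than 12 months", stacklevel=2
        )
    return out


def temperature_trend_lmm(
    series: pd.DataFrame,
    element: str = "tmean",
    scope: str | int = "annual",
    span: tuple[int, int] | None = None,
) -> TrendEstimate:
    """Regional temperature trend: value ~ year with a site random intercept.

    ``scope`` is "annual" (mean of the 12 monthly means per site-year) or a
    calendar month 1-12.  ``implied_change`` multiplies the slope by the
    study span (last minus first year by default).
    """
    if scope == "annual":
        data = annual_means(series, element)
    else:
        month = int(scope)
        data = (
            series[series["month"] == month][["site_id", "year", element]]
            .rename(columns={element: "value"})
            .dropna()
        )
        if data.empty:
            raise ValueError(f"no data for month {month}")
    fit = fit_random_intercept_lmm(
        data["value"], data["year"], data["site_id"], method="REML", x_name="year"
    )
    y0, y1 = span if span else (data["year"].min(), data["year"].max())
    slope = float(fit.params["year"])
    return TrendEstimate(
        level="region",
        response="temperature",
        unit_id=f"{element}:{scope}",
        slope=slope,
        se=float(fit.bse["year"]),
        statistic=float(fit.tvalues["year"]),
        p_value=float(fit.pvalues["year"]),
        n_obs=fit.n_obs,
        n_years=data["year"].nunique(),
        implied_change=slope * (y1 - y0),
    )


def per_site_trends(series: pd.DataFrame, element: str = "tmean") -> pd.DataFrame:
    """OLS trend of the annual mean on year, separately per site."""
    data = annual_means(series, element)
    rows = []
    for site_id, sub in data.groupby("site_id"):
        if sub["year"].nunique() < 3:
            continue
        fit = stats.linregress(sub["year"], sub["value"])
        rows.append(
            dict(
                site_id=site_id,
                slope=fit.slope,
                se=fit.stderr,
                p_value=fit.pvalue,
                n_years=sub["year"].nunique(),
            )
        )
    out = pd.DataFrame(rows)
    assert not out.isna().any().any()
    return out


def region_slope_glm(site_slopes: pd.DataFrame, sites: pd.DataFrame):
    """One-way Gaussian GLM of per-site temperature slopes on climate region.

    Returns (fit, anova_table); the F test of the region factor answers
    whether warming differs between climate regions.
    """
    data = site_slopes.merge(
        sites[["site_id", "climate_region"]], on="site_id", how="inner"
    )
    regions = data["climate_region"].unique()
    if len(regions) < 2:
        raise ValueError("need at least two climate regions")
    small = data["climate_region"].value_counts()
    if (small < 2).any():
        warnings.warn(
            f"regions with <2 sites: {list(small[small < 2].index)}", stacklevel=2
        )
    fit = smf.ols("slope ~ C(climate_region)", data=data).fit()
    if fit.df_resid < 1:
        warnings.warn("saturated region model: no residual df for an F test", stacklevel=2)
        return fit, None
    anova = sm.stats.anova_lm(fit, typ=2)
    return fit, anova
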