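"""Climate-window analysis: each species' critical period and sensitivity.

Candidate windows are all contiguous runs of one to three calendar months
within the 13-month span from September of the year preceding emergence to
September of the emergence year (36 windows by default).  For each window
the species' peak days are regressed on the window's mean temperature with
a site random intercept; the window minimising the AIC of the
maximum-likelihood fit is the species' *critical period*, and the slope of
that model (days per °C, refitted by REML) is its phenological
sensitivity.  Negative sensitivity means earlier flight in warmer years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trends import LMMFit, TrendEstimate, fit_random_intercept_lmm

__all__ = [
    "WindowSpec",
    "SensitivityResult",
    "enumerate_windows",
    "window_mean_temperature",
    "window_temperature_table",
    "fit_window_model",
    "select_critical_period",
    "critical_period_trend",
    "month_inclusion_summary",
]

# index 1..13 spans Sep of the previous year .. Sep of the focal year
SPAN_MONTHS = [9, 10, 11, 12, 1, 2, 3, 4, 5, 6, 7, 8, 9]
_ABBR = ["Jan", "Feb", "Mar", "Apr", "May", "Jun", "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]


def _index_to_calendar(idx: int) -> tuple[int, int]:
    """Span index -> (calendar month, year offset relative to the focal year)."""
    if not 1 <= idx <= 13:
        raise ValueError(f"window month index {idx} outside 1..13")
    return SPAN_MONTHS[idx - 1], (-1 if idx <= 4 else 0)


@dataclass(frozen=True)
class WindowSpec:
    """A contiguous run of months within the 13-month candidate span."""

    start_index: int  # 1..13, 1 = Sep of the previous year
    length: int  # months, 1..3

    def __post_init__(self):
        if self.start_index < 1 or self.start_index + self.length - 1 > 13:
            raise ValueError("window extends outside the 13-month span")
        if self.length < 1:
            raise ValueError("window length must be positive")

    @property
    def indices(self) -> list[int]:
        return list(range(self.start_index, self.start_index + self.length))

    @property
    def calendar_months(self) -> list[int]:
        return [_index_to_calendar(i)[0] for i in self.indices]

    @property
    def label(self) -> str:
        parts = []
        for i in self.indices:
            m, off = _index_to_calendar(i)
            parts.append(_ABBR[m - 1] + ("(-1)" if off else ""))
        return parts[0] if len(parts) == 1 else f"{parts[0]}-{parts[-1]}"


@dataclass
class SensitivityResult:
    """A species' critical period and its temperature sensitivity."""

    species_id: str
    critical_period: WindowSpec
    sensitivity: float  # days per degree C
    se: float
    p_value: float
    aic: float
    delta_aic_runner_up: float
    n_obs: int
    sign_class: str  # advance | delay | nonsignificant

    @property
    def months_included(self) -> list[int]:
        return self.critical_period.calendar_months


def enumerate_windows(span_months: int = 13, max_length: int = 3) -> list[WindowSpec]:
    """All contiguous candidate windows; sum over l of (span - l + 1) in total."""
    out = []
    for length in range(1, max_length + 1):
        for start in range(1, span_months - length + 2):
            out.append(WindowSpec(start, length))
    return out


def _monthly_lookup(series: pd.DataFrame, element: str) -> pd.Series:
    return series.set_index(["site_id", "year", "month"])[element]


def window_mean_temperature(
    series: pd.DataFrame,
    site_id,
    window: WindowSpec,
    focal_year: int,
    element: str = "tmean",
) -> float:
    """Unweighted mean of the window's monthly temperatures for one site-year.

    Span indices 1-4 (Sep-Dec) read the year before the focal year; indices
    5-13 (Jan-Sep) read the focal year itself.
    """
    lut = _monthly_lookup(series, element)
    vals = []
    for i in window.indices:
        m, off = _index_to_calendar(i)
        key = (site_id, focal_year + off, m)
        if key not in lut.index:
            raise KeyError(
                f"missing temperature for site={site_id}, year={focal_year + off}, month={m}"
            )
        vals.append(lut.loc[key])
    return float(np.mean(vals))


def window_temperature_table(
    series: pd.DataFrame,
    windows: list[WindowSpec],
    element: str = "tmean",
) -> pd.DataFrame:
    """Window mean temperatures for every site x focal year x window.

    Vectorised companion of :func:`window_mean_temperature`; focal years for
    which a window reaches into an unavailable previous year are omitted.
    Returns columns site_id, year, window label columns.
    """
    wide = series.pivot_table(index=["site_id", "year"], columns="month", values=element)
    out = {}
    for w in windows:
        acc = None
        for i in w.indices:
            m, off = _index_to_calendar(i)
            col = wide[m]
            if off:
                col = col.groupby(level="site_id").shift(1)
            acc = col if acc is None else acc + col
        out[w.label] = acc / w.length
    res = pd.DataFrame(out).reset_index()
    return res


def fit_window_model(
    phenology: pd.DataFrame,
    window_temps: pd.Series | pd.DataFrame,
    method: str = "ML",
    min_obs: int = 10,
    min_sites: int = 2,
) -> LMMFit | None:
    """peak_day ~ window temperature + (1 | site), Gaussian.

    ``phenology`` needs columns site_id, year, peak_day; ``window_temps``
    a frame with site_id, year and a single temperature column.  Returns
    None when the species has too little data or the fit fails.
    """
    if isinstance(window_temps, pd.Series):
        window_temps = window_temps.reset_index()
    tcol = [c for c in window_temps.columns if c not in ("site_id", "year")][0]
    data = phenology.merge(window_temps, on=["site_id", "year"]).dropna(
        subset=["peak_day", tcol]
    )
    if len(data) < min_obs or data["site_id"].nunique() < min_sites:
        return None
    try:
        return fit_random_intercept_lmm(
            data["peak_day"], data[tcol], data["site_id"], method=method,
            x_name="temperature",
        )
    except (ValueError, np.linalg.LinAlgError):
        return None


def select_critical_period(
    species_id: str,
    phenology: pd.DataFrame,
    temperature: pd.DataFrame,
    windows: list[WindowSpec] | None = None,
    element: str = "tmean",
    alpha: float = 0.05,
    return_aic_table: bool = False,
):
    """AIC selection of the best window for one species.

    All candidate models are fitted by ML (the fixed effects differ between
    windows, so REML AICs would not be comparable); the winning window is
    refitted by REML to report the sensitivity slope.  AIC ties break
    deterministically towards the shorter, then earlier, window.  Returns
    None when no window model can be fitted.
    """
    windows = windows or enumerate_windows()
    wtab = window_temperature_table(temperature, windows, element)
    fits: list[tuple[WindowSpec, LMMFit]] = []
    for w in windows:
        fit = fit_window_model(
            phenology, wtab[["site_id", "year", w.label]], method="ML"
        )
        if fit is not None and fit.converged:
            fits.append((w, fit))
    if not fits:
        return (None, None) if return_aic_table else None
    aic_table = pd.DataFrame(
        [
            dict(
                species_id=species_id, window=w.label,
                start_index=w.start_index, length=w.length,
                aic=f.aic, slope=float(f.params["temperature"]),
            )
            for w, f in fits
        ]
    )
    fits.sort(key=lambda t: (t[1].aic, t[0].length, t[0].start_index))
    best_w, best_fit = fits[0]
    delta = fits[1][1].aic - best_fit.aic if len(fits) > 1 else np.inf
    reml = fit_window_model(
        phenology, wtab[["site_id", "year", best_w.label]], method="REML"
    )
    slope = float(reml.params["temperature"])
    p = float(reml.pvalues["temperature"])
    if p >= alpha:
        sign_class = "nonsignificant"
    else:
        sign_class = "advance" if slope < 0 else "delay"
    result = SensitivityResult(
        species_id=species_id,
        critical_period=best_w,
        sensitivity=slope,
        se=float(reml.bse["temperature"]),
        p_value=p,
        aic=float(best_fit.aic),
        delta_aic_runner_up=float(delta),
        n_obs=best_fit.n_obs,
        sign_class=sign_class,
    )
    return (result, aic_table) if return_aic_table else result


def critical_period_trend(
    window: WindowSpec,
    temperature: pd.DataFrame,
    element: str = "tmean",
) -> TrendEstimate:
    """Yearly trend of a window's mean temperature (site random intercept).

    Flags whether a species' critical period warmed or cooled over the
    study span.
    """
    wtab = window_temperature_table(temperature, [window], element).dropna()
    fit = fit_random_intercept_lmm(
        wtab[window.label], wtab["year"], wtab["site_id"], method="REML",
        x_name="year",
    )
    slope = float(fit.params["year"])
    y0, y1 = wtab["year"].min(), wtab["year"].max()
    return TrendEstimate(
        level="region",
        response="temperature",
        unit_id=window.label,
        slope=slope,
        se=float(fit.bse["year"]),
        statistic=float(fit.tvalues["year"]),
        p_value=float(fit.pvalues["year"]),
        n_obs=fit.n_obs,
        n_years=wtab["year"].nunique(),
        implied_change=slope * (y1 - y0),
    )


def month_inclusion_summary(results: list[SensitivityResult]) -> pd.Series:
    """Fraction of species whose critical period includes each calendar month."""
    if not results:
        raise ValueError("no sensitivity results to summarise")
    frac = {}
    for m in range(1, 13):
        frac[_ABBR[m - 1]] = np.mean(
            [m in r.months_included for r in results]
        )
    return pd.Series(frac, name="fraction_of_species")
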