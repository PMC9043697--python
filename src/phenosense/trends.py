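"""Population- and species-level trend estimation.

Population trends are ordinary least-squares slopes of an annual response
(log abundance or peak day) on calendar year.  Species trends pool the
populations of a species with a Gaussian random-intercept mixed model,
``response ~ year + (1 | site)``, so that sites contribute through a shared
slope while site-level baselines are absorbed by the random intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LMMFit",
    "TrendEstimate",
    "fit_random_intercept_lmm",
    "population_trend",
    "species_trend",
    "classify_trend",
    "trend_summary",
]


@dataclass
class LMMFit:
    """A fitted Gaussian random-intercept linear mixed model.

    ``params`` etc. are indexed by fixed-effect name.  ``aic`` is
    ``2 k - 2 logLik`` for the stated fitting method, with
    ``k = n fixed effects + 2`` variance parameters (group and residual);
    for the single-group OLS fallback ``k = n fixed effects + 1``.
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    group_var: float
    resid_var: float
    llf: float
    aic: float
    method: str  # "ML", "REML" or "OLS" (single-group fallback)
    converged: bool
    n_obs: int
    n_groups: int


@dataclass
class TrendEstimate:
    """Slope of a yearly trend with its uncertainty."""

    level: str  # "population" | "species" | "site" | "region"
    response: str  # "log_abundance" | "peak_day" | "temperature"
    unit_id: str
    slope: float
    se: float
    statistic: float
    p_value: float
    n_obs: int
    n_years: int
    implied_change: float | None = None
    extra: dict = field(default_factory=dict)


def _ols_fallback(y: np.ndarray, X: np.ndarray, names: list[str]) -> LMMFit:
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(n - p, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / np.where(se > 0, se, np.nan)
    pvals = 2 * stats.t.sf(np.abs(t), dof)
    s2_ml = float(resid @ resid) / n
    llf = -0.5 * n * (np.log(2 * np.pi * max(s2_ml, 1e-300)) + 1)
    k = p + 1
    return LMMFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        tvalues=pd.Series(t, index=names),
        pvalues=pd.Series(pvals, index=names),
        group_var=0.0,
        resid_var=s2,
        llf=llf,
        aic=2 * k - 2 * llf,
        method="OLS",
        converged=True,
        n_obs=n,
        n_groups=1,
    )


def fit_random_intercept_lmm(
    y,
    x,
    groups,
    method: str = "REML",
    x_name: str = "x",
) -> LMMFit:
    """Fit ``y = b0 + b1 x + u_group + e`` with Gaussian errors.

    The variance ratio ``psi = var(u)/var(e)`` is profiled out analytically
    (block structure of a single random intercept), and the remaining
    one-dimensional likelihood is maximised numerically.  Fixed-effect
    p-values use a Wald t statistic with ``n - p`` residual degrees of
    freedom.

    With a single group the random effect is unidentifiable and the fit
    degrades to OLS with a warning.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    if y.shape != x.shape or y.shape != groups.shape:
        raise ValueError("y, x and groups must have equal length")
    mask = np.isfinite(y) & np.isfinite(x)
    y, x, groups = y[mask], x[mask], groups[mask]
    names = ["Intercept", x_name]
    X = np.column_stack([np.ones_like(x), x])

    codes, uniq = pd.factorize(groups)
    n_groups = len(uniq)
    n, p = X.shape
    if n_groups < 2:
        warnings.warn(
            "single group: random intercept unidentifiable, falling back to OLS",
            stacklevel=2,
        )
        return _ols_fallback(y, X, names)
    if n <= p:
        raise ValueError(f"need more than {p} observations, got {n}")

    order = np.argsort(codes, kind="stable")
    Xo, yo, co = X[order], y[order], codes[order]
    sizes = np.bincount(co)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])

    reml = method.upper() == "REML"

    def _profile(psi: float):
        """GLS quantities for V = I + psi * J per group (Woodbury)."""
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        ytVy = 0.0
        logdetV = 0.0
        for s, m in zip(starts, sizes):
            Xi = Xo[s : s + m]
            yi = yo[s : s + m]
            f = psi / (1.0 + m * psi)
            sx = Xi.sum(axis=0)
            sy = yi.sum()
            XtVX += Xi.T @ Xi - f * np.outer(sx, sx)
            XtVy += Xi.T @ yi - f * sx * sy
            ytVy += yi @ yi - f * sy * sy
            logdetV += np.log1p(m * psi)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - beta @ XtVy  # r' V^-1 r at the GLS solution
        rss = max(rss, 1e-300)
        return beta, rss, logdetV, XtVX

    def _negll(log_psi: float) -> float:
        psi = np.exp(log_psi)
        _, rss, logdetV, XtVX = _profile(psi)
        if reml:
            dof = n - p
            s2 = rss / dof
            sign, logdetXVX = np.linalg.slogdet(XtVX)
            ll = -0.5 * (
                dof * np.log(2 * np.pi * s2) + logdetV + logdetXVX + dof
            )
        else:
            s2 = rss / n
            ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdetV + n)
        return -ll

    # coarse grid then local refinement on log psi; include the psi -> 0 edge
    grid = np.linspace(-12.0, 8.0, 41)
    vals = [_negll(g) for g in grid]
    i0 = int(np.argmin(vals))
    lo = grid[max(i0 - 1, 0)]
    hi = grid[min(i0 + 1, len(grid) - 1)]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(_negll, bounds=(lo, hi), method="bounded")
    log_psi = float(res.x) if res.fun <= vals[i0] else grid[i0]
    psi = float(np.exp(log_psi))
    # boundary check: psi = 0 (pure OLS) may beat the interior optimum
    if _negll(-30.0) <= _negll(log_psi):
        psi = 0.0
        log_psi = -30.0

    beta, rss, logdetV, XtVX = _profile(max(psi, 1e-13))
    dof = n - p
    s2 = rss / (dof if reml else n)
    cov = s2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    t = beta / np.where(se > 0, se, np.nan)
    pvals = 2 * stats.t.sf(np.abs(t), dof)
    llf = -_negll(log_psi)
    k = p + 2
    return LMMFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        tvalues=pd.Series(t, index=names),
        pvalues=pd.Series(pvals, index=names),
        group_var=psi * s2,
        resid_var=float(s2),
        llf=float(llf),
        aic=float(2 * k - 2 * llf),
        method="REML" if reml else "ML",
        converged=bool(np.isfinite(llf)),
        n_obs=n,
        n_groups=n_groups,
    )


def population_trend(
    records: pd.DataFrame,
    response: str,
    unit_id: str = "",
    min_years: int = 3,
) -> TrendEstimate | None:
    """OLS slope of ``response`` on year for one site x species population.

    Returns None (to be logged by the caller) when fewer than ``min_years``
    usable years are available — a slope needs at least three points for a
    p-value.
    """
    rec = records.dropna(subset=[response, "year"])
    years = rec["year"].to_numpy(dtype=float)
    if len(np.unique(years)) < min_years:
        return None
    vals = rec[response].to_numpy(dtype=float)
    fit = stats.linregress(years, vals)
    return TrendEstimate(
        level="population",
        response=response,
        unit_id=unit_id,
        slope=float(fit.slope),
        se=float(fit.stderr),
        statistic=float(fit.slope / fit.stderr) if fit.stderr > 0 else np.inf,
        p_value=float(fit.pvalue),
        n_obs=len(vals),
        n_years=len(np.unique(years)),
    )


def species_trend(
    records: pd.DataFrame,
    response: str,
    unit_id: str = "",
    method: str = "REML",
) -> TrendEstimate:
    """Species-level trend: random-intercept mixed model over all populations.

    ``records`` needs columns site_id, year and ``response``; the site factor
    enters as the random intercept.  With a single population this reduces to
    the population OLS.
    """
    rec = records.dropna(subset=[response, "year"])
    fit = fit_random_intercept_lmm(
        rec[response], rec["year"], rec["site_id"], method=method, x_name="year"
    )
    return TrendEstimate(
        level="species",
        response=response,
        unit_id=unit_id,
        slope=float(fit.params["year"]),
        se=float(fit.bse["year"]),
        statistic=float(fit.tvalues["year"]),
        p_value=float(fit.pvalues["year"]),
        n_obs=fit.n_obs,
        n_years=rec["year"].nunique(),
        extra={"n_sites": fit.n_groups, "group_var": fit.group_var},
    )


def classify_trend(est: TrendEstimate, alpha: float = 0.05) -> str:
    """Three-way significance class of a trend."""
    if est.p_value < alpha:
        return "significant_negative" if est.slope < 0 else "significant_positive"
    return "nonsignificant"


def trend_summary(classes: list[str] | pd.Series) -> pd.DataFrame:
    """Counts and percentages per significance class."""
    s = pd.Series(list(classes), dtype=object)
    levels = ["significant_negative", "nonsignificant", "significant_positive"]
    counts = s.value_counts().reindex(levels, fill_value=0)
    out = pd.DataFrame(
        {"count": counts, "percent": 100.0 * counts / max(len(s), 1)}
    )
    out.index.name = "class"
    return out
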