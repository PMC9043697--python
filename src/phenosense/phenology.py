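"""Flight curves, emergence peaks and abundance indices from weekly counts.

The seasonal activity of adult butterflies is estimated per site, species
and year by a penalized B-spline Poisson regression of weekly counts on
Julian day (a P-spline GAM: cubic B-spline basis, second-order difference
penalty, log link).  The smoothing parameter is selected by maximising the
Laplace-approximate restricted marginal likelihood (LAML), the criterion
behind REML smoothing in modern GAM software.  The fitted curve is
evaluated on a daily grid; its first retained local maximum is the annual
phenological estimate (first emergence peak, Julian day).

Annual abundance is the natural log of the season's total count divided by
the number of recording events of the transect in that year.

Inclusion rules mirror standard monitoring practice: a species must be
recorded in at least five weeks of a season for a curve to be trusted;
migratory species and multivoltine species with heavily overlapping
generations are excluded by configuration; sites need at least ten
monitored years; species need at least three surviving populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.signal import find_peaks

__all__ = [
    "FlightCurve",
    "FilterDecision",
    "fit_flight_curve",
    "detect_peaks",
    "first_emergence_peak",
    "abundance_index",
    "apply_dataset_filters",
    "estimate_phenology",
]

FILTER_REASONS = (
    "too_few_weeks",
    "no_convergence",
    "no_peak",
    "migratory",
    "overlapping_broods",
    "too_few_populations",
    "site_under_10y",
)


@dataclass
class FilterDecision:
    site_id: object = None
    species_id: object = None
    year: object = None
    kept: bool = False
    reason: str = ""

    def __post_init__(self):
        if not self.kept and self.reason not in FILTER_REASONS:
            raise ValueError(f"unknown filter reason: {self.reason!r}")


@dataclass
class FlightCurve:
    """A fitted daily intensity curve for one site x species x year."""

    spline: BSpline  # acts on Julian day, returns the linear predictor
    day_min: float
    day_max: float
    converged: bool
    edf: float
    deviance_explained: float
    lambda_: float

    def grid(self, step: float = 1.0) -> np.ndarray:
        return np.arange(np.ceil(self.day_min), np.floor(self.day_max) + 1, step)

    def intensity(self, days: np.ndarray | None = None) -> np.ndarray:
        days = self.grid() if days is None else np.asarray(days, dtype=float)
        return np.exp(np.clip(self.spline(days), -30, 30))


def _bspline_design(x: np.ndarray, n_basis: int, degree: int = 3):
    lo, hi = x.min(), x.max()
    n_interior = n_basis - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    t = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    B = BSpline.design_matrix(x, t, degree).toarray()
    return B, t


def _diff_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


def fit_flight_curve(
    days,
    counts,
    n_basis: int | None = None,
    lambda_grid: np.ndarray | None = None,
    min_positive_weeks: int = 5,
) -> FlightCurve | FilterDecision:
    """Penalized Poisson spline of weekly counts on Julian day.

    Returns a :class:`FlightCurve`, or a :class:`FilterDecision` when the
    unit fails the five-positive-weeks rule or the fit does not converge.
    The smoothing parameter is chosen by LAML over ``lambda_grid``
    (log-spaced 1e-2..1e6 by default).
    """
    days = np.asarray(days, dtype=float)
    counts = np.asarray(counts, dtype=float)
    order = np.argsort(days)
    days, counts = days[order], counts[order]
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    if (counts > 0).sum() < min_positive_weeks:
        return FilterDecision(reason="too_few_weeks")

    n = len(days)
    k = n_basis or min(10, n - 1)
    k = max(k, 5)
    B, t = _bspline_design(days, k)
    S = _diff_penalty(k)
    rank_S = k - 2  # second differences annihilate constants and lines
    if lambda_grid is None:
        lambda_grid = np.logspace(-2, 6, 13)

    def _irls(lam: float):
        theta = np.zeros(k)
        mu = np.clip(counts, 0.5, None)
        eta = np.log(mu)
        # seed theta from a ridge LS fit to log counts
        theta = np.linalg.solve(B.T @ B + (lam * S) + 1e-8 * np.eye(k), B.T @ eta)
        ll_pen_prev = -np.inf
        ok = False
        for _ in range(100):
            eta = np.clip(B @ theta, -30, 30)
            mu = np.exp(eta)
            W = mu  # Poisson: var = mu, canonical link
            z = eta + (counts - mu) / mu
            H = B.T @ (B * W[:, None]) + lam * S
            try:
                theta_new = np.linalg.solve(H, B.T @ (W * z))
            except np.linalg.LinAlgError:
                return None
            step = theta_new - theta
            theta = theta_new
            eta = np.clip(B @ theta, -30, 30)
            mu = np.exp(eta)
            ll = float(counts @ eta - mu.sum())
            ll_pen = ll - 0.5 * lam * float(theta @ S @ theta)
            if not np.isfinite(ll_pen):
                return None
            if abs(ll_pen - ll_pen_prev) < 1e-9 * (abs(ll_pen) + 1):
                ok = True
                break
            ll_pen_prev = ll_pen
        if not ok and np.max(np.abs(step)) > 1e-4:
            return None
        W = np.exp(np.clip(B @ theta, -30, 30))
        H = B.T @ (B * W[:, None]) + lam * S
        sign, logdetH = np.linalg.slogdet(H)
        if sign <= 0:
            return None
        laml = ll_pen + 0.5 * rank_S * np.log(lam) - 0.5 * logdetH
        edf = float(np.trace(np.linalg.solve(H, B.T @ (B * W[:, None]))))
        return theta, laml, edf

    best = None
    for lam in lambda_grid:
        res = _irls(lam)
        if res is None:
            continue
        if best is None or res[1] > best[1]:
            best = (*res, lam)
    if best is None:
        return FilterDecision(reason="no_convergence")
    theta, _, edf, lam = best

    eta = np.clip(B @ theta, -30, 30)
    mu = np.exp(eta)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = 2 * np.sum(np.where(counts > 0, counts * np.log(counts / mu), 0.0) - (counts - mu))
    mu0 = counts.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        null_dev = 2 * np.sum(
            np.where(counts > 0, counts * np.log(counts / mu0), 0.0) - (counts - mu0)
        )
    dev_expl = 1.0 - dev / null_dev if null_dev > 0 else 0.0
    return FlightCurve(
        spline=BSpline(t, theta, 3),
        day_min=float(days.min()),
        day_max=float(days.max()),
        converged=True,
        edf=edf,
        deviance_explained=float(dev_expl),
        lambda_=float(lam),
    )


def detect_peaks(
    intensity: np.ndarray,
    grid_days: np.ndarray,
    prominence_fraction: float = 0.05,
) -> list[float]:
    """Julian days of retained local maxima of a daily intensity curve.

    A maximum is retained when its height reaches ``prominence_fraction``
    of the global maximum; boundary grid points are never peaks.
    """
    intensity = np.asarray(intensity, dtype=float)
    grid_days = np.asarray(grid_days, dtype=float)
    if intensity.size < 3:
        return []
    height = prominence_fraction * intensity.max()
    idx, _ = find_peaks(intensity, height=height)
    return [float(grid_days[i]) for i in idx]


def first_emergence_peak(peaks: list[float], peak_rule: str = "first") -> float | FilterDecision:
    """Select the annual phenological estimate from the ordered peak list.

    ``peak_rule`` is "first" (default) or "second_generation" for species
    whose first detected peak is not the biologically relevant one (e.g.
    species with a conspicuous second brood, or hibernating adults whose
    spring activity precedes emergence).
    """
    if not peaks:
        return FilterDecision(reason="no_peak")
    if peak_rule == "second_generation":
        return peaks[1] if len(peaks) > 1 else peaks[0]
    return peaks[0]


def abundance_index(total_count: float, n_recording_events: int) -> float:
    """log(total individuals / recording events), natural log."""
    if n_recording_events < 1:
        raise ValueError("need at least one recording event")
    if total_count <= 0:
        raise ValueError("abundance index undefined for zero total count")
    return float(np.log(total_count / n_recording_events))


def apply_dataset_filters(
    counts: pd.DataFrame,
    species_config: dict | None = None,
    min_site_years: int = 10,
    min_positive_weeks: int = 5,
    min_populations: int = 3,
) -> tuple[pd.DataFrame, list[FilterDecision]]:
    """Dataset-level inclusion rules applied before any curve fitting.

    In order: sites monitored for fewer than ``min_site_years`` years are
    dropped; species flagged migratory or with overlapping broods are
    dropped; species left with fewer than ``min_populations`` populations
    (site x species with at least one year passing the five-positive-weeks
    rule) are dropped.  Returns the surviving counts and the decision log.
    """
    species_config = species_config or {}
    log: list[FilterDecision] = []
    df = counts

    site_years = df.groupby("site_id")["year"].nunique()
    bad_sites = site_years[site_years < min_site_years].index
    for s in bad_sites:
        log.append(FilterDecision(site_id=s, reason="site_under_10y"))
    df = df[~df["site_id"].isin(bad_sites)]

    for sp, cfg in species_config.items():
        if cfg.get("migratory"):
            if sp in set(df["species_id"]):
                log.append(FilterDecision(species_id=sp, reason="migratory"))
            df = df[df["species_id"] != sp]
        elif cfg.get("overlapping_broods"):
            if sp in set(df["species_id"]):
                log.append(FilterDecision(species_id=sp, reason="overlapping_broods"))
            df = df[df["species_id"] != sp]

    pos = df[df["count"] > 0]
    weeks = pos.groupby(["site_id", "species_id", "year"])["julian_day"].nunique()
    usable = weeks[weeks >= min_positive_weeks].reset_index()
    n_pops = usable.groupby("species_id")["site_id"].nunique()
    all_species = df["species_id"].unique()
    for sp in all_species:
        if n_pops.get(sp, 0) < min_populations:
            log.append(FilterDecision(species_id=sp, reason="too_few_populations"))
    df = df[df["species_id"].isin(n_pops[n_pops >= min_populations].index)]

    if df.empty:
        raise ValueError("no data survive the dataset filters")
    return df, log


def _recording_events(counts: pd.DataFrame) -> pd.Series:
    """Visits per site-year: distinct sampling days, species-independent."""
    return counts.groupby(["site_id", "year"])["julian_day"].nunique()


def estimate_phenology(
    counts: pd.DataFrame,
    species_config: dict | None = None,
    prominence_fraction: float = 0.05,
    min_positive_weeks: int = 5,
    progress: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full per-unit pipeline: filters, flight curves, peaks, abundance.

    Returns ``(abundance, phenology, filter_log)`` data frames.  Abundance
    and phenology rows exist only for site-species-years that pass every
    rule and yield a converged curve with at least one peak.
    """
    species_config = species_config or {}
    kept, log = apply_dataset_filters(
        counts, species_config, min_positive_weeks=min_positive_weeks
    )
    events = _recording_events(counts)

    ab_rows, ph_rows = [], []
    groups = kept.groupby(["site_id", "species_id", "year"], sort=True)
    for (site, sp, year), sub in groups:
        curve = fit_flight_curve(
            sub["julian_day"], sub["count"], min_positive_weeks=min_positive_weeks
        )
        if isinstance(curve, FilterDecision):
            curve.site_id, curve.species_id, curve.year = site, sp, year
            log.append(curve)
            continue
        grid = curve.grid()
        peaks = detect_peaks(curve.intensity(grid), grid, prominence_fraction)
        rule = species_config.get(sp, {}).get("peak_rule", "first")
        peak = first_emergence_peak(peaks, rule)
        if isinstance(peak, FilterDecision):
            peak.site_id, peak.species_id, peak.year = site, sp, year
            log.append(peak)
            continue
        total = float(sub["count"].sum())
        n_ev = int(events.loc[(site, year)])
        ab_rows.append(
            dict(
                site_id=site,
                species_id=sp,
                year=year,
                log_abundance=abundance_index(total, n_ev),
            )
        )
        ph_rows.append(
            dict(
                site_id=site,
                species_id=sp,
                year=year,
                peak_day=peak,
                n_peaks_found=len(peaks),
                deviance_explained=curve.deviance_explained,
                edf=curve.edf,
            )
        )

    abundance = pd.DataFrame(ab_rows)
    phenology = pd.DataFrame(ph_rows)
    log_df = pd.DataFrame(
        [
            dict(
                site_id=d.site_id,
                species_id=d.species_id,
                year=d.year,
                kept=d.kept,
                reason=d.reason,
            )
            for d in log
        ]
    )
    return abundance, phenology, log_df
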