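"""Synthetic butterfly monitoring data with recorded ground truth.

The generator emulates a Mediterranean-style monitoring scheme: tens of
transect sites visited weekly from March to September over a multi-decade
span, with per-site monthly temperatures trending at month-specific rates
of mixed sign.  Each species flies in a unimodal (or bimodal, for
multivoltine species) Gaussian-shaped flight curve whose peak day responds
linearly to the mean temperature of a species-specific monthly window (the
true critical period), and whose season total follows an exponential
abundance trend.  Weekly counts are independent Poisson draws; whole
visits go missing at a configurable rate.

Defaults mirror the structure of the Catalan monitoring data that motivate
the pipeline: 59 sites, 26 years (1994-2019), ~30 weekly visits per
season, 51 species, monthly warming of roughly +0.04 °C/yr in nine months
and cooling of -0.02 °C/yr in February, March and May (an annual-mean
trend near +0.024 °C/yr, i.e. ~0.59 °C over the span), species
sensitivities between -8 and 0 days/°C with late-winter critical periods,
and log-abundance trends between -0.05 and +0.05 per year.

Every dataset carries its ground truth, so downstream estimates can be
scored against the generating parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .windows import WindowSpec, _index_to_calendar, enumerate_windows

__all__ = [
    "SpeciesTraits",
    "SpeciesTruth",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_temperatures",
    "expected_weekly_intensity",
    "simulate_counts",
    "simulate_tree",
    "simulate_species_effects",
    "simulate_dataset",
    "default_species_params",
    "write_dataset",
    "load_truth",
]

SEASON_FIRST_WEEK = 10  # ISO week of the first visit (early March)
SEASONAL_AMPLITUDE = 8.0  # deg C, sinusoidal annual cycle peaking in July
SITE_BASELINE_SD = 2.0  # deg C spread of site baselines

# default per-month trends (deg C / yr): cooling in Feb, Mar, May, warming
# elsewhere; the implied annual-mean slope is ~ +0.0236 deg C / yr.
DEFAULT_MONTHLY_TRENDS = tuple(
    -0.02 if m in (2, 3, 5) else 0.0383 for m in range(1, 13)
)


@dataclass
class SpeciesTraits:
    voltinism: str  # univoltine | multivoltine
    overwinter_stage: str  # egg | larva | pupa | adult
    larval_diet: str  # grass | forb | tree
    ssi: float  # habitat specialization index
    tao: float  # open/closed habitat preference
    hpi: float  # host plant index (raw; sqrt-normalised downstream)


@dataclass
class SpeciesTruth:
    """Generating parameters of one species (the recovery targets)."""

    species_id: str
    baseline_peak_day: float
    sensitivity_true: float  # days per deg C
    critical_window_true: WindowSpec
    abundance_trend_true: float  # d log abundance / yr
    phenology_trend_extra: float  # residual days / yr not via temperature
    voltinism: str
    second_brood_offset: float | None
    flight_sd: float
    expected_total_count: float
    traits: SpeciesTraits

    def __post_init__(self):
        if self.flight_sd <= 0:
            raise ValueError("flight_sd must be positive")
        if self.expected_total_count <= 0:
            raise ValueError("expected_total_count must be positive")


@dataclass
class SimulationConfig:
    n_sites: int = 59
    n_species: int = 51
    year_start: int = 1994
    year_end: int = 2019
    weeks_per_season: int = 30
    mean_site_temp: float = 13.0
    monthly_trend_vector: tuple = DEFAULT_MONTHLY_TRENDS
    temp_noise_sd: float = 0.5
    detection_missingness: float = 0.1
    species_params: list[SpeciesTruth] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.year_end <= self.year_start:
            raise ValueError("year_end must exceed year_start")
        if len(self.monthly_trend_vector) != 12:
            raise ValueError("monthly_trend_vector needs exactly 12 entries")
        if not 0 <= self.detection_missingness < 1:
            raise ValueError("detection_missingness must lie in [0, 1)")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def site_ids(self) -> list[str]:
        return [f"site{i + 1:03d}" for i in range(self.n_sites)]

    @property
    def sampling_days(self) -> np.ndarray:
        """Julian days of the weekly visits (mid-week of ISO weeks 10..)."""
        weeks = np.arange(SEASON_FIRST_WEEK, SEASON_FIRST_WEEK + self.weeks_per_season)
        return 7.0 * (weeks - 1) + 4.0

    @property
    def sampling_weeks(self) -> np.ndarray:
        return np.arange(SEASON_FIRST_WEEK, SEASON_FIRST_WEEK + self.weeks_per_season)


@dataclass
class SyntheticDataset:
    counts: pd.DataFrame
    temperature: pd.DataFrame
    traits: pd.DataFrame
    sites: pd.DataFrame
    tree_newick: str
    truth: list[SpeciesTruth]
    config: SimulationConfig


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    """Independent, reproducible stream per simulation stage."""
    return np.random.default_rng(np.random.SeedSequence([config_seed, stream]))


def _seasonal_cycle(month: np.ndarray) -> np.ndarray:
    return SEASONAL_AMPLITUDE * np.cos(2 * np.pi * (month - 7) / 12.0)


def _site_baselines(config: SimulationConfig) -> np.ndarray:
    rng = _rng(config.seed, 1)
    return config.mean_site_temp + SITE_BASELINE_SD * rng.normal(size=config.n_sites)


def simulate_temperatures(config: SimulationConfig) -> pd.DataFrame:
    """Monthly site temperatures: baseline + seasonal cycle + trend + noise.

    Returns columns site_id, year, month, tmin, tmean, tmax.  tmin/tmax are
    fixed offsets of the mean (the downstream analyses use tmean).
    Deterministic given the config seed.
    """
    baselines = _site_baselines(config)
    rng = _rng(config.seed, 2)
    years = config.years
    months = np.arange(1, 13)
    trend = np.asarray(config.monthly_trend_vector, dtype=float)

    # include the year before year_start so Sep-Dec windows of the first
    # focal year are covered
    all_years = np.arange(config.year_start - 1, config.year_end + 1)
    site_idx, yr_idx, mo_idx = np.meshgrid(
        np.arange(config.n_sites), all_years, months, indexing="ij"
    )
    value = (
        baselines[site_idx]
        + _seasonal_cycle(mo_idx)
        + trend[mo_idx - 1] * (yr_idx - config.year_start)
        + config.temp_noise_sd * rng.normal(size=site_idx.shape)
    )
    df = pd.DataFrame(
        {
            "site_id": np.array(config.site_ids)[site_idx.ravel()],
            "year": yr_idx.ravel(),
            "month": mo_idx.ravel(),
            "tmean": value.ravel(),
        }
    )
    df["tmin"] = df["tmean"] - 5.0
    df["tmax"] = df["tmean"] + 5.0
    return df


def _expected_window_mean(
    config: SimulationConfig, site_index: int, window: WindowSpec, focal_year: int
) -> float:
    """Noise-free window mean implied by the generator (no lookup)."""
    baselines = _site_baselines(config)
    trend = np.asarray(config.monthly_trend_vector, dtype=float)
    vals = []
    for i in window.indices:
        m, off = _index_to_calendar(i)
        vals.append(
            baselines[site_index]
            + _seasonal_cycle(np.array(m))
            + trend[m - 1] * (focal_year + off - config.year_start)
        )
    return float(np.mean(vals))


def expected_weekly_intensity(
    truth: SpeciesTruth,
    site_id: str,
    year: int,
    temperature: pd.DataFrame,
    config: SimulationConfig,
    days: np.ndarray | None = None,
) -> np.ndarray:
    """Expected counts per sampling week for one site-species-year.

    The peak day is ``baseline + sensitivity * (T_window - T_baseline) +
    extra_trend * (year - year_start)``, where T_window is the realised
    (noisy) mean temperature of the species' true critical window and
    T_baseline its noise-free value in the first study year.  The curve is
    Gaussian in day (a second brood is added for multivoltine species) and
    is normalised on the weekly sampling grid so that the season total
    equals ``expected_total_count * exp(abundance_trend * (year - year_start))``
    exactly.

    ``days`` evaluates the same continuous curve on an arbitrary grid
    (daily, for instance) without changing the normalisation.
    """
    from .windows import window_mean_temperature

    site_index = config.site_ids.index(site_id)
    try:
        t_window = window_mean_temperature(
            temperature, site_id, truth.critical_window_true, year
        )
    except KeyError as e:
        raise KeyError(
            f"climate coverage missing for {truth.species_id} window: {e}"
        ) from e
    t_base = _expected_window_mean(
        config, site_index, truth.critical_window_true, config.year_start
    )
    dy = year - config.year_start
    mu = (
        truth.baseline_peak_day
        + truth.sensitivity_true * (t_window - t_base)
        + truth.phenology_trend_extra * dy
    )
    total = truth.expected_total_count * np.exp(truth.abundance_trend_true * dy)

    sample_days = config.sampling_days

    def _shape(d):
        s = np.exp(-0.5 * ((d - mu) / truth.flight_sd) ** 2)
        if truth.voltinism == "multivoltine" and truth.second_brood_offset:
            s = 0.5 * s + 0.5 * np.exp(
                -0.5 * ((d - mu - truth.second_brood_offset) / truth.flight_sd) ** 2
            )
        return s

    norm = _shape(sample_days).sum()
    eval_days = sample_days if days is None else np.asarray(days, dtype=float)
    return total * _shape(eval_days) / norm


def simulate_counts(
    intensities: pd.DataFrame,
    missingness: float,
    seed: int,
) -> pd.DataFrame:
    """Poisson observation of expected intensities with missing visits.

    ``intensities`` has columns site_id, species_id, year, week,
    julian_day, intensity.  Visits (site x year x week) are dropped
    independently with probability ``missingness``; dropped visits are
    absent rows, not zeros.  All species share a visit.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    visits = (
        intensities[["site_id", "year", "week"]]
        .drop_duplicates()
        .sort_values(["site_id", "year", "week"])
        .reset_index(drop=True)
    )
    keep = rng.random(len(visits)) >= missingness
    kept_visits = visits[keep]
    df = intensities.merge(kept_visits, on=["site_id", "year", "week"])
    df = df.sort_values(["site_id", "species_id", "year", "week"]).reset_index(drop=True)
    df["count"] = rng.poisson(df["intensity"].to_numpy())
    return df.drop(columns=["intensity"])


def simulate_tree(n_species: int, seed: int, birth_rate: float = 1.0) -> str:
    """Pure-birth (Yule) tree with ``n_species`` tips, as a Newick string.

    Tips are labelled sp001..spNNN; all branch lengths are strictly
    positive.  Implemented directly (exponential waiting times, uniform
    lineage choice) so the draw is reproducible from a numpy seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species for a tree")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))

    next_id = [0]

    def _node():
        next_id[0] += 1
        return {"children": [], "birth": 0.0, "id": next_id[0]}

    root = _node()
    t = 0.0
    active = [root]
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        parent = active.pop(rng.integers(len(active)))
        for _ in range(2):
            child = _node()
            child["birth"] = t
            parent["children"].append(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))

    labels = [f"sp{i + 1:03d}" for i in range(n_species)]
    tips = iter(rng.permutation(n_species))

    # a node's branch runs from its own birth to the time it splits (or to
    # the present for tips); waiting times are a.s. positive, so branch
    # lengths are strictly positive
    def render(node, birth):
        if not node["children"]:
            return f"{labels[next(tips)]}:{t_end - birth:.6f}"
        split = node["children"][0]["birth"]
        inner = ",".join(render(c, split) for c in node["children"])
        return f"({inner}):{max(split - birth, 1e-9):.6f}"

    split0 = root["children"][0]["birth"]
    inner = ",".join(render(c, split0) for c in root["children"])
    return f"({inner});"


def simulate_species_effects(
    traits: pd.DataFrame,
    tree_newick: str,
    effect_sizes: dict[str, float],
    sigma2: float,
    seed: int,
) -> pd.Series:
    """Species-level trends as X beta + Brownian phylogenetic residuals.

    ``effect_sizes`` maps numeric trait columns of ``traits`` (indexed by
    species_id) to linear coefficients; residuals are multivariate normal
    with covariance sigma2 * C, C the shared-path-length matrix of the
    tree.  Closely related species therefore receive correlated trends.
    """
    from .pgls import brownian_covariance

    C, labels = brownian_covariance(tree_newick)
    traits = traits.loc[labels]
    mean = np.zeros(len(labels))
    for col, beta in effect_sizes.items():
        if col not in traits.columns:
            raise ValueError(f"trait column {col!r} absent from traits table")
        mean = mean + beta * traits[col].to_numpy(dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    if sigma2 > 0:
        L = np.linalg.cholesky(C + 1e-10 * np.eye(len(labels)))
        eps = np.sqrt(sigma2) * (L @ rng.normal(size=len(labels)))
    else:
        eps = np.zeros(len(labels))
    return pd.Series(mean + eps, index=labels, name="trend")


def default_species_params(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    sensitivity_range: tuple[float, float] = (-8.0, 0.0),
    abundance_trend_range: tuple[float, float] = (-0.05, 0.05),
    multivoltine_fraction: float = 0.3,
) -> list[SpeciesTruth]:
    """Draw a realistic community of species truths.

    Critical windows sit in late autumn to spring (the developmental
    period of most Mediterranean species); flight peaks span late April to
    mid August; totals span roughly 100-600 individuals per season.
    """
    rng = rng or _rng(config.seed, 6)
    # candidate true windows: months Nov-Apr, any length 1-3
    candidates = [
        w
        for w in enumerate_windows()
        if all(m in (11, 12, 1, 2, 3, 4) for m in w.calendar_months)
    ]
    out = []
    for i in range(config.n_species):
        multiv = rng.random() < multivoltine_fraction
        traits = SpeciesTraits(
            voltinism="multivoltine" if multiv else "univoltine",
            overwinter_stage=str(rng.choice(["egg", "larva", "pupa", "adult"])),
            larval_diet=str(rng.choice(["grass", "forb", "tree"])),
            ssi=float(rng.uniform(1.0, 8.0)),
            tao=float(rng.normal(0.0, 1.0)),
            hpi=float(rng.uniform(1.0, 30.0)),
        )
        out.append(
            SpeciesTruth(
                species_id=f"sp{i + 1:03d}",
                baseline_peak_day=float(rng.uniform(115, 225)),
                sensitivity_true=float(rng.uniform(*sensitivity_range)),
                critical_window_true=candidates[rng.integers(len(candidates))],
                abundance_trend_true=float(rng.uniform(*abundance_trend_range)),
                phenology_trend_extra=0.0,
                voltinism=traits.voltinism,
                second_brood_offset=float(rng.uniform(60, 90)) if multiv else None,
                flight_sd=float(rng.uniform(8, 16)),
                expected_total_count=float(rng.uniform(100, 600)),
                traits=traits,
            )
        )
    return out


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete synthetic monitoring dataset with ground truth."""
    if not config.species_params:
        config.species_params = default_species_params(config)
    temps = simulate_temperatures(config)
    days = config.sampling_days
    weeks = config.sampling_weeks

    rows = []
    for truth in config.species_params:
        for site_id in config.site_ids:
            for year in config.years:
                lam = expected_weekly_intensity(truth, site_id, year, temps, config)
                rows.append(
                    pd.DataFrame(
                        {
                            "site_id": site_id,
                            "species_id": truth.species_id,
                            "year": year,
                            "week": weeks,
                            "julian_day": days,
                            "intensity": lam,
                        }
                    )
                )
    intensities = pd.concat(rows, ignore_index=True)
    counts = simulate_counts(intensities, config.detection_missingness, config.seed)

    traits = pd.DataFrame(
        [
            dict(species_id=t.species_id, **asdict(t.traits))
            for t in config.species_params
        ]
    )
    if config.n_species >= 2:
        tree = simulate_tree(config.n_species, config.seed)
    else:
        tree = f"({config.species_params[0].species_id}:1.0);"
    site_rng = _rng(config.seed, 7)
    sites = pd.DataFrame(
        {
            "site_id": config.site_ids,
            "x": site_rng.uniform(0, 200_000, config.n_sites),
            "y": site_rng.uniform(0, 150_000, config.n_sites),
            "altitude": site_rng.uniform(0, 1800, config.n_sites),
            "climate_region": site_rng.choice(
                ["alpine_subalpine", "mediterranean_mesic", "mediterranean_xeric"],
                config.n_sites,
            ),
        }
    )
    return SyntheticDataset(
        counts=counts,
        temperature=temps,
        traits=traits,
        sites=sites,
        tree_newick=tree,
        truth=config.species_params,
        config=config,
    )


def _truth_record(t: SpeciesTruth) -> dict:
    d = asdict(t)
    d["critical_window_true"] = {
        "start_index": t.critical_window_true.start_index,
        "length": t.critical_window_true.length,
        "label": t.critical_window_true.label,
    }
    return d


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write counts/temperature/traits CSVs, tree Newick and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.csv",
        "temperature": out / "temperature.csv",
        "traits": out / "traits.csv",
        "sites": out / "sites.csv",
        "tree": out / "tree.nwk",
        "truth": out / "truth.json",
    }
    ds.counts.to_csv(paths["counts"], index=False)
    ds.temperature.to_csv(paths["temperature"], index=False)
    ds.traits.to_csv(paths["traits"], index=False)
    ds.sites.to_csv(paths["sites"], index=False)
    paths["tree"].write_text(ds.tree_newick + "\n")
    cfg = asdict(ds.config)
    cfg.pop("species_params", None)
    payload = {
        "config": cfg,
        "species": [_truth_record(t) for t in ds.truth],
    }
    paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths


def load_truth(path: str | Path) -> pd.DataFrame:
    """Load a truth sidecar into a species-indexed frame."""
    payload = json.loads(Path(path).read_text())
    rows = []
    for s in payload["species"]:
        w = s["critical_window_true"]
        rows.append(
            dict(
                species_id=s["species_id"],
                baseline_peak_day=s["baseline_peak_day"],
                sensitivity_true=s["sensitivity_true"],
                window_start=w["start_index"],
                window_length=w["length"],
                window_label=w["label"],
                abundance_trend_true=s["abundance_trend_true"],
                phenology_trend_extra=s["phenology_trend_extra"],
                voltinism=s["voltinism"],
                flight_sd=s["flight_sd"],
                expected_total_count=s["expected_total_count"],
            )
        )
    return pd.DataFrame(rows).set_index("species_id")
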