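"""One-shot orchestration: simulate -> flight curves -> trends ->
sensitivity -> comparative models, with a provenance manifest and a
ground-truth recovery report for synthetic runs.

Each stage reads only its predecessors' CSV outputs, so any stage can be
re-run in isolation; all randomness flows from the single root seed in the
run configuration.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate, pgls, phenology, trends, windows
from .simulate import SimulationConfig, load_truth, simulate_dataset, write_dataset

__all__ = ["RunConfig", "RecoveryReport", "run_pipeline", "recovery_report"]

ALL_STAGES = ("simulate", "climate", "flight_curves", "trends", "sensitivity", "pgls", "report")


@dataclass
class RunConfig:
    out_dir: str = "phenosense_run"
    seed: int = 0
    alpha: float = 0.05
    element: str = "tmean"
    idw_power: float = 2.0
    lambda_: float = 1.0
    prominence_fraction: float = 0.05
    stages: tuple = ALL_STAGES
    simulation: dict = field(default_factory=dict)
    species_config: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class RecoveryReport:
    """How well estimates recovered the simulation's ground truth."""

    sensitivity_correlation: float
    sensitivity_rmse: float
    window_overlap_rate: float
    abundance_trend_correlation: float
    abundance_trend_rmse: float
    abundance_ci_coverage: float
    phenology_trend_rmse: float
    n_species: int

    def as_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Writes stage CSVs plus ``manifest.json`` (file hashes, seed, config)
    into ``config.out_dir`` and returns the manifest dict.  Re-running
    with the same config reproduces identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stages = set(config.stages)

    def _need(name: str) -> Path:
        p = out / name
        if not p.exists():
            raise FileNotFoundError(f"stage input missing: {p}")
        return p

    if "simulate" in stages:
        sim_cfg = SimulationConfig(seed=config.seed, **config.simulation)
        ds = simulate_dataset(sim_cfg)
        written.update(write_dataset(ds, out))

    if "climate" in stages:
        stations_path = out / "stations.csv"
        if stations_path.exists():
            # build temperature.csv from a station table (two-step
            # interpolation: monthly regression + IDW residual correction)
            stations = pd.read_csv(stations_path)
            sites = pd.read_csv(_need("sites.csv"))
            interp = climate.site_temperature_table(
                stations, sites, power=config.idw_power
            )
            interp.to_csv(out / "temperature.csv", index=False)
            written["temperature"] = out / "temperature.csv"
        temps = pd.read_csv(_need("temperature.csv"))
        rows = []
        for scope in ["annual"] + list(range(1, 13)):
            est = climate.temperature_trend_lmm(temps, config.element, scope)
            rows.append(
                dict(scope=scope, element=config.element, slope=est.slope,
                     se=est.se, stat=est.statistic, p=est.p_value,
                     implied_change=est.implied_change)
            )
        pd.DataFrame(rows).to_csv(out / "temperature_trends.csv", index=False)
        written["temperature_trends"] = out / "temperature_trends.csv"
        site_tr = climate.per_site_trends(temps, config.element)
        site_tr.to_csv(out / "site_temperature_trends.csv", index=False)
        written["site_temperature_trends"] = out / "site_temperature_trends.csv"
        sites_path = out / "sites.csv"
        if sites_path.exists():
            sites = pd.read_csv(sites_path)
            if sites["climate_region"].nunique() >= 2:
                fit, anova = climate.region_slope_glm(site_tr, sites)
                if anova is not None:
                    anova.to_csv(out / "region_anova.csv")
                    written["region_anova"] = out / "region_anova.csv"

    if "flight_curves" in stages:
        counts = pd.read_csv(_need("counts.csv"))
        ab, ph, log = phenology.estimate_phenology(
            counts,
            config.species_config,
            prominence_fraction=config.prominence_fraction,
        )
        ab.to_csv(out / "abundance.csv", index=False)
        ph.to_csv(out / "phenology.csv", index=False)
        log.to_csv(out / "filter_log.csv", index=False)
        written.update(
            abundance=out / "abundance.csv",
            phenology=out / "phenology.csv",
            filter_log=out / "filter_log.csv",
        )

    if "trends" in stages:
        rows = []
        for resp, fname in (("log_abundance", "abundance.csv"), ("peak_day", "phenology.csv")):
            df = pd.read_csv(_need(fname))
            for (site, sp), sub in df.groupby(["site_id", "species_id"]):
                est = trends.population_trend(sub, resp, unit_id=f"{site}|{sp}")
                if est is None:
                    continue
                rows.append(_trend_row(est, config.alpha))
            for sp, sub in df.groupby("species_id"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est = trends.species_trend(sub, resp, unit_id=sp)
                rows.append(_trend_row(est, config.alpha))
        tdf = pd.DataFrame(rows)
        tdf.to_csv(out / "trends.csv", index=False)
        written["trends"] = out / "trends.csv"
        summ = []
        for (level, resp), sub in tdf.groupby(["level", "response"]):
            s = trends.trend_summary(sub["class"])
            s = s.reset_index().assign(level=level, response=resp)
            summ.append(s)
        pd.concat(summ).to_csv(out / "trend_summary.csv", index=False)
        written["trend_summary"] = out / "trend_summary.csv"

    if "sensitivity" in stages:
        ph = pd.read_csv(_need("phenology.csv"))
        temps = pd.read_csv(_need("temperature.csv"))
        results = []
        rows = []
        aic_tables = []
        for sp, sub in ph.groupby("species_id"):
            res, aics = windows.select_critical_period(
                sp, sub, temps, element=config.element, alpha=config.alpha,
                return_aic_table=True,
            )
            if res is None:
                continue
            results.append(res)
            aic_tables.append(aics)
            wtrend = windows.critical_period_trend(
                res.critical_period, temps, config.element
            )
            rows.append(
                dict(
                    species_id=sp,
                    window=res.critical_period.label,
                    window_start=res.critical_period.start_index,
                    window_length=res.critical_period.length,
                    sensitivity=res.sensitivity,
                    se=res.se,
                    p=res.p_value,
                    aic=res.aic,
                    delta_aic=res.delta_aic_runner_up,
                    n_obs=res.n_obs,
                    sign_class=res.sign_class,
                    window_trend_slope=wtrend.slope,
                    window_trend_p=wtrend.p_value,
                )
            )
        pd.DataFrame(rows).to_csv(out / "sensitivity.csv", index=False)
        written["sensitivity"] = out / "sensitivity.csv"
        if aic_tables:
            pd.concat(aic_tables).to_csv(out / "window_aic.csv", index=False)
            written["window_aic"] = out / "window_aic.csv"
        if results:
            windows.month_inclusion_summary(results).to_csv(
                out / "month_inclusion.csv", header=True
            )
            written["month_inclusion"] = out / "month_inclusion.csv"

    if "pgls" in stages:
        table = _assemble_comparative(out)
        tree = _need("tree.nwk").read_text().strip()
        tmods = pgls.trait_models(table, tree, alpha=config.alpha, lambda_=config.lambda_)
        sig = [
            t for t, f in tmods["abundance_trend"].items()
            if t != "combined" and (f.pvalues.drop("Intercept") < config.alpha).any()
        ]
        try:
            pmods = pgls.phenology_abundance_models(
                table, tree, significant_traits=sig,
                alpha=config.alpha, lambda_=config.lambda_,
            )
        except ValueError as e:
            warnings.warn(f"phenology-abundance models skipped: {e}")
            pmods = {}
        rows = []
        for resp, fits in tmods.items():
            for name, f in fits.items():
                rows.extend(_pgls_rows(f"trait:{name}", f))
        for name, f in pmods.items():
            rows.extend(_pgls_rows(name, f))
        pd.DataFrame(rows).to_csv(out / "pgls_models.csv", index=False)
        written["pgls_models"] = out / "pgls_models.csv"
        single = {t: f for t, f in tmods["abundance_trend"].items() if t != "combined"}
        pgls.compare_models(single).to_csv(out / "pgls_ranking.csv", index=False)
        written["pgls_ranking"] = out / "pgls_ranking.csv"

    if "report" in stages:
        truth_path = out / "truth.json"
        if truth_path.exists():
            rep = recovery_report(out, truth_path)
            (out / "recovery_report.json").write_text(
                json.dumps(rep.as_dict(), indent=1)
            )
            written["recovery_report"] = out / "recovery_report.json"
        else:
            raise FileNotFoundError(
                "recovery report needs a truth sidecar (synthetic runs only)"
            )

    manifest = {
        "seed": config.seed,
        "stages": sorted(stages),
        "config_hash": hashlib.sha256(
            json.dumps(config.__dict__, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "files": {k: _sha256(p) for k, p in sorted(written.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _trend_row(est: trends.TrendEstimate, alpha: float) -> dict:
    return dict(
        level=est.level,
        unit=est.unit_id,
        response=est.response,
        slope=est.slope,
        se=est.se,
        stat=est.statistic,
        p=est.p_value,
        n_obs=est.n_obs,
        n_years=est.n_years,
        **{"class": trends.classify_trend(est, alpha)},
    )


def _pgls_rows(model: str, f: pgls.PGLSFit) -> list[dict]:
    return [
        dict(
            model=model,
            response=f.response,
            term=term,
            coef=f.params[term],
            se=f.bse[term],
            t=f.tvalues[term],
            p=f.pvalues[term],
            aicc=f.aicc,
            n=f.n,
            n_excluded=len(f.excluded),
        )
        for term in f.params.index
    ]


def _assemble_comparative(out: Path) -> pd.DataFrame:
    tdf = pd.read_csv(out / "trends.csv")
    sp_tr = tdf[tdf["level"] == "species"]
    ab = sp_tr[sp_tr["response"] == "log_abundance"].set_index("unit")["slope"]
    ph = sp_tr[sp_tr["response"] == "peak_day"].set_index("unit")["slope"]
    sens = pd.read_csv(out / "sensitivity.csv").set_index("species_id")["sensitivity"]
    traits = pd.read_csv(out / "traits.csv")
    return pgls.build_comparative_table(ab, ph, sens, traits)


def recovery_report(out_dir: str | Path, truth_path: str | Path) -> RecoveryReport:
    """Score pipeline estimates against the simulation's truth sidecar.

    Window overlap counts a species as recovered when the selected critical
    period shares at least one (calendar month, year offset) cell with the
    true window.  CI coverage is the fraction of species whose true
    abundance trend lies within slope +/- 1.96 SE.
    """
    out = Path(out_dir)
    truth = load_truth(truth_path)
    sens = pd.read_csv(out / "sensitivity.csv").set_index("species_id")
    tdf = pd.read_csv(out / "trends.csv")
    sp = tdf[(tdf["level"] == "species")].set_index("unit")
    ab = sp[sp["response"] == "log_abundance"]
    ph = sp[sp["response"] == "peak_day"]

    # both frames carry window_start/window_length columns (truth vs estimate)
    j = truth.join(sens, how="inner", lsuffix="_t", rsuffix="_e")
    if j.empty:
        raise ValueError("no species overlap between estimates and truth")
    sens_corr = float(np.corrcoef(j["sensitivity_true"], j["sensitivity"])[0, 1])
    sens_rmse = float(np.sqrt(np.mean((j["sensitivity_true"] - j["sensitivity"]) ** 2)))
    overlap = []
    for spid in j.index:
        e0 = int(sens.loc[spid, "window_start"])
        el = int(sens.loc[spid, "window_length"])
        t0 = int(truth.loc[spid, "window_start"])
        tl = int(truth.loc[spid, "window_length"])
        overlap.append(bool(set(range(e0, e0 + el)) & set(range(t0, t0 + tl))))
    overlap_rate = float(np.mean(overlap))

    ja = truth.join(ab, how="inner")
    ab_corr = float(np.corrcoef(ja["abundance_trend_true"], ja["slope"])[0, 1])
    ab_rmse = float(np.sqrt(np.mean((ja["abundance_trend_true"] - ja["slope"]) ** 2)))
    cover = np.mean(
        (ja["abundance_trend_true"] >= ja["slope"] - 1.96 * ja["se"])
        & (ja["abundance_trend_true"] <= ja["slope"] + 1.96 * ja["se"])
    )
    jp = truth.join(ph, how="inner")
    # the expected phenology trend is sensitivity x the true window's
    # temperature trend plus any extra drift; report raw RMSE against the
    # temperature-mediated prediction
    ph_rmse = float(
        np.sqrt(np.mean((jp["slope"] - jp["phenology_trend_extra"]) ** 2))
    ) if len(jp) else float("nan")
    return RecoveryReport(
        sensitivity_correlation=sens_corr,
        sensitivity_rmse=sens_rmse,
        window_overlap_rate=overlap_rate,
        abundance_trend_correlation=ab_corr,
        abundance_trend_rmse=ab_rmse,
        abundance_ci_coverage=float(cover),
        phenology_trend_rmse=ph_rmse,
        n_species=int(len(j)),
    )
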