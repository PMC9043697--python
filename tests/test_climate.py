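"""Station-to-site interpolation and temperature trend analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phenosense.climate import (
    annual_means,
    fit_monthly_regression,
    idw_residual_correction,
    per_site_trends,
    region_slope_glm,
    site_temperature_table,
    temperature_trend_lmm,
)


def _stations(n=12, seed=0, lapse=-0.0065, noise=0.0):
    rng = np.random.default_rng(seed)
    alt = rng.uniform(0, 2000, n)
    df = pd.DataFrame(
        {
            "station_id": [f"st{i}" for i in range(n)],
            "x": rng.uniform(0, 1e5, n),
            "y": rng.uniform(0, 1e5, n),
            "altitude": alt,
            "latitude": np.full(n, 41.5),
            "continentality": np.full(n, 0.3),
            "solar_radiation": np.full(n, 1.0),
            "month": 1,
        }
    )
    df["tmean"] = 20.0 + lapse * alt + noise * rng.normal(size=n)
    return df


class TestMonthlyRegression:
    def test_recovers_lapse_rate(self):
        coefs, resid = fit_monthly_regression(_stations(), 1, "tmean")
        assert coefs["altitude"] == pytest.approx(-0.0065, abs=1e-9)
        assert np.abs(resid).max() < 1e-8

    def test_constant_field_zero_slopes(self):
        st_ = _stations(lapse=0.0)
        st_["tmean"] = 12.3
        coefs, _ = fit_monthly_regression(st_, 1, "tmean")
        assert coefs["Intercept"] == pytest.approx(12.3)
        assert np.abs(coefs.drop("Intercept")).max() < 1e-9

    def test_too_few_stations_raises(self):
        with pytest.raises(ValueError):
            fit_monthly_regression(_stations(n=4), 1, "tmean")

    def test_collinear_predictor_named(self):
        stn = _stations()
        stn["continentality"] = 2.0 * stn["altitude"]
        with pytest.raises(ValueError, match="altitude|continentality"):
            fit_monthly_regression(stn, 1, "tmean")


class TestIDW:
    def test_exact_at_station(self):
        xy = np.array([[0.0, 0.0], [10.0, 0.0]])
        r = np.array([1.5, -0.5])
        out = idw_residual_correction(xy, r, np.array([[10.0, 0.0]]), power=2)
        assert out[0] == pytest.approx(-0.5)

    def test_constant_residual_field(self):
        xy = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 5.0]])
        out = idw_residual_correction(xy, np.full(3, 2.0), np.array([[3.0, 1.0]]))
        assert out[0] == pytest.approx(2.0)

    def test_two_station_midpoint(self):
        xy = np.array([[0.0, 0.0], [10.0, 0.0]])
        out = idw_residual_correction(
            xy, np.array([0.0, 2.0]), np.array([[5.0, 0.0]]), power=2
        )
        assert out[0] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=25)
    @given(power=st.floats(0.1, 6.0), idx=st.integers(0, 2))
    def test_exact_interpolation_property(self, power, idx):
        xy = np.array([[0.0, 0.0], [7.0, 3.0], [2.0, 9.0]])
        r = np.array([1.0, -2.0, 0.5])
        out = idw_residual_correction(xy, r, xy[[idx]], power=power)
        assert out[0] == pytest.approx(r[idx])

    def test_no_stations_raises(self):
        with pytest.raises(ValueError):
            idw_residual_correction(np.empty((0, 2)), np.array([]), np.array([[0.0, 0.0]]))


class TestSiteTable:
    def _sites_from(self, stn):
        return pd.DataFrame(
            {
                "site_id": ["siteA", "siteB"],
                "x": stn["x"].iloc[:2].to_numpy(),
                "y": stn["y"].iloc[:2].to_numpy(),
                "altitude": stn["altitude"].iloc[:2].to_numpy(),
                "latitude": stn["latitude"].iloc[:2].to_numpy(),
                "continentality": stn["continentality"].iloc[:2].to_numpy(),
                "solar_radiation": stn["solar_radiation"].iloc[:2].to_numpy(),
            }
        )

    def test_colocated_sites_reproduce_station_values(self):
        stn = _stations(noise=0.8, seed=3)
        sites = self._sites_from(stn)
        out = site_temperature_table(stn, sites, elements=["tmean"])
        assert out.loc[out.site_id == "siteA", "tmean"].iloc[0] == pytest.approx(
            stn["tmean"].iloc[0]
        )

    def test_constant_shift_equivariance(self):
        stn = _stations(noise=0.8, seed=4)
        sites = self._sites_from(stn)
        base = site_temperature_table(stn, sites, elements=["tmean"])
        shifted_in = stn.assign(tmean=stn["tmean"] + 3.0)
        shifted = site_temperature_table(shifted_in, sites, elements=["tmean"])
        assert np.allclose(shifted["tmean"], base["tmean"] + 3.0)

    def test_leave_one_out_rmse_finite(self):
        stn = _stations(n=10, noise=0.5, seed=5)
        errs = []
        for i in range(len(stn)):
            train = stn.drop(index=i).reset_index(drop=True)
            target = stn.iloc[[i]].rename(columns={"station_id": "site_id"})
            pred = site_temperature_table(train, target, elements=["tmean"])
            errs.append(pred["tmean"].iloc[0] - stn["tmean"].iloc[i])
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        assert np.isfinite(rmse)


def _linear_series(slope, n_sites=3, years=range(1994, 2020), noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sites):
        base = 10.0 + s
        for y in years:
            for m in range(1, 13):
                rows.append(
                    dict(
                        site_id=f"s{s}",
                        year=y,
                        month=m,
                        tmean=base + slope * (y - 1994) + noise * rng.normal(),
                    )
                )
    return pd.DataFrame(rows)


class TestTrendLMM:
    def test_known_annual_slope_recovered(self):
        series = _linear_series(0.0236, n_sites=10, noise=0.5, seed=1)
        est = temperature_trend_lmm(series, "tmean", "annual")
        assert abs(est.slope - 0.0236) < 2 * est.se
        assert est.implied_change == pytest.approx(est.slope * 25)

    def test_zero_trend_type_one_rate(self):
        hits = 0
        n = 40
        for s in range(n):
            series = _linear_series(0.0, n_sites=4, noise=0.5, seed=100 + s)
            est = temperature_trend_lmm(series, "tmean", "annual")
            hits += abs(est.slope) <= 2 * est.se
        assert hits / n >= 0.90

    def test_shared_exact_line(self):
        series = _linear_series(0.05)
        est = temperature_trend_lmm(series, "tmean", "annual")
        assert est.slope == pytest.approx(0.05, abs=1e-8)
        assert est.se < 1e-3

    def test_monthly_scope(self):
        series = _linear_series(0.03, noise=0.0)
        est = temperature_trend_lmm(series, "tmean", scope=2)
        assert est.slope == pytest.approx(0.03, abs=1e-8)


class TestPerSiteTrends:
    def test_exact_line(self):
        out = per_site_trends(_linear_series(0.02))
        assert np.allclose(out["slope"], 0.02)

    def test_significant_fraction_computable(self):
        out = per_site_trends(_linear_series(0.05, n_sites=6, noise=0.3, seed=2))
        frac = (out["p_value"] < 0.05).mean()
        assert 0.0 <= frac <= 1.0

    def test_permutation_destroys_significance(self):
        series = _linear_series(0.05, n_sites=1, noise=0.2, seed=3)
        ann = annual_means(series)
        rng = np.random.default_rng(0)
        destroyed = 0
        for _ in range(40):
            perm = rng.permutation(ann["value"].to_numpy())
            fit = stats.linregress(ann["year"], perm)
            destroyed += fit.pvalue > 0.05
        assert destroyed / 40 >= 0.95


class TestRegionGLM:
    def _sites(self, slopes, regions):
        return (
            pd.DataFrame(
                {
                    "site_id": [f"s{i}" for i in range(len(slopes))],
                    "slope": slopes,
                }
            ),
            pd.DataFrame(
                {
                    "site_id": [f"s{i}" for i in range(len(slopes))],
                    "climate_region": regions,
                }
            ),
        )

    def test_near_identical_slopes_nonsignificant(self, rng):
        slopes = 0.02 + 1e-6 * rng.normal(size=12)
        regions = ["alpine_subalpine"] * 4 + ["mediterranean_mesic"] * 4 + [
            "mediterranean_xeric"
        ] * 4
        site_slopes, sites = self._sites(slopes, regions)
        fit, anova = region_slope_glm(site_slopes, sites)
        assert anova.loc["C(climate_region)", "PR(>F)"] > 0.5
        assert np.abs(fit.params.drop("Intercept")).max() < 1e-5

    def test_region_means_recovered(self, rng):
        means = {"alpine_subalpine": 0.01, "mediterranean_mesic": 0.02, "mediterranean_xeric": 0.03}
        regions = sum([[r] * 6 for r in means], [])
        slopes = [means[r] + 1e-5 * rng.normal() for r in regions]
        site_slopes, sites = self._sites(slopes, regions)
        fit, _ = region_slope_glm(site_slopes, sites)
        assert fit.params["Intercept"] == pytest.approx(0.01, abs=1e-4)
        assert (
            fit.params["C(climate_region)[T.mediterranean_xeric]"]
            == pytest.approx(0.02, abs=1e-4)
        )

    def test_single_region_raises(self):
        site_slopes, sites = self._sites([0.01, 0.02], ["alpine_subalpine"] * 2)
        with pytest.raises(ValueError):
            region_slope_glm(site_slopes, sites)
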