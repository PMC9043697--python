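"""Phylogenetic GLS: covariance construction, estimation, model sets."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from phenosense.pgls import (
    brownian_covariance,
    build_comparative_table,
    compare_models,
    estimate_lambda,
    fit_pgls,
    pagel_transform,
    phenology_abundance_models,
    trait_models,
)
from phenosense.simulate import simulate_species_effects, simulate_tree


def _design(index, x):
    return pd.DataFrame({"Intercept": 1.0, "x": x}, index=index)


class TestBrownianCovariance:
    def test_two_sisters_oracle(self):
        C, labels = brownian_covariance("((A:1,B:1):2);")
        assert labels == ["A", "B"]
        assert np.allclose(C, [[3.0, 2.0], [2.0, 3.0]])

    def test_star_tree_is_diagonal(self):
        C, _ = brownian_covariance("(A:1,B:1,C:1,D:1);")
        assert np.allclose(C, np.eye(4))

    def test_ultrametric_constant_diagonal(self):
        nwk = simulate_tree(12, seed=8)
        C, _ = brownian_covariance(nwk)
        assert np.ptp(np.diag(C)) < 1e-4

    def test_positive_semidefinite_and_symmetric(self):
        C, _ = brownian_covariance(simulate_tree(20, seed=9))
        assert np.allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > -1e-10

    def test_missing_tip_raises(self):
        with pytest.raises(KeyError, match="Z"):
            brownian_covariance("((A:1,B:1):2);", taxa=["A", "Z"])


class TestPagel:
    def test_lambda_one_is_identity_transform(self):
        C = np.array([[2.0, 1.0], [1.0, 2.0]])
        assert np.allclose(pagel_transform(C, 1.0), C)

    def test_lambda_zero_is_diagonal(self):
        C = np.array([[2.0, 1.0], [1.0, 2.0]])
        assert np.allclose(pagel_transform(C, 0.0), np.diag([2.0, 2.0]))

    def test_half_lambda_halves_offdiagonals(self):
        C = np.array([[2.0, 1.0], [1.0, 2.0]])
        out = pagel_transform(C, 0.5)
        assert out[0, 1] == 0.5
        assert out[0, 0] == 2.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pagel_transform(np.eye(2), 1.5)


class TestFitPGLS:
    def test_identity_covariance_equals_ols(self, rng):
        n = 25
        idx = [f"s{i}" for i in range(n)]
        x = rng.normal(size=n)
        y = pd.Series(1.5 * x + rng.normal(size=n), index=idx)
        X = _design(idx, x)
        ours = fit_pgls(y, X, np.eye(n))
        ref = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
        assert np.allclose(ours.params.to_numpy(), ref.params, atol=1e-8)
        assert np.allclose(ours.bse.to_numpy(), ref.bse, atol=1e-8)
        assert np.allclose(ours.tvalues.to_numpy(), ref.tvalues, atol=1e-6)

    def test_brownian_coverage(self):
        nwk = simulate_tree(30, seed=10)
        C, labels = brownian_covariance(nwk)
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        traits = pd.DataFrame({"x": x}, index=labels)
        hits = 0
        n = 60
        for s in range(n):
            eps = simulate_species_effects(traits, nwk, {}, sigma2=1.0, seed=s)
            y = pd.Series(1.5 * x, index=labels) + eps
            fit = fit_pgls(y, _design(labels, x), C)
            hits += abs(fit.params["x"] - 1.5) <= 2 * fit.bse["x"]
        assert hits / n >= 0.90

    def test_rank_deficient_design_rejected(self, rng):
        n = 10
        idx = [f"s{i}" for i in range(n)]
        x = rng.normal(size=n)
        X = _design(idx, x)
        X["x2"] = X["x"]
        with pytest.raises(ValueError, match="rank"):
            fit_pgls(pd.Series(rng.normal(size=n), index=idx), X, np.eye(n))

    def test_lambda_grid_recovers_no_signal_limit(self, rng):
        # independent residuals: the profiled lambda should land near 0
        nwk = simulate_tree(40, seed=11)
        C, labels = brownian_covariance(nwk)
        x = rng.normal(size=40)
        y = pd.Series(x + 0.1 * rng.normal(size=40), index=labels)
        fit = estimate_lambda(y, _design(labels, x), C)
        assert fit.lambda_ <= 0.3


class TestComparativeTable:
    def _table(self, sens):
        n = len(sens)
        idx = [f"sp{i:03d}" for i in range(1, n + 1)]
        traits = pd.DataFrame(
            {
                "species_id": idx,
                "voltinism": (["univoltine", "multivoltine"] * n)[:n],
                "overwinter_stage": (["egg", "larva", "pupa", "adult"] * n)[:n],
                "larval_diet": (["grass", "forb", "tree"] * n)[:n],
                "ssi": np.linspace(1, 5, n),
                "tao": np.linspace(-1, 1, n),
                "hpi": np.linspace(1, 20, n),
            }
        )
        ab = pd.Series(np.linspace(-0.04, 0.02, n), index=idx)
        ph = pd.Series(np.linspace(-0.5, 0.5, n), index=idx)
        return build_comparative_table(ab, ph, pd.Series(sens, index=idx), traits)

    def test_sqrt_transforms_are_exact(self):
        tab = self._table(np.linspace(-6, -1, 8))
        assert np.allclose(tab["abs_phenology_trend_sqrt"] ** 2, np.abs(tab["phenology_trend"]))
        assert np.allclose(tab["hpi_sqrt"] ** 2, tab["hpi"])

    def test_positive_sensitivity_species_excluded_from_model1(self):
        sens = np.linspace(-6, -1, 12).tolist() + [0.5, 1.0, 2.0]
        tab = self._table(np.array(sens))
        nwk = simulate_tree(15, seed=12)
        mods = phenology_abundance_models(tab, nwk)
        assert set(mods["abs_trend~sensitivity"].excluded) == {"sp013", "sp014", "sp015"}
        assert mods["abs_trend~sensitivity"].n == 12

    def test_constant_sensitivity_rejected(self):
        tab = self._table(np.full(10, -3.0))
        nwk = simulate_tree(10, seed=13)
        with pytest.raises(ValueError, match="variance"):
            phenology_abundance_models(tab, nwk)


class TestModelSets:
    def test_trait_models_cover_six_traits(self):
        rng = np.random.default_rng(3)
        nwk = simulate_tree(24, seed=14)
        _, labels = brownian_covariance(nwk)
        traits = pd.DataFrame(
            {
                "species_id": labels,
                "voltinism": rng.choice(["univoltine", "multivoltine"], 24),
                "overwinter_stage": rng.choice(["egg", "larva", "pupa", "adult"], 24),
                "larval_diet": rng.choice(["grass", "forb", "tree"], 24),
                "ssi": rng.uniform(1, 8, 24),
                "tao": rng.normal(size=24),
                "hpi": rng.uniform(1, 30, 24),
            }
        )
        ab = pd.Series(rng.normal(size=24) * 0.02, index=labels)
        ph = pd.Series(rng.normal(size=24) * 0.3, index=labels)
        sens = pd.Series(-rng.uniform(0, 8, 24), index=labels)
        tab = build_comparative_table(ab, ph, sens, traits)
        mods = trait_models(tab, nwk)
        for resp in ("sensitivity", "phenology_trend", "abundance_trend"):
            single = {k: v for k, v in mods[resp].items() if k != "combined"}
            assert len(single) == 6

    def test_constant_response_gives_zero_slopes(self):
        nwk = simulate_tree(12, seed=15)
        _, labels = brownian_covariance(nwk)
        rng = np.random.default_rng(4)
        traits = pd.DataFrame(
            {
                "species_id": labels,
                "voltinism": ["univoltine"] * 6 + ["multivoltine"] * 6,
                "overwinter_stage": (["egg", "larva", "pupa", "adult"] * 3),
                "larval_diet": (["grass", "forb", "tree"] * 4),
                "ssi": rng.uniform(1, 8, 12),
                "tao": rng.normal(size=12),
                "hpi": rng.uniform(1, 30, 12),
            }
        )
        const = pd.Series(0.01, index=labels)
        ph = pd.Series(rng.normal(size=12), index=labels)
        sens = pd.Series(-rng.uniform(1, 8, 12), index=labels)
        tab = build_comparative_table(const, ph, sens, traits)
        mods = trait_models(tab, nwk, responses=("abundance_trend",))
        for name, fit in mods["abundance_trend"].items():
            slopes = fit.params.drop("Intercept")
            assert np.abs(slopes).max() < 1e-10


class TestCompareModels:
    def _fit(self, aicc, k=2, n=20, response="y"):
        idx = pd.Index(["Intercept", "x"])
        from phenosense.pgls import PGLSFit

        return PGLSFit(
            response=response, predictors=["x"],
            params=pd.Series(0.0, index=idx), bse=pd.Series(1.0, index=idx),
            tvalues=pd.Series(0.0, index=idx), pvalues=pd.Series(1.0, index=idx),
            sigma2=1.0, llf=-10.0, aicc=aicc, n=n, k=k, lambda_=1.0,
        )

    def test_delta_aicc(self):
        out = compare_models({"a": self._fit(100.0), "b": self._fit(104.0)})
        assert list(out["delta_aicc"]) == [0.0, 4.0]
        assert out["model"].iloc[0] == "a"

    def test_tie_broken_by_fewer_parameters(self):
        out = compare_models({"big": self._fit(100.0, k=4), "small": self._fit(100.0, k=2)})
        assert out["model"].iloc[0] == "small"

    def test_mixed_responses_rejected(self):
        with pytest.raises(ValueError, match="responses"):
            compare_models({"a": self._fit(1.0), "b": self._fit(1.0, response="z")})
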