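"""Phylogenetic generalized least squares for species-level comparisons.

Species are not independent data points: close relatives share ancestry
and hence tend to share trait values.  Under a Brownian-motion model of
trait evolution the residual covariance of a cross-species regression is
proportional to C, the matrix of shared root-to-ancestor path lengths.
PGLS therefore estimates beta = (X' C^-1 X)^-1 X' C^-1 y, with an optional
Pagel lambda scaling of the off-diagonal covariances.

This module fits single-trait and combined models for phenological
sensitivity, phenological trends and abundance trends, the
sensitivity-versus-absolute-trend model (excluding species with atypical
positive sensitivity), and ranks models by AICc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PGLSFit",
    "brownian_covariance",
    "pagel_transform",
    "fit_pgls",
    "estimate_lambda",
    "build_comparative_table",
    "trait_models",
    "phenology_abundance_models",
    "compare_models",
]

TRAIT_PREDICTORS = ["voltinism", "overwinter_stage", "larval_diet", "ssi", "tao", "hpi_sqrt"]
CATEGORICAL_TRAITS = {"voltinism", "overwinter_stage", "larval_diet"}


@dataclass
class PGLSFit:
    response: str
    predictors: list[str]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2: float
    llf: float
    aicc: float
    n: int
    k: int  # parameter count entering AICc (coefficients + sigma2)
    lambda_: float
    excluded: list[str] = field(default_factory=list)


def brownian_covariance(tree: str | dendropy.Tree, taxa: list[str] | None = None):
    """Shared path-length matrix of a phylogeny.

    C[i, j] is the root-to-MRCA distance of tips i and j; C[i, i] the
    root-to-tip distance.  Accepts a Newick string or a dendropy Tree.
    Returns (C, labels) with labels in ``taxa`` order when given.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    tips = [leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()]
    index = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))
    for node in tree.preorder_node_iter():
        if node.edge.length is None:
            continue
        desc = [
            index[leaf.taxon.label.replace(" ", "_")]
            for leaf in node.leaf_iter()
        ]
        length = float(node.edge.length)
        if length < 0:
            raise ValueError("negative branch length in tree")
        idx = np.array(desc)
        C[np.ix_(idx, idx)] += length
    if taxa is not None:
        missing = [t for t in taxa if t not in index]
        if missing:
            raise KeyError(f"species missing from tree: {missing}")
        order = [index[t] for t in taxa]
        return C[np.ix_(order, order)], list(taxa)
    return C, tips


def pagel_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal covariances by Pagel's lambda in [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def _design(table: pd.DataFrame, predictors: list[str]):
    """Treatment-coded design matrix with intercept; alphabetical reference."""
    cols = [pd.Series(1.0, index=table.index, name="Intercept")]
    for p in predictors:
        if p in CATEGORICAL_TRAITS:
            levels = sorted(table[p].dropna().unique())
            for lev in levels[1:]:
                cols.append(
                    (table[p] == lev).astype(float).rename(f"{p}[{lev}]")
                )
        else:
            cols.append(table[p].astype(float))
    return pd.concat(cols, axis=1)


def fit_pgls(
    y: pd.Series,
    X: pd.DataFrame,
    C: np.ndarray,
    response: str = "y",
    lambda_: float = 1.0,
) -> PGLSFit:
    """Generalized least squares under the covariance C (after any lambda).

    SEs come from sigma2 (X' C^-1 X)^-1 with the unbiased GLS residual
    variance; t and p use n - p degrees of freedom; AICc is computed from
    the ML Gaussian log-likelihood with k = p + 1 parameters.
    """
    yv = y.to_numpy(dtype=float)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    if np.linalg.matrix_rank(Xv) < p:
        raise ValueError("design matrix is rank deficient")
    Cl = pagel_transform(C, lambda_)
    try:
        L = np.linalg.cholesky(Cl)
    except np.linalg.LinAlgError as e:
        raise ValueError("covariance matrix is not positive definite") from e
    yw = np.linalg.solve(L, yv)
    Xw = np.linalg.solve(L, Xv)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    dof = n - p
    sigma2 = rss / dof if dof > 0 else np.nan
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    t = beta / np.where(se > 0, se, np.nan)
    pvals = 2 * stats.t.sf(np.abs(t), dof)
    sigma2_ml = rss / n
    logdetC = 2.0 * np.log(np.diag(L)).sum()
    llf = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdetC + n)
    k = p + 1
    aic = 2 * k - 2 * llf
    aicc = aic + (2 * k * (k + 1)) / max(n - k - 1, 1)
    return PGLSFit(
        response=response,
        predictors=[c for c in X.columns if c != "Intercept"],
        params=pd.Series(beta, index=X.columns),
        bse=pd.Series(se, index=X.columns),
        tvalues=pd.Series(t, index=X.columns),
        pvalues=pd.Series(pvals, index=X.columns),
        sigma2=float(sigma2),
        llf=float(llf),
        aicc=float(aicc),
        n=n,
        k=k,
        lambda_=float(lambda_),
    )


def estimate_lambda(
    y: pd.Series,
    X: pd.DataFrame,
    C: np.ndarray,
    grid: np.ndarray | None = None,
    response: str = "y",
) -> PGLSFit:
    """Profile Pagel's lambda over a grid, return the ML fit."""
    grid = np.linspace(0.0, 1.0, 21) if grid is None else grid
    best = None
    for lam in grid:
        try:
            fit = fit_pgls(y, X, C, response=response, lambda_=float(lam))
        except ValueError:
            continue
        if best is None or fit.llf > best.llf:
            best = fit
    if best is None:
        raise ValueError("no lambda value produced a valid fit")
    return best


def build_comparative_table(
    abundance_trends: pd.Series,
    phenology_trends: pd.Series,
    sensitivities: pd.Series,
    traits: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the species-level table feeding the comparative models.

    Adds the square-root transforms: ``abs_phenology_trend_sqrt`` =
    sqrt(|phenology trend|) (magnitude of timing change, normalised) and
    ``hpi_sqrt`` = sqrt(HPI).
    """
    table = traits.copy()
    if "species_id" in table.columns:
        table = table.set_index("species_id")
    table["abundance_trend"] = abundance_trends
    table["phenology_trend"] = phenology_trends
    table["sensitivity"] = sensitivities
    table["abs_phenology_trend_sqrt"] = np.sqrt(np.abs(table["phenology_trend"]))
    table["hpi_sqrt"] = np.sqrt(table["hpi"])
    return table.dropna(subset=["abundance_trend", "phenology_trend", "sensitivity"])


def trait_models(
    table: pd.DataFrame,
    tree: str | dendropy.Tree,
    responses: tuple[str, ...] = ("sensitivity", "phenology_trend", "abundance_trend"),
    alpha: float = 0.05,
    lambda_: float = 1.0,
) -> dict[str, dict[str, PGLSFit]]:
    """Single-trait PGLS fits per response, plus a combined model.

    For each response, each of the six traits is fitted alone; traits whose
    slope (any level, for categorical traits) is significant at ``alpha``
    then enter one combined model (key "combined", present only when at
    least two traits are significant).
    """
    C, labels = brownian_covariance(tree, taxa=list(table.index))
    out: dict[str, dict[str, PGLSFit]] = {}
    for resp in responses:
        fits: dict[str, PGLSFit] = {}
        significant = []
        for trait in TRAIT_PREDICTORS:
            X = _design(table, [trait])
            fit = fit_pgls(table[resp], X, C, response=resp, lambda_=lambda_)
            fits[trait] = fit
            slope_p = fit.pvalues.drop("Intercept")
            if (slope_p < alpha).any():
                significant.append(trait)
        if len(significant) >= 2:
            X = _design(table, significant)
            fits["combined"] = fit_pgls(
                table[resp], X, C, response=resp, lambda_=lambda_
            )
        out[resp] = fits
    return out


def phenology_abundance_models(
    table: pd.DataFrame,
    tree: str | dendropy.Tree,
    significant_traits: list[str] | None = None,
    alpha: float = 0.05,
    lambda_: float = 1.0,
    min_species: int = 5,
) -> dict[str, PGLSFit]:
    """PGLS models linking phenology to abundance trends.

    Fits (1) ``abs_phenology_trend_sqrt ~ sensitivity`` on the species with
    negative sensitivity only (positive-sensitivity species are excluded
    as atypical responders and recorded on the fit); and (2)
    ``abundance_trend`` on each of sensitivity, phenology_trend and
    abs_phenology_trend_sqrt, alone and — when ``significant_traits`` is
    given (normally from :func:`trait_models` on abundance trends) — jointly
    with those traits.
    """
    out: dict[str, PGLSFit] = {}

    neg = table[table["sensitivity"] < 0]
    excluded = [s for s in table.index if s not in neg.index]
    if len(neg) < min_species:
        raise ValueError(
            f"only {len(neg)} species with negative sensitivity (need {min_species})"
        )
    if neg["sensitivity"].nunique() < 2:
        raise ValueError("sensitivity has no variance among included species")
    Cn, _ = brownian_covariance(tree, taxa=list(neg.index))
    fit1 = fit_pgls(
        neg["abs_phenology_trend_sqrt"],
        _design(neg, ["sensitivity"]),
        Cn,
        response="abs_phenology_trend_sqrt",
        lambda_=lambda_,
    )
    fit1.excluded = excluded
    out["abs_trend~sensitivity"] = fit1

    C, _ = brownian_covariance(tree, taxa=list(table.index))
    for pred in ("sensitivity", "phenology_trend", "abs_phenology_trend_sqrt"):
        X = _design(table, [pred])
        out[f"abundance~{pred}"] = fit_pgls(
            table["abundance_trend"], X, C, response="abundance_trend", lambda_=lambda_
        )
        if significant_traits:
            X2 = _design(table, [pred] + list(significant_traits))
            out[f"abundance~{pred}+traits"] = fit_pgls(
                table["abundance_trend"], X2, C,
                response="abundance_trend", lambda_=lambda_,
            )
    return out


def compare_models(fits: dict[str, PGLSFit] | list[PGLSFit]) -> pd.DataFrame:
    """AICc ranking of models sharing one response and observation set.

    Ties in AICc break towards the model with fewer parameters.
    """
    if isinstance(fits, dict):
        items = list(fits.items())
    else:
        items = [(f"model{i}", f) for i, f in enumerate(fits)]
    responses = {f.response for _, f in items}
    if len(responses) > 1:
        raise ValueError(f"models mix responses: {sorted(responses)}")
    ns = {f.n for _, f in items}
    if len(ns) > 1:
        raise ValueError("models were fitted on different observation counts")
    rows = [
        dict(model=name, predictors="+".join(f.predictors) or "1",
             k=f.k, aicc=f.aicc, llf=f.llf)
        for name, f in items
    ]
    df = pd.DataFrame(rows).sort_values(["aicc", "k"], kind="stable").reset_index(drop=True)
    df["delta_aicc"] = df["aicc"] - df["aicc"].iloc[0]
    return df
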