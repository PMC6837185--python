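"""Statistical layer: AICc multimodel inference, clustering, group tests.

All-subsets ordinary least-squares model selection with the small-sample
Akaike criterion, full (zero-substitution) model averaging with
unconditional standard errors and per-predictor relative importance;
collinearity screening; nested-model likelihood-ratio tests; hierarchical
agglomerative clustering of per-seal foraging summaries on Euclidean
distances after standardizing each feature by its column total; and the
non-parametric group comparisons (one-tailed exact Mann-Whitney, one-way
ANOVA, Spearman rank correlation).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ModelSet",
    "ClusterResult",
    "collinearity_screen",
    "all_subsets_aicc",
    "model_average",
    "lrt_nested",
    "standardize_and_cluster",
    "group_compare",
]


# ---------------------------------------------------------------------------
# Collinearity screen


def collinearity_screen(
    predictors: pd.DataFrame,
    keep: Sequence[str] = (),
    r_max: float = 0.7,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy exclusion of predictors correlated beyond ``|r| > r_max``.

    Predictors named in ``keep`` are always retained. The remaining
    columns are screened in order: a candidate is dropped if its absolute
    Pearson correlation with any already-retained predictor exceeds
    ``r_max``. Returns the retained names and an exclusion log of
    ``(dropped, retained_partner, r)`` triples.
    """
    if predictors.shape[1] < 2:
        raise ValueError("need at least two predictors")
    for col in predictors.columns:
        if np.isclose(predictors[col].std(ddof=0), 0.0):
            raise ValueError(f"constant predictor: {col}")
    retained = [c for c in predictors.columns if c in set(keep)]
    log: list[tuple[str, str, float]] = []
    for col in predictors.columns:
        if col in retained:
            continue
        clash = None
        for other in retained:
            r = float(predictors[col].corr(predictors[other]))
            if abs(r) > r_max:
                clash = (col, other, r)
                break
        if clash is None:
            retained.append(col)
        else:
            log.append(clash)
    return retained, log


# ---------------------------------------------------------------------------
# All-subsets AICc and model averaging


@dataclass
class FittedModel:
    terms: tuple[str, ...]
    params: pd.Series  # includes "(Intercept)"
    bse: pd.Series
    rss: float
    k: int  # parameter count incl. intercept and residual variance
    loglik: float
    aicc: float


@dataclass
class ModelSet:
    """AICc-ranked OLS candidate set over all predictor subsets."""

    models: list[FittedModel]
    n: int
    response: str

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "terms": "+".join(m.terms) if m.terms else "(intercept only)",
                "k": m.k,
                "aicc": m.aicc,
            }
            for m in self.models
        ]
        df = pd.DataFrame(rows)
        df["delta"] = df["aicc"] - df["aicc"].min()
        w = np.exp(-df["delta"] / 2.0)
        df["weight"] = w / w.sum()
        return df.sort_values("aicc", ignore_index=True)


def _ols_fit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    n, p = X.shape
    dof = max(n - p, 1)
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    return beta, np.sqrt(np.diag(cov)), rss


def gaussian_loglik(rss: float, n: int) -> float:
    """Maximized Gaussian log-likelihood of an OLS fit."""
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def aicc_from_loglik(loglik: float, k: int, n: int) -> float:
    aic = -2.0 * loglik + 2.0 * k
    if n - k - 1 <= 0:
        return float("inf")
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def all_subsets_aicc(
    y: Sequence[float],
    predictors: pd.DataFrame,
    response: str = "y",
) -> ModelSet:
    """Fit OLS models for every predictor subset and rank them by AICc.

    The parameter count ``k`` includes the intercept and the residual
    variance, so the intercept-only model has ``k = 2``. Subsets too large
    for the sample (``n - k - 1 <= 0``) are skipped with a warning entry.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    cols = list(predictors.columns)
    models = []
    for r in range(len(cols) + 1):
        for terms in combinations(cols, r):
            Xdf = predictors.loc[:, list(terms)]
            X = np.column_stack([np.ones(n)] + [Xdf[c].to_numpy(dtype=float) for c in terms])
            k = X.shape[1] + 1  # + residual variance
            if n - k - 1 <= 0:
                import warnings

                warnings.warn(f"subset {terms} skipped: n too small for k={k}")
                continue
            beta, bse, rss = _ols_fit(y, X)
            ll = gaussian_loglik(rss, n)
            names = ["(Intercept)", *terms]
            models.append(
                FittedModel(
                    terms=terms,
                    params=pd.Series(beta, index=names),
                    bse=pd.Series(bse, index=names),
                    rss=rss,
                    k=k,
                    loglik=ll,
                    aicc=aicc_from_loglik(ll, k, n),
                )
            )
    models.sort(key=lambda m: m.aicc)
    return ModelSet(models=models, n=n, response=response)


def model_average(model_set: ModelSet, delta_max: float = 4.0) -> pd.DataFrame:
    """Full model averaging over the ``delta AICc <= delta_max`` subset.

    Akaike weights ``w_i = exp(-delta_i/2)`` renormalized over the retained
    models. Coefficients are averaged with zero substituted where a term
    is absent from a model; the unconditional standard error combines
    within-model variance with between-model spread,
    ``se = sum_i w_i * sqrt(se_i^2 + (beta_i - beta_bar)^2)``. Relative
    importance of a term is the summed weight of retained models that
    contain it.
    """
    if not model_set.models:
        raise ValueError("empty model set")
    best = model_set.models[0].aicc
    retained = [m for m in model_set.models if m.aicc - best <= delta_max]
    if not retained:
        raise ValueError("no models within delta_max")
    deltas = np.array([m.aicc - best for m in retained])
    w = np.exp(-deltas / 2.0)
    w = w / w.sum()
    terms = ["(Intercept)"]
    for m in retained:
        for t in m.terms:
            if t not in terms:
                terms.append(t)
    rows = []
    for t in terms:
        betas = np.array([float(m.params.get(t, 0.0)) for m in retained])
        ses = np.array([float(m.bse.get(t, 0.0)) for m in retained])
        beta_bar = float(np.sum(w * betas))
        se_u = float(np.sum(w * np.sqrt(ses**2 + (betas - beta_bar) ** 2)))
        contains = np.array([t == "(Intercept)" or t in m.terms for m in retained])
        z = abs(beta_bar) / se_u if se_u > 0 else float("inf")
        rows.append(
            {
                "term": t,
                "estimate": beta_bar,
                "se": se_u,
                "z": z,
                "p": 2.0 * sps.norm.sf(z),
                "relative_importance": float(np.sum(w[contains])),
                "n_models": int(np.sum(contains)),
            }
        )
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# Likelihood-ratio test for nested OLS models


def lrt_nested(
    y: Sequence[float],
    predictors_small: pd.DataFrame,
    predictors_large: pd.DataFrame,
) -> tuple[float, float, int]:
    """LRT between nested Gaussian linear models.

    Statistic ``n * ln(RSS_small / RSS_large)``, referred to chi-squared
    with df equal to the difference in parameter count. The smaller
    model's predictors must be a subset of the larger's.
    """
    small = set(predictors_small.columns)
    large = set(predictors_large.columns)
    if not small <= large:
        raise ValueError("models are not nested")
    y = np.asarray(y, dtype=float)
    n = len(y)

    def rss_of(df: pd.DataFrame) -> float:
        X = np.column_stack([np.ones(n), df.to_numpy(dtype=float)]) if df.shape[1] else np.ones((n, 1))
        _, _, rss = _ols_fit(y, X)
        return rss

    rss_s, rss_l = rss_of(predictors_small), rss_of(predictors_large)
    stat = n * np.log(rss_s / rss_l) if rss_l > 0 else float("inf")
    df_diff = len(large) - len(small)
    p = float(sps.chi2.sf(stat, df_diff)) if df_diff > 0 else 1.0
    return float(stat), p, df_diff


# ---------------------------------------------------------------------------
# Hierarchical clustering of foraging strategies


@dataclass
class ClusterResult:
    standardized: pd.DataFrame
    distances: pd.DataFrame  # square symmetric Euclidean distance matrix
    linkage_matrix: np.ndarray
    memberships: pd.Series  # cluster id per seal at the flat cut


def standardize_and_cluster(
    features: pd.DataFrame,
    k: int = 2,
    normalizer: str = "total",
    method: str = "average",
) -> ClusterResult:
    """Cluster seals on standardized foraging-trip features.

    Each feature column is divided by its total (default) or its maximum,
    balancing variables measured on different scales; seals are then
    agglomeratively clustered on Euclidean distances with group-average
    linkage and cut into ``k`` flat clusters.
    """
    if len(features) < 2:
        raise ValueError("need at least two seals")
    if features.isna().any().any():
        raise ValueError("features contain missing values")
    if normalizer == "total":
        denom = features.sum(axis=0)
    elif normalizer == "max":
        denom = features.max(axis=0)
    else:
        raise ValueError("normalizer must be 'total' or 'max'")
    if np.any(np.isclose(denom.to_numpy(dtype=float), 0.0)):
        raise ValueError("a feature column has zero total")
    std = features / denom
    condensed = pdist(std.to_numpy(dtype=float), metric="euclidean")
    Z = linkage(condensed, method=method)
    members = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(
        standardized=std,
        distances=pd.DataFrame(
            squareform(condensed), index=features.index, columns=features.index
        ),
        linkage_matrix=Z,
        memberships=pd.Series(members, index=features.index, name="cluster"),
    )


# ---------------------------------------------------------------------------
# Group comparisons


def group_compare(
    *groups: Sequence[float],
    test: str = "mannwhitney",
    alternative: str = "less",
):
    """Nonparametric and classical group comparisons.

    ``test='mannwhitney'``: one-tailed Mann-Whitney U on two groups, exact
    p for small samples (scipy's exact method when no ties). ``alternative``
    states the direction for the first group. ``test='anova'``: one-way
    ANOVA F over two or more groups. ``test='spearman'``: Spearman rank
    correlation of two paired vectors.
    """
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    if test == "mannwhitney":
        if len(groups) != 2:
            raise ValueError("Mann-Whitney compares exactly two groups")
        a, b = groups
        method = "exact" if (len(a) <= 8 and len(b) <= 8) else "auto"
        res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
        return {"U": float(res.statistic), "p": float(res.pvalue)}
    if test == "anova":
        if len(groups) < 2:
            raise ValueError("ANOVA needs at least two groups")
        res = sps.f_oneway(*groups)
        return {"F": float(res.statistic), "p": float(res.pvalue)}
    if test == "spearman":
        if len(groups) != 2 or len(groups[0]) != len(groups[1]):
            raise ValueError("Spearman needs two paired vectors")
        res = sps.spearmanr(groups[0], groups[1])
        return {"rho": float(res.statistic), "p": float(res.pvalue)}
    raise ValueError(f"unknown test: {test!r}")
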