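"""Covariate-adjusted three-group contrasts: ANOVA, least-squares means,
fold changes, and driving-pair attribution.

For each feature y the linear model

    y ~ population + sex + batch/plate (+ further categorical covariates)

is fitted by OLS and the population factor is assessed by a partial F-test
(full vs. population-free model), i.e. testing that the adjusted group
means are identical.  Least-squares means are model predictions per
population averaged over a balanced grid of the other factor levels; on
log2-scale data the fold change between groups a and b is 2^(lsm_a -
lsm_b).  Significance is declared per platform after Bonferroni correction
over the features actually tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "FeatureFit",
    "anova_feature",
    "least_squares_means",
    "fold_change",
    "platform_contrast",
]


@dataclass
class FeatureFit:
    """Per-feature fit summary: partial F for the group factor plus lsm."""

    feature: str
    f_stat: float
    p_raw: float
    lsm: dict
    n_used: int
    skipped: bool = False
    skip_reason: str | None = None


def _design(
    population: pd.Series, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, np.ndarray, list, dict]:
    """Build full and reduced (no population) dummy-coded design matrices.

    Returns (X_full, X_reduced, population level order, factor level map).
    Treatment coding with the first level as reference; factor levels are
    taken in order of first appearance.
    """
    pop_levels = list(pd.unique(population))
    if len(pop_levels) < 2:
        raise ValueError("need at least two populations")
    n = len(population)
    cols_full = [np.ones(n)]
    pop_dummies = []
    for lev in pop_levels[1:]:
        pop_dummies.append((population == lev).to_numpy(dtype=float))
    cols_full += pop_dummies
    cols_reduced = [np.ones(n)]
    factor_levels = {}
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            levels = list(pd.unique(col))
            factor_levels[name] = levels
            for lev in levels[1:]:
                d = (col == lev).to_numpy(dtype=float)
                cols_full.append(d)
                cols_reduced.append(d)
    X_full = np.column_stack(cols_full)
    X_reduced = np.column_stack(cols_reduced)
    return X_full, X_reduced, pop_levels, factor_levels


def anova_feature(
    y: pd.Series,
    population: pd.Series,
    covariates: pd.DataFrame | None = None,
    min_per_group: int = 2,
) -> FeatureFit:
    """Partial F-test for the population factor on one feature.

    Samples with missing y are dropped featurewise (complete-case); the
    model is OLS of y on population + covariate dummies, and the test
    compares it against the covariate-only model.

    Raises
    ------
    ValueError
        If a covariate is collinear with population (the partial F would
        be undefined), naming the covariate.
    """
    mask = y.notna().to_numpy()
    if covariates is not None:
        mask &= covariates.notna().all(axis=1).to_numpy()
    yv = y[mask]
    pop = population[mask]
    cov = covariates[mask] if covariates is not None else None

    counts = pop.value_counts()
    if (counts < min_per_group).any() or counts.size < population.nunique():
        missing = sorted(set(pd.unique(population)) - set(counts.index))
        reason = (
            f"population(s) {missing} unobserved"
            if missing
            else f"fewer than {min_per_group} observations in some population"
        )
        return FeatureFit(str(y.name), np.nan, np.nan, {}, int(mask.sum()), True, reason)

    X_full, X_reduced, pop_levels, factor_levels = _design(pop, cov)
    rank_full = np.linalg.matrix_rank(X_full)
    if rank_full < X_full.shape[1]:
        # identify the offending covariate for the error message
        for name in (cov.columns if cov is not None else []):
            X_wo = _design(pop, cov.drop(columns=[name]))[0]
            if np.linalg.matrix_rank(X_wo) == X_wo.shape[1]:
                raise ValueError(f"covariate {name!r} is collinear with population")
        raise ValueError("design matrix is rank deficient")

    fit_full = sm.OLS(yv.to_numpy(dtype=float), X_full).fit()
    fit_reduced = sm.OLS(yv.to_numpy(dtype=float), X_reduced).fit()
    df_num = X_full.shape[1] - X_reduced.shape[1]
    df_den = int(fit_full.df_resid)
    if fit_full.ssr <= 0:
        f_stat, p_raw = np.inf, 0.0
    else:
        f_stat = ((fit_reduced.ssr - fit_full.ssr) / df_num) / (fit_full.ssr / df_den)
        p_raw = float(stats.f.sf(f_stat, df_num, df_den))
    lsm = least_squares_means(fit_full.params, pop_levels, factor_levels)
    return FeatureFit(str(y.name), float(f_stat), p_raw, lsm, int(mask.sum()))


def least_squares_means(
    params: np.ndarray, pop_levels: Sequence[str], factor_levels: dict
) -> dict:
    """Least-squares mean per population from a fitted dummy-coded model.

    With treatment coding the prediction averaged over a balanced grid of
    the other factors is

        lsm(g) = intercept + beta_g + sum_f mean(0, beta_f2, ..., beta_fL)

    where beta_g = 0 for the reference population and each factor f with L
    levels contributes the average of its L level effects (reference
    effect 0 included).
    """
    params = np.asarray(params, dtype=float)
    k = len(pop_levels)
    offset = 0.0
    idx = k  # params: [intercept, pop_2..pop_k, then factor dummies in order]
    for name, levels in factor_levels.items():
        n_lev = len(levels)
        coefs = params[idx : idx + n_lev - 1]
        offset += coefs.sum() / n_lev
        idx += n_lev - 1
    lsm = {pop_levels[0]: params[0] + offset}
    for i, lev in enumerate(pop_levels[1:], start=1):
        lsm[lev] = params[0] + params[i] + offset
    return {k: float(v) for k, v in lsm.items()}


def fold_change(lsm_a: float, lsm_b: float) -> float:
    """Natural-scale fold change between two log2-scale group means.

    FC(a, b) = 2^(lsm_a - lsm_b), so FC(a, b) * FC(b, a) = 1 exactly.
    """
    if not (np.isfinite(lsm_a) and np.isfinite(lsm_b)):
        raise ValueError("least-squares means must be finite")
    return float(2.0 ** (lsm_a - lsm_b))


def platform_contrast(
    matrix: pd.DataFrame,
    population: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature adjusted ANOVA over a whole platform with Bonferroni control.

    Parameters
    ----------
    matrix
        samples x features values (log2 scale), NaN = missing.
    population
        Group factor per sample.
    covariates
        Optional categorical covariates (sex, batch, RT plate, ...);
        samples with a missing covariate are dropped platform-wide.
    alpha
        Family-wise significance level applied to Bonferroni-adjusted p.

    Returns
    -------
    DataFrame indexed by feature with columns ``f_stat``, ``p_raw``,
    ``p_bonferroni`` (= min(1, m * p_raw) with m = features actually
    tested), ``lsm_<pop>``, ``fc_<a>_vs_<b>`` for every ordered pair,
    ``driving_pair`` (largest |lsm difference|, ties by declared pair
    order) and ``significant``.
    """
    if matrix.shape[1] == 0:
        raise ValueError("empty feature matrix")
    population = population.reindex(matrix.index)
    if covariates is not None:
        covariates = covariates.reindex(matrix.index)
        complete = covariates.notna().all(axis=1)
        matrix, population, covariates = (
            matrix[complete],
            population[complete],
            covariates[complete],
        )
    pop_levels = list(pd.unique(population.dropna()))
    fits = [
        anova_feature(matrix[feat], population, covariates)
        for feat in matrix.columns
    ]
    tested = [f for f in fits if not f.skipped]
    m = len(tested)
    rows = []
    for f in fits:
        row = {
            "feature": f.feature,
            "f_stat": f.f_stat,
            "p_raw": f.p_raw,
            "n_used": f.n_used,
            "skipped": f.skipped,
        }
        if f.skipped:
            row["p_bonferroni"] = np.nan
        else:
            row["p_bonferroni"] = min(1.0, m * f.p_raw)
        for pop in pop_levels:
            row[f"lsm_{pop}"] = f.lsm.get(pop, np.nan)
        best_pair, best_delta = "none", -1.0
        for a, b in combinations(pop_levels, 2):
            if f.lsm:
                row[f"fc_{a}_vs_{b}"] = fold_change(f.lsm[a], f.lsm[b])
                delta = abs(f.lsm[a] - f.lsm[b])
                if delta > best_delta:
                    best_pair, best_delta = f"{a}-{b}", delta
            else:
                row[f"fc_{a}_vs_{b}"] = np.nan
        row["driving_pair"] = best_pair if f.lsm and best_delta > 0 else "none"
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature")
    out["significant"] = out["p_bonferroni"] < alpha
    return out
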