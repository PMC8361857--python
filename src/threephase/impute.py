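"""Multiple imputation by chained equations, and Rubin's pooling rules.

Missing covariate values on observation periods are imputed by cycling
over the incomplete variables: continuous variables by predictive-mean
matching (k = 5 donors, with a posterior draw of the regression
coefficients), categorical variables by multinomial draws from a fitted
multinomial logistic model.  The predictor set always contains the
contraceptive category, the ART category, the pregnancy indicator and
log exposure time, plus the other covariates at their current imputed
values.  Each of the m completed datasets is an independent chain with
10 burn-in cycles, deterministic under the seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (DEFAULT_CONTRAST, PoissonRateResults, _irr_table)

logger = logging.getLogger(__name__)

_DEFAULT_CATEGORICAL = {"marital_status", "education", "who_stage", "program"}


def _static_predictors(df):
    """Exposure/outcome predictor block, constant across imputation cycles."""
    parts = [np.ones((len(df), 1))]
    for fac in ("contraceptive", "art"):
        dummies = pd.get_dummies(df[fac], dtype=float)
        parts.append(dummies.values[:, 1:])
    parts.append(df["pregnancy"].astype(float).values[:, None])
    parts.append(np.log(df["exposure_time"].astype(float).values)[:, None])
    return np.column_stack(parts)


def _predictor_matrix(df, exclude, all_imputed, categorical, static):
    """Static block plus the other imputed variables at current values."""
    parts = [static]
    for v in all_imputed:
        if v == exclude:
            continue
        if v in categorical:
            dm = pd.get_dummies(df[v].astype(str), dtype=float)
            parts.append(dm.values[:, 1:])
        else:
            parts.append(df[v].astype(float).values[:, None])
    return np.column_stack(parts)


def _pmm_impute(y_obs, X_obs, X_mis, k, rng):
    """Predictive-mean matching with a normal posterior draw of beta."""
    beta, res_ss, rank, _sv = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    n, p = X_obs.shape
    dof = max(n - rank, 1)
    sigma2 = float(res_ss[0]) / dof if len(np.atleast_1d(res_ss)) else \
        float(np.sum((y_obs - X_obs @ beta) ** 2)) / dof
    XtX = X_obs.T @ X_obs
    try:
        cov = sigma2 * np.linalg.pinv(XtX)
        beta_star = rng.multivariate_normal(beta, cov, method="cholesky")
    except Exception:
        beta_star = beta
    pred_obs = X_obs @ beta
    pred_mis = X_mis @ beta_star
    order = np.argsort(pred_obs, kind="mergesort")
    sorted_pred = pred_obs[order]
    n_obs = len(y_obs)
    pos = np.searchsorted(sorted_pred, pred_mis)
    # candidate window of 2k sorted neighbours around the insertion point
    offs = np.arange(-k, k)
    idx = np.clip(pos[:, None] + offs[None, :], 0, n_obs - 1)
    cand = order[idx]                              # (n_mis, 2k)
    dist = np.abs(pred_obs[cand] - pred_mis[:, None])
    kk = min(k, dist.shape[1])
    nearest = np.take_along_axis(cand, np.argpartition(dist, kk - 1, axis=1)[:, :kk],
                                 axis=1)
    pick = rng.integers(kk, size=len(pred_mis))
    return y_obs[nearest[np.arange(len(pred_mis)), pick]]


def _multinomial_impute(y_obs, X_obs, X_mis, rng):
    """Multinomial-logistic draws for a categorical variable."""
    from sklearn.linear_model import LogisticRegression

    levels, codes = np.unique(y_obs, return_inverse=True)
    if len(levels) == 1:
        return np.repeat(levels[0], len(X_mis))
    # a touch of ridge keeps sparse categories from separating
    clf = LogisticRegression(max_iter=500, C=10.0)
    import warnings
    from sklearn.exceptions import ConvergenceWarning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X_obs[:, 1:], codes)  # sklearn adds its own intercept
    probs = clf.predict_proba(X_mis[:, 1:])
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(X_mis))
    pick = (u[:, None] > cum).sum(axis=1)
    return levels[np.clip(pick, 0, len(levels) - 1)]


def mice_impute(periods: pd.DataFrame, variables=None, m: int = 10,
                n_burn: int = 10, k_pmm: int = 5, seed: int = 0,
                categorical=None) -> list[pd.DataFrame]:
    """Return ``m`` completed copies of the periods table.

    ``variables`` defaults to every covariate column with missing values;
    ``categorical`` defaults to the usual categorical covariates.  A
    variable that is 100% missing cannot be imputed and raises.  With no
    missing data the input is returned as ``m`` identical copies.
    """
    from .cohort import COVARIATE_COLUMNS

    categorical = set(categorical) if categorical is not None else set(_DEFAULT_CATEGORICAL)
    if variables is None:
        variables = [c for c in COVARIATE_COLUMNS
                     if c in periods.columns and periods[c].isna().any()]
    variables = list(variables)
    for v in variables:
        if periods[v].isna().all():
            raise ValueError(f"variable {v!r} is 100% missing; cannot impute")
    if not variables:
        return [periods.copy() for _ in range(m)]

    masks = {v: periods[v].isna().values for v in variables}
    static = _static_predictors(periods)
    completed = []
    for chain in range(m):
        rng = np.random.default_rng([seed, chain])
        df = periods.copy()
        # initialize by random draws from the observed marginals
        for v in variables:
            obs = df.loc[~masks[v], v].values
            df.loc[masks[v], v] = obs[rng.integers(len(obs), size=masks[v].sum())]
        for _cycle in range(n_burn):
            for v in variables:
                X = _predictor_matrix(df, v, variables, categorical, static)
                X_obs, X_mis = X[~masks[v]], X[masks[v]]
                if v in categorical:
                    y_obs = df.loc[~masks[v], v].values
                    df.loc[masks[v], v] = _multinomial_impute(y_obs, X_obs, X_mis, rng)
                else:
                    y_obs = df.loc[~masks[v], v].astype(float).values
                    df.loc[masks[v], v] = _pmm_impute(y_obs, X_obs, X_mis, k_pmm, rng)
        completed.append(df)
    return completed


@dataclass
class PooledResults:
    """Rubin's-rules pooled fit across m imputations.

    Total covariance = mean within-imputation covariance plus
    (1 + 1/m) times the between-imputation covariance of the coefficient
    vectors.  The influence attribute averages the per-imputation
    influence functions (used when raking auxiliaries come from a pooled
    phase-1 fit).
    """

    params: pd.Series
    cov: pd.DataFrame
    m: int
    within: pd.DataFrame
    between: pd.DataFrame
    influence: pd.DataFrame
    design: object
    n_clusters: int

    @property
    def bse(self) -> pd.Series:
        d = np.clip(np.diag(self.cov.values), 0.0, None)
        return pd.Series(np.sqrt(d), index=self.params.index)

    def irr_contrasts(self, contrasts=(DEFAULT_CONTRAST,)) -> pd.DataFrame:
        return _irr_table(self.params, self.cov, self.design, contrasts)


def pool_rubin(fits) -> PooledResults:
    """Pool m fitted models (PoissonRateResults) by Rubin's rules."""
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("pooling needs m >= 2 fits")
    index = fits[0].params.index
    for f in fits[1:]:
        if not f.params.index.equals(index):
            raise ValueError("mismatched parameterizations across imputations")
    m = len(fits)
    betas = np.stack([f.params.values for f in fits])
    beta_bar = betas.mean(axis=0)
    within = np.mean([f.cov.values for f in fits], axis=0)
    dev = betas - beta_bar
    between = dev.T @ dev / (m - 1)
    total = within + (1.0 + 1.0 / m) * between
    infl = sum(f.influence for f in fits) / m
    return PooledResults(
        params=pd.Series(beta_bar, index=index),
        cov=pd.DataFrame(total, index=index, columns=index),
        m=m,
        within=pd.DataFrame(within, index=index, columns=index),
        between=pd.DataFrame(between, index=index, columns=index),
        influence=infl,
        design=fits[0].model.design,
        n_clusters=fits[0].n_clusters,
    )
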