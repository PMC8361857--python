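"""Estimator paths: naive phase-1 fits and raking-calibrated weighted fits.

The corrected estimator works in four steps: (1) fit the Poisson model to
the full error-prone EMR data and keep the per-woman influence functions;
(2) attach design weights 1/p1 (chart phase) or 1/(p1 p2) (interview
phase) to the validated women; (3) calibrate those weights by generalized
raking so that weighted sums of the phase-1 influence functions over the
validated sample match their known full-cohort totals; (4) refit the
model to the validated (reconciled, re-coded) data with the calibrated
weights and a woman-clustered sandwich variance.  Under
missing-at-random validation sampling this recovers what a fully
validated analysis would estimate.

Two variance estimators are available for the weighted fit:

``robust``
    the sandwich with calibrated weights treated as fixed (clustered by
    woman).  Simple and self-contained but ignores both the variance
    reduction from calibration and the finite sampling fractions, so it
    is conservative.
``linearized``
    an approximate design-based estimator: scores are residualized on the
    calibration auxiliaries and their weighted totals get the stratified
    without-replacement variance (with finite-population correction) of
    the phase-2 design.  With many sparsely sampled strata (single-unit
    strata contribute no variance estimate) it can understate the true
    variance, so the robust sandwich stays the default.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .impute import mice_impute, pool_rubin
from .model import ModelSpec, PoissonRateModel, PoissonRateResults
from .raking import raking_calibrate
from .sampling import compute_weights

logger = logging.getLogger(__name__)


def naive_fit(periods: pd.DataFrame, spec: ModelSpec | None = None,
              m: int = 10, seed: int = 0, weights=None):
    """Phase-1 style fit: impute if the spec's covariates have missing
    values (pooling by Rubin's rules), otherwise a single direct fit."""
    spec = spec or ModelSpec()
    need = [c for c in spec.covariates
            if c not in ("age_sq", "sqrt_cd4", "log_bmi", "sqrt_log_bmi",
                         "any_children", "calendar_time")]
    alias = {"age_sq": "age", "sqrt_cd4": "cd4", "log_bmi": "bmi",
             "sqrt_log_bmi": "bmi", "any_children": "n_children",
             "calendar_time": "calendar_year"}
    need += [alias[c] for c in spec.covariates if c in alias]
    need = [c for c in dict.fromkeys(need) if c in periods.columns]
    has_missing = any(periods[c].isna().any() for c in need)
    if not has_missing:
        return PoissonRateModel(periods, spec=spec, weights=weights).fit()
    imputed = mice_impute(periods, variables=[c for c in need
                                              if periods[c].isna().any()],
                          m=m, seed=seed)
    fits = [PoissonRateModel(df, spec=spec, weights=weights).fit() for df in imputed]
    return pool_rubin(fits)


def _aux_matrix(phase1_fit, aux, design):
    """Auxiliary matrix (full cohort) for calibration.

    ``aux`` may be ``"all"`` (every influence column -- only advisable
    when the validated sample is large relative to the parameter count),
    a list of influence column names, or a list of
    :class:`~threephase.model.Contrast` objects, in which case the
    influence functions are projected onto the contrast vectors: the
    efficient one-dimensional auxiliary for each target log IRR.
    """
    infl = phase1_fit.influence
    if isinstance(aux, str):
        if aux != "all":
            raise ValueError(f"unknown aux option {aux!r}")
        return infl
    aux = list(aux)
    if aux and hasattr(aux[0], "within_factor"):  # contrasts
        col_pos = {c: j for j, c in enumerate(design.columns)}
        kept = [col_pos[c] for c in infl.columns]
        kept_set = set(kept)
        cols = {}
        for ct in aux:
            c_full = design.contrast_vector(ct)
            bad = [design.columns[j] for j in np.flatnonzero(c_full)
                   if j not in kept_set]
            if bad:
                raise ValueError(f"contrast {ct.label!r} touches pruned "
                                 f"phase-1 column(s) {bad}")
            cols[f"infl({ct.label})"] = infl.values @ c_full[kept]
        return pd.DataFrame(cols, index=infl.index)
    return infl[aux]


def weighted_corrected_fit(
    validated_periods: pd.DataFrame,
    assignments: pd.DataFrame,
    phase1_fit,
    spec: ModelSpec | None = None,
    phase: str = "interview",
    calibrate: bool = True,
    aux="all",
    variance: str = "robust",
    raking_kwargs: dict | None = None,
) -> PoissonRateResults:
    """Raking-calibrated (or plain IPW) weighted fit on validated data.

    ``phase1_fit`` supplies the per-woman influence functions (auxiliaries
    known for the whole cohort) and may be a plain or a pooled fit.  With
    ``calibrate=False`` the base 1/p1 (or 1/(p1 p2)) weights are used
    as-is, giving the plain IPW estimator.  See :func:`_aux_matrix` for
    the ``aux`` choices.
    """
    spec = spec or ModelSpec()
    w = compute_weights(assignments, phase=phase)
    have = pd.Index(pd.unique(validated_periods["woman_id"]))
    sampled = w.index.intersection(have)
    lost = w.index.difference(have)
    if len(lost):
        logger.warning("%d validated woman(en) contribute no validated periods "
                       "and drop from the weighted fit", len(lost))
    if len(sampled) == 0:
        raise ValueError("no validated women with usable periods")
    d = w.loc[sampled].values.astype(float)

    infl = _aux_matrix(phase1_fit, aux, phase1_fit.design
                       if hasattr(phase1_fit, "design")
                       else phase1_fit.model.design)
    aux_full = infl.values
    aux_sample = infl.reindex(sampled)
    if aux_sample.isna().any().any():
        missing = sampled[aux_sample.isna().any(axis=1)]
        raise ValueError(f"no phase-1 influence for women {missing[:5].tolist()}")

    rk = None
    if calibrate:
        rk = raking_calibrate(d, aux_sample.values, aux_full,
                              **(raking_kwargs or {}))
        weights = pd.Series(rk.weights, index=sampled)
    else:
        weights = pd.Series(d, index=sampled)

    sub = validated_periods[validated_periods["woman_id"].isin(set(sampled))]
    model = PoissonRateModel(sub, spec=spec, weights=weights)
    res = model.fit()
    res.raking = rk
    if variance == "linearized":
        res = _linearized_variance(res, assignments, aux_sample.values
                                   if calibrate else None)
    elif variance != "robust":
        raise ValueError(f"unknown variance {variance!r}")
    return res


def _linearized_variance(res: PoissonRateResults, assignments: pd.DataFrame,
                         aux_sample: np.ndarray | None) -> PoissonRateResults:
    """Design-based variance for the weighted estimator.

    Per-woman weighted scores are residualized on the calibration
    auxiliaries (when raking was used) and the resulting totals get the
    stratified SRSWOR variance with finite-population correction, using
    the phase-2 strata.  The phase-3 stage is absorbed into the weights
    (its extra variability is approximated by the within-stratum spread
    of the weighted residuals).
    """
    ids = res._cluster_ids
    U = res._U  # per-woman weighted scores at beta-hat
    A = res._A
    if aux_sample is not None:
        H = np.column_stack([np.ones(len(ids)), aux_sample])
        # weighted projection of scores on auxiliaries
        coef, *_ = np.linalg.lstsq(H, U, rcond=None)
        E = U - H @ coef
    else:
        E = U
    amap = assignments.set_index("woman_id")
    strata = amap["stratum"].reindex(ids).values
    p1 = amap["p1"].reindex(ids).values
    V = np.zeros((U.shape[1], U.shape[1]))
    for s in pd.unique(strata):
        mask = strata == s
        n_h = int(mask.sum())
        if n_h < 2:
            continue  # single sampled unit: no within-stratum variance estimate
        f_h = float(np.clip(p1[mask][0], 0.0, 1.0))
        Z = E[mask]
        Zc = Z - Z.mean(axis=0, keepdims=True)
        V += (1.0 - f_h) * n_h / (n_h - 1) * (Zc.T @ Zc)
    Ainv = np.linalg.inv(A)
    vcov = Ainv @ V @ Ainv
    vcov = (vcov + vcov.T) / 2.0
    new = PoissonRateResults(
        model=res.model, params=res.params,
        cov=pd.DataFrame(vcov, index=res.params.index, columns=res.params.index),
        influence=res.influence, converged=res.converged, llf=res.llf,
        n_clusters=res.n_clusters, _A=res._A, _U=res._U,
        _cluster_ids=res._cluster_ids, raking=res.raking)
    return new
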