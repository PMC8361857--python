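"""Poisson incidence-rate models with cluster-robust variance, influence
functions, and within-stratum incidence-rate-ratio contrasts.

The model is a log-linear Poisson regression of the per-period pregnancy
indicator with offset log(exposure time):

    log E[Y | x] = log(t) + x' beta

where x contains the contraceptive category, the ART category, their full
interaction (the study question lives in the interaction), and optional
covariates (program, average age and age squared, marital status,
education, any-children indicator, WHO stage, CD4 and sqrt CD4, log BMI
and sqrt log BMI, anti-TB treatment, calendar time).  Nevirapine-containing
ART is the reference ART category.

Maximum (pseudo-)likelihood estimation is delegated to
:class:`statsmodels.api.GLM`; on top of it this module computes the
sandwich covariance A^{-1} B A^{-1} with B built from woman-level
(cluster-summed, weighted) scores, and the per-woman influence functions
A^{-1} score_i that drive the raking calibration.  Because periods from
one woman share unobserved factors, all variances are clustered by woman.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

CONTRACEPTIVE_ORDER = ("NONE", "IMPLANT", "DMPA", "MEC", "OCP", "LEC")
ART_ORDER = ("NVP", "EFV", "PI", "NO_ART", "NRTI_ONLY", "COMBINATION")

#: the full covariate adjustment set of the primary analysis
FULL_COVARIATES = (
    "program", "age", "age_sq", "marital_status", "education", "any_children",
    "who_stage", "cd4", "sqrt_cd4", "log_bmi", "sqrt_log_bmi", "anti_tb",
    "calendar_time",
)

_CATEGORICAL_COVARIATES = {"program", "marital_status", "education", "who_stage"}


@dataclass(frozen=True)
class Contrast:
    """A within-stratum incidence-rate-ratio contrast.

    ``within_factor`` names the stratifying factor (``"contraceptive"`` or
    ``"art"``); the contrast compares ``level_a`` vs ``level_b`` of the
    *other* factor inside stratum ``within_level``.  E.g.
    ``Contrast("contraceptive", "IMPLANT", "EFV", "NVP")`` is the
    efavirenz-vs-nevirapine rate ratio among implant users.
    """

    within_factor: str
    within_level: str
    level_a: str
    level_b: str

    def __post_init__(self):
        if self.within_factor not in ("contraceptive", "art"):
            raise ValueError("within_factor must be 'contraceptive' or 'art'")

    @property
    def label(self) -> str:
        return (f"{self.level_a} vs {self.level_b} | "
                f"{self.within_factor}={self.within_level}")


DEFAULT_CONTRAST = Contrast("contraceptive", "IMPLANT", "EFV", "NVP")


@dataclass
class ModelSpec:
    """What goes into the design matrix and which rows are eligible.

    ``drop_art`` removes rarely-populated ART categories before fitting
    (configurable; PI is retained by default).  Periods with MISSING
    exposure categories are always excluded from fitting.
    """

    contraceptive_ref: str = "NONE"
    art_ref: str = "NVP"
    covariates: tuple = ()
    interaction: bool = True
    drop_art: tuple = ("NRTI_ONLY", "COMBINATION")
    #: with False (default) an empty exposure cell raises a rank-deficiency
    #: error naming the cell; with True the unidentifiable columns are
    #: pruned instead (needed for small validated subsamples, where not
    #: every contraceptive x ART combination is observed)
    drop_empty_cells: bool = False

    @classmethod
    def full(cls, **kw) -> "ModelSpec":
        return cls(covariates=FULL_COVARIATES, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        for k in ("covariates", "drop_art"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _continuous_terms(df: pd.DataFrame, name: str) -> pd.Series:
    if name == "age":
        return df["age"].astype(float)
    if name == "age_sq":
        return df["age"].astype(float) ** 2
    if name == "any_children":
        return (pd.to_numeric(df["n_children"]) > 0).astype(float)
    if name == "cd4":
        return df["cd4"].astype(float)
    if name == "sqrt_cd4":
        return np.sqrt(df["cd4"].astype(float))
    if name == "log_bmi":
        return np.log(df["bmi"].astype(float))
    if name == "sqrt_log_bmi":
        return np.sqrt(np.log(df["bmi"].astype(float)))
    if name == "anti_tb":
        return pd.to_numeric(df["anti_tb"]).astype(float)
    if name == "calendar_time":
        return df["calendar_year"].astype(float) - 2013.0
    raise ValueError(f"unknown covariate term {name!r}")


class _Design:
    """Design-matrix builder shared by fits and contrast construction."""

    def __init__(self, frame: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        self.c_levels = [spec.contraceptive_ref] + [
            c for c in CONTRACEPTIVE_ORDER
            if c != spec.contraceptive_ref and c in set(frame["contraceptive"])]
        self.a_levels = [spec.art_ref] + [
            a for a in ART_ORDER
            if a != spec.art_ref and a in set(frame["art"])]
        self.columns: list[str] = ["intercept"]
        for c in self.c_levels[1:]:
            self.columns.append(f"contraceptive[{c}]")
        for a in self.a_levels[1:]:
            self.columns.append(f"art[{a}]")
        if spec.interaction:
            for c in self.c_levels[1:]:
                for a in self.a_levels[1:]:
                    self.columns.append(f"contraceptive[{c}]:art[{a}]")
        self._cov_cols: list[tuple[str, str]] = []  # (column name, term)
        self._cat_levels: dict[str, list] = {}
        for term in spec.covariates:
            if term in _CATEGORICAL_COVARIATES:
                levels = sorted(pd.unique(frame[term].dropna()), key=str)
                self._cat_levels[term] = levels
                for lvl in levels[1:]:
                    self._cov_cols.append((f"{term}[{lvl}]", term))
            else:
                self._cov_cols.append((term, term))
        self.columns += [c for c, _ in self._cov_cols]

    def matrix(self, frame: pd.DataFrame) -> np.ndarray:
        n = len(frame)
        X = np.zeros((n, len(self.columns)))
        X[:, 0] = 1.0
        j = 1
        c_ind = {}
        for c in self.c_levels[1:]:
            c_ind[c] = (frame["contraceptive"].values == c).astype(float)
            X[:, j] = c_ind[c]
            j += 1
        a_ind = {}
        for a in self.a_levels[1:]:
            a_ind[a] = (frame["art"].values == a).astype(float)
            X[:, j] = a_ind[a]
            j += 1
        if self.spec.interaction:
            for c in self.c_levels[1:]:
                for a in self.a_levels[1:]:
                    X[:, j] = c_ind[c] * a_ind[a]
                    j += 1
        for col, term in self._cov_cols:
            if term in _CATEGORICAL_COVARIATES:
                lvl = col[len(term) + 1:-1]
                vals = frame[term]
                if pd.api.types.is_numeric_dtype(vals):
                    X[:, j] = (vals.astype(float) == float(lvl)).astype(float)
                else:
                    X[:, j] = (vals.astype(str) == lvl).astype(float)
            else:
                v = _continuous_terms(frame, term).values
                if np.any(~np.isfinite(v)):
                    raise ValueError(
                        f"covariate term {term!r} has missing/non-finite values; "
                        "impute first (mice_impute)")
                X[:, j] = v
            j += 1
        return X

    def _factor_row(self, c_level: str, a_level: str) -> np.ndarray:
        """Factor-part design row at covariates = 0 (covariates cancel in
        within-stratum contrasts because they do not interact with the
        exposure factors)."""
        row = np.zeros(len(self.columns))
        row[0] = 1.0
        for j, col in enumerate(self.columns):
            if col == f"contraceptive[{c_level}]" or col == f"art[{a_level}]":
                row[j] = 1.0
            if col == f"contraceptive[{c_level}]:art[{a_level}]":
                row[j] = 1.0
        return row

    def contrast_vector(self, contrast: Contrast) -> np.ndarray:
        if contrast.within_factor == "contraceptive":
            c = contrast.within_level
            for lvl in (c,):
                if lvl not in self.c_levels:
                    raise ValueError(f"unknown contraceptive level {lvl!r}")
            for lvl in (contrast.level_a, contrast.level_b):
                if lvl not in self.a_levels:
                    raise ValueError(f"unknown ART level {lvl!r}")
            return self._factor_row(c, contrast.level_a) - self._factor_row(c, contrast.level_b)
        a = contrast.within_level
        if a not in self.a_levels:
            raise ValueError(f"unknown ART level {a!r}")
        for lvl in (contrast.level_a, contrast.level_b):
            if lvl not in self.c_levels:
                raise ValueError(f"unknown contraceptive level {lvl!r}")
        return self._factor_row(contrast.level_a, a) - self._factor_row(contrast.level_b, a)


class PoissonRateModel:
    """Log-linear pregnancy-incidence model on observation periods.

    Parameters
    ----------
    periods
        Observation-period table from :func:`threephase.cohort.code_cohort`
        (columns ``woman_id``, ``contraceptive``, ``art``, ``pregnancy``,
        ``exposure_time``, plus any covariates the spec uses).
    spec
        A :class:`ModelSpec`; default is the interaction model without
        covariates.
    weights
        Optional per-woman weights (Series indexed by woman_id) or a
        per-period array; omitted means 1.  All weights must be positive.
    """

    def __init__(self, periods: pd.DataFrame, spec: ModelSpec | None = None,
                 weights=None):
        self.spec = spec or ModelSpec()
        frame = periods
        frame = frame[~frame["contraceptive"].eq("MISSING")
                      & ~frame["art"].eq("MISSING")
                      & ~frame["art"].isin(self.spec.drop_art)]
        frame = frame[frame["exposure_time"] > 0]
        if len(frame) == 0:
            raise ValueError("no usable observation periods")
        self.frame = frame.reset_index(drop=True)
        self.design = _Design(self.frame, self.spec)
        self.exog = self.design.matrix(self.frame)
        self.columns = list(self.design.columns)
        self._kept = np.arange(self.exog.shape[1])
        self.endog = self.frame["pregnancy"].astype(float).values
        self._check_cells()
        if self.spec.drop_empty_cells:
            self._prune_columns()
        self.offset = np.log(self.frame["exposure_time"].astype(float).values)
        self.groups = self.frame["woman_id"].values
        if weights is None:
            self.weights = np.ones(len(self.frame))
        elif isinstance(weights, pd.Series):
            w = self.frame["woman_id"].map(weights)
            if w.isna().any():
                missing = self.frame.loc[w.isna(), "woman_id"].unique()
                raise ValueError(f"no weight for women {missing[:5].tolist()}")
            self.weights = w.astype(float).values
        else:
            self.weights = np.asarray(weights, dtype=float)
            if len(self.weights) != len(self.frame):
                raise ValueError("per-period weights length mismatch")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    @classmethod
    def from_coded(cls, cohort, spec=None, weights=None) -> "PoissonRateModel":
        return cls(cohort.periods, spec=spec, weights=weights)

    def _check_cells(self):
        if self.spec.drop_empty_cells:
            return
        sums = self.exog.sum(axis=0)
        empty = [self.design.columns[j] for j in range(len(sums))
                 if sums[j] == 0 and ":" in self.design.columns[j]]
        # all-zero interaction columns make the model rank deficient
        if empty:
            raise ValueError(f"empty exposure cell(s): {empty}")

    def _prune_columns(self):
        """Drop inestimable and collinear design columns.

        A factor column with person-time but zero events pushes its
        coefficient to minus infinity (and wrecks the influence
        functions), so it is dropped along with all-zero and collinear
        columns (pivoted QR)."""
        from scipy.linalg import qr as _qr
        events = self.endog @ self.exog
        estimable = np.array(
            [events[j] > 0 or not ("contraceptive[" in c or "art[" in c)
             for j, c in enumerate(self.columns)])
        nz = np.flatnonzero((self.exog.sum(axis=0) != 0) & estimable)
        X = self.exog[:, nz]
        _q, r, piv = _qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        rank = int(np.sum(diag > 1e-10 * max(diag[0], 1e-300)))
        keep = nz[np.sort(piv[:rank])]
        if len(keep) < self.exog.shape[1]:
            dropped = [self.columns[j] for j in range(self.exog.shape[1])
                       if j not in set(keep.tolist())]
            logger.info("pruning %d unidentifiable design column(s): %s",
                        len(dropped), dropped)
        self._kept = keep
        self.exog = self.exog[:, keep]
        self.columns = [self.columns[j] for j in keep]

    def fit(self, maxiter: int = 100, tol: float = 1e-10) -> "PoissonRateResults":
        glm = sm.GLM(self.endog, self.exog, family=sm.families.Poisson(),
                     offset=self.offset, var_weights=self.weights)
        res = glm.fit(maxiter=maxiter, tol=tol)
        beta = np.asarray(res.params)
        mu = np.asarray(res.mu)
        w = self.weights
        X = self.exog
        score_obs = (w * (self.endog - mu))[:, None] * X
        A = X.T @ (X * (w * mu)[:, None])
        codes, uniques = pd.factorize(self.groups)
        U = np.zeros((len(uniques), X.shape[1]))
        np.add.at(U, codes, score_obs)
        G = len(uniques)
        ssc = G / max(G - 1, 1)
        B = ssc * (U.T @ U)
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError as err:
            raise ValueError("singular information matrix (empty factor cell "
                             "or collinear covariates)") from err
        vcov = Ainv @ B @ Ainv
        vcov = (vcov + vcov.T) / 2.0
        influence = pd.DataFrame(U @ Ainv.T, index=pd.Index(uniques, name="woman_id"),
                                 columns=self.columns)
        return PoissonRateResults(
            model=self, params=pd.Series(beta, index=self.columns),
            cov=pd.DataFrame(vcov, index=self.columns,
                             columns=self.columns),
            influence=influence, converged=bool(res.converged),
            llf=float(res.llf), n_clusters=G, _A=A, _U=U,
            _cluster_ids=np.asarray(uniques))


def _irr_table(params: pd.Series, cov: pd.DataFrame, design: _Design,
               contrasts) -> pd.DataFrame:
    rows = []
    beta = params.values
    V = cov.values
    col_pos = {c: j for j, c in enumerate(design.columns)}
    kept = [col_pos[c] for c in params.index]
    kept_set = set(kept)
    for ct in contrasts:
        c_full = design.contrast_vector(ct)
        bad = [design.columns[j] for j in np.flatnonzero(c_full)
               if j not in kept_set]
        if bad:
            raise ValueError(
                f"contrast {ct.label!r} involves unidentified cell(s) {bad}")
        c = c_full[kept]
        est = float(c @ beta)
        var = float(c @ V @ c)
        se = np.sqrt(max(var, 0.0))
        rows.append({
            "stratum": f"{ct.within_factor}={ct.within_level}",
            "contrast": f"{ct.level_a} vs {ct.level_b}",
            "log_irr": est, "se_log_irr": se, "irr": np.exp(est),
            "ci_low": np.exp(est - 1.96 * se), "ci_high": np.exp(est + 1.96 * se),
        })
    return pd.DataFrame(rows)


@dataclass
class PoissonRateResults:
    """Fit results: coefficients, cluster-robust covariance, influence.

    ``influence`` holds one row per woman: A^{-1} times her summed score
    contributions; rows sum to ~0 at the MLE (the score identity) and are
    the auxiliaries used for raking calibration.
    """

    model: PoissonRateModel
    params: pd.Series
    cov: pd.DataFrame
    influence: pd.DataFrame
    converged: bool
    llf: float
    n_clusters: int
    _A: np.ndarray = field(repr=False, default=None)
    _U: np.ndarray = field(repr=False, default=None)
    _cluster_ids: np.ndarray = field(repr=False, default=None)
    raking: object = None

    @property
    def bse(self) -> pd.Series:
        d = np.clip(np.diag(self.cov.values), 0.0, None)
        return pd.Series(np.sqrt(d), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def irr_contrasts(self, contrasts=(DEFAULT_CONTRAST,)) -> pd.DataFrame:
        """Adjusted incidence-rate-ratio table for within-stratum contrasts."""
        return _irr_table(self.params, self.cov, self.model.design, contrasts)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Poisson incidence-rate model (offset log women-years)",
            f"periods: {len(self.model.frame)}   women (clusters): {self.n_clusters}"
            f"   converged: {self.converged}   loglik: {self.llf:.2f}",
            "variance: sandwich, clustered by woman",
            "-" * 78,
            f"{'term':<34}{'coef':>10}{'se':>9}{'IRR':>9}{'[95% CI]':>16}",
        ]
        for name in self.params.index:
            b = self.params[name]
            lines.append(
                f"{name:<34}{b:>10.4f}{self.bse[name]:>9.4f}{np.exp(b):>9.3f}"
                f"   [{np.exp(ci.loc[name, 'lower']):>6.3f}, "
                f"{np.exp(ci.loc[name, 'upper']):>6.3f}]")
        return "\n".join(lines)


def fit_poisson_robust(periods: pd.DataFrame, spec: ModelSpec | None = None,
                       weights=None, **fit_kw) -> PoissonRateResults:
    """Fit the interaction Poisson model with woman-clustered sandwich
    variance (convenience wrapper around :class:`PoissonRateModel`)."""
    return PoissonRateModel(periods, spec=spec, weights=weights).fit(**fit_kw)
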