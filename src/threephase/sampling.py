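"""Phase-2 stratified chart sampling, phase-3 priority interview sampling,
inclusion-probability estimation, and cross-phase record reconciliation.

Phase 1 is the routine EMR itself.  Phase 2 draws a stratified random
subsample of women for manual chart review over the 32 cells formed by
contraceptive category (implant, DMPA, MEC, none) x ART category
(efavirenz, nevirapine, PI, no ART) x pregnancy status, with
over-sampling of cells of interest; the phase-2 inclusion probability
``p1`` is estimated empirically as the realized sampling fraction per
stratum.  Phase 3 selects chart-reviewed women for telephone interview
in a fixed priority order (pregnant implant users first), subject to a
budget and to phone reachability; the phase-3 probability ``p2`` is
estimated by logistic regression on the priority categories.

Sampling units are women, not observation periods, because charts and
interviews are per woman; a woman whose periods span several cells is
assigned to her rarest cell (configurable).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GRID_CONTRACEPTIVES = ("IMPLANT", "DMPA", "MEC", "NONE")
GRID_ARTS = ("EFV", "NVP", "PI", "NO_ART")
OTHER_STRATUM = "OTHER"

P2_FLOOR = 1e-3  # probability floor bounding interview weights

DEFAULT_PRIORITY = ("pregnant-implant", "nonpregnant-implant",
                    "pregnant-dmpa", "nonpregnant-dmpa", "other")


def stratum_label(contraceptive: str, art: str, pregnant: int) -> str:
    return f"{contraceptive}|{art}|{int(pregnant)}"


def all_strata() -> list[str]:
    """The 32 contraceptive x ART x pregnancy validation cells."""
    return [stratum_label(c, a, p)
            for c in GRID_CONTRACEPTIVES for a in GRID_ARTS for p in (0, 1)]


def priority_category(stratum: str) -> str:
    if stratum == OTHER_STRATUM:
        return "other"
    c, _a, p = stratum.split("|")
    if c == "IMPLANT":
        return "pregnant-implant" if p == "1" else "nonpregnant-implant"
    if c == "DMPA":
        return "pregnant-dmpa" if p == "1" else "nonpregnant-dmpa"
    return "other"


@dataclass
class SamplingDesign:
    """Phase-2 targets, phase-3 priority order and budget.

    ``phase2_targets`` maps stratum labels (``"IMPLANT|EFV|1"`` or
    ``"OTHER"``) to either a sampling fraction (float < 1 or 1.0) or an
    integer count; unlisted strata fall back to ``default_fraction``.
    """

    phase2_targets: dict = field(default_factory=dict)
    default_fraction: float = 0.02
    phase3_priority: tuple = DEFAULT_PRIORITY
    phase3_budget: int = 72
    seed: int = 0

    def target_for(self, stratum: str, size: int) -> int:
        t = self.phase2_targets.get(stratum, self.default_fraction)
        if isinstance(t, float) and t <= 1.0:
            # ceil so a non-empty stratum with a positive fraction always
            # contributes at least one chart (keeps weights defined)
            n = int(np.ceil(t * size)) if t > 0 else 0
        else:
            n = int(t)
        if n > size:
            logger.warning("stratum %s target %d capped at size %d", stratum, n, size)
            n = size
        return n

    @classmethod
    def default(cls, seed: int = 0) -> "SamplingDesign":
        """A chart-review design over-sampling (pregnant) implant users,
        validating roughly 6% of women under the default generator."""
        targets = {}
        for c in GRID_CONTRACEPTIVES:
            for a in GRID_ARTS:
                for p in (0, 1):
                    if c == "IMPLANT" and p == 1:
                        f = 0.5
                    elif c == "IMPLANT":
                        f = 0.06
                    elif c == "DMPA" and p == 1:
                        f = 0.15
                    elif p == 1:
                        f = 0.08
                    elif c == "DMPA":
                        f = 0.03
                    else:
                        f = 0.02
                    targets[stratum_label(c, a, p)] = f
        targets[OTHER_STRATUM] = 0.01
        return cls(phase2_targets=targets, phase3_budget=72, seed=seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SamplingDesign":
        d = dict(d)
        if "phase3_priority" in d:
            d["phase3_priority"] = tuple(d["phase3_priority"])
        return cls(**d)


def assign_strata(periods: pd.DataFrame,
                  grid_contraceptives=GRID_CONTRACEPTIVES,
                  grid_arts=GRID_ARTS,
                  rule: str = "cohort_rarest") -> pd.DataFrame:
    """Map each woman to one of the 32 validation cells (or OTHER).

    A woman's candidate cells are the (contraceptive, ART) combinations of
    her periods inside the 4 x 4 grid, with the pregnancy flag marking
    whether she became pregnant under that combination.  Under the default
    ``cohort_rarest`` rule she is assigned to the candidate cell held by
    the fewest women in the cohort (ties broken toward pregnancy cells,
    then by grid order), so rare exposure-outcome combinations stay
    visible to the sampler.  Women with no period in the grid get OTHER.
    """
    if rule != "cohort_rarest":
        raise ValueError(f"unknown stratum rule {rule!r}")
    p = periods[periods["contraceptive"].isin(grid_contraceptives)
                & periods["art"].isin(grid_arts)]
    everyone = pd.Index(periods["woman_id"].unique(), name="woman_id")
    if len(p) == 0:
        out = pd.DataFrame({"woman_id": everyone, "stratum": OTHER_STRATUM})
    else:
        cand = (p.groupby(["woman_id", "contraceptive", "art"], observed=True)["pregnancy"]
                .max().reset_index().rename(columns={"pregnancy": "pregnant"}))
        freq = (cand.groupby(["contraceptive", "art", "pregnant"], observed=True)
                .size().rename("freq").reset_index())
        cand = cand.merge(freq, on=["contraceptive", "art", "pregnant"])
        c_order = {c: i for i, c in enumerate(grid_contraceptives)}
        a_order = {a: i for i, a in enumerate(grid_arts)}
        cand["_c"] = cand["contraceptive"].map(c_order)
        cand["_a"] = cand["art"].map(a_order)
        cand = cand.sort_values(
            ["woman_id", "freq", "pregnant", "_c", "_a"],
            ascending=[True, True, False, True, True], kind="mergesort")
        best = cand.drop_duplicates("woman_id", keep="first")
        out = pd.DataFrame({"woman_id": best["woman_id"].values,
                            "stratum": [stratum_label(c, a, pr) for c, a, pr in
                                        zip(best["contraceptive"], best["art"],
                                            best["pregnant"])]})
        missing = everyone.difference(out["woman_id"])
        if len(missing):
            out = pd.concat([out, pd.DataFrame({"woman_id": missing,
                                                "stratum": OTHER_STRATUM})],
                            ignore_index=True)
    out["priority_category"] = out["stratum"].map(priority_category)
    return out.sort_values("woman_id", kind="mergesort").reset_index(drop=True)


def _rng(seed_or_rng):
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sample_phase2(strata: pd.DataFrame, design: SamplingDesign,
                  seed=None) -> pd.DataFrame:
    """Simple random sampling without replacement within each stratum.

    Returns an assignments table with ``sampled_phase2`` flags and the
    empirically realized inclusion probability ``p1`` (sampled / size) for
    every woman.  Strata sampled at zero are flagged: their members have
    ``p1 = 0`` and are excluded from weighted analyses.
    """
    rng = _rng(design.seed if seed is None else seed)
    out = strata.sort_values("woman_id", kind="mergesort").reset_index(drop=True).copy()
    out["sampled_phase2"] = False
    out["p1"] = 0.0
    for stratum in sorted(out["stratum"].unique()):
        idx = out.index[out["stratum"] == stratum].values
        n_target = design.target_for(stratum, len(idx))
        if n_target == 0:
            if len(idx):
                logger.warning("stratum %s sampled 0 of %d: weights undefined, "
                               "excluded from weighted analyses", stratum, len(idx))
            continue
        pick = rng.permutation(len(idx))[:n_target]
        out.loc[idx[pick], "sampled_phase2"] = True
        out.loc[idx, "p1"] = n_target / len(idx)
    return out


def sample_phase3(assignments: pd.DataFrame, design: SamplingDesign,
                  reachable=None, seed=None) -> pd.DataFrame:
    """Select interviewees among chart-reviewed women in priority order.

    Women are taken category by category following
    ``design.phase3_priority`` until the budget is exhausted; within a
    category the order is random.  ``reachable`` (a bool Series indexed by
    woman_id, or None for everyone) models having a working phone number.
    """
    rng = _rng(design.seed + 1 if seed is None else seed)
    out = assignments.copy()
    out["sampled_phase3"] = False
    pool = out[out["sampled_phase2"]]
    if reachable is not None:
        ok = pool["woman_id"].map(reachable).fillna(False).astype(bool)
        pool = pool[ok.values]
    budget = int(design.phase3_budget)
    cats = list(design.phase3_priority)
    for c in pool["priority_category"].unique():
        if c not in cats:
            cats.append(c)
    for cat in cats:
        if budget <= 0:
            break
        members = pool.index[pool["priority_category"] == cat].values
        if len(members) == 0:
            continue
        take = rng.permutation(len(members))[:budget]
        out.loc[members[take], "sampled_phase3"] = True
        budget -= len(take)
    return out


def fit_p2_model(assignments: pd.DataFrame, floor: float = P2_FLOOR) -> pd.DataFrame:
    """Estimate the phase-3 inclusion probability p2 among phase-2 women.

    Logistic regression of interview selection on the priority-category
    indicators (a saturated model); on separation or non-convergence the
    empirical per-category selection fractions are used instead.  Fitted
    probabilities are clipped to ``[floor, 1]`` and attached as ``p2``.
    """
    import statsmodels.api as sm

    out = assignments.copy()
    sub = out[out["sampled_phase2"]]
    if len(sub) == 0 or not sub["sampled_phase3"].any() or sub["sampled_phase3"].all():
        raise ValueError("p2 model needs at least one selected and one "
                         "non-selected phase-2 woman")
    y = sub["sampled_phase3"].astype(float).values
    X = pd.get_dummies(sub["priority_category"], dtype=float)
    empirical = sub.groupby("priority_category")["sampled_phase3"].mean()
    fitted = None
    try:
        res = sm.GLM(y, X.values, family=sm.families.Binomial()).fit(maxiter=100)
        if res.converged and np.all(np.isfinite(res.params)):
            fitted = pd.Series(res.predict(X.values), index=sub.index)
    except Exception:  # separation and friends
        fitted = None
    if fitted is None:
        logger.warning("p2 logistic model failed (separation?); using empirical "
                       "category fractions")
        fitted = sub["priority_category"].map(empirical)
    out["p2"] = np.nan
    out.loc[sub.index, "p2"] = np.clip(fitted.values, floor, 1.0)
    return out


def compute_weights(assignments: pd.DataFrame, phase: str = "chart") -> pd.Series:
    """Design weights 1/p1 (chart phase) or 1/(p1*p2) (interview phase),
    indexed by woman_id, for the women validated in that phase."""
    if phase == "chart":
        sub = assignments[assignments["sampled_phase2"] & (assignments["p1"] > 0)]
        w = 1.0 / sub["p1"]
    elif phase == "interview":
        if "p2" not in assignments.columns:
            raise ValueError("run fit_p2_model before interview weights")
        sub = assignments[assignments["sampled_phase3"] & (assignments["p1"] > 0)]
        w = 1.0 / (sub["p1"] * sub["p2"])
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return pd.Series(w.values, index=sub["woman_id"].values, name="weight")


_VALIDATED_FIELDS = ("contraceptive_codes", "art_drugs", "preg_reported",
                     "lmp_date", "gest_age_weeks", "edd_date")
_OPTIONAL_FIELDS = ("outcome", "outcome_date")


def reconcile(emr_visits: pd.DataFrame, chart_visits: pd.DataFrame,
              interview_visits: pd.DataFrame | None = None) -> pd.DataFrame:
    """Merge the validation phases into one best-value visits table.

    Precedence is interview > chart (> EMR), except that an ART value the
    interviewee could not recall (the ``"unsure"`` sentinel) falls back to
    the chart value.  Only the primary exposures and the pregnancy outcome
    are validated; covariates ride along from the chart rows.  Validated
    observation time outside each woman's EMR window (first to last EMR
    visit) is trimmed.  The output carries per-variable ``*_source``
    columns and is meant to be re-coded with
    :func:`threephase.cohort.code_cohort` so corrected exposures redefine
    period boundaries.

    Raises if an interview woman has no chart review (the three phases
    must nest).
    """
    out = chart_visits.copy()
    out["contraceptive_source"] = "CHART"
    out["art_source"] = "CHART"
    out["pregnancy_source"] = "CHART"

    if interview_visits is not None and len(interview_visits):
        extra = set(interview_visits["woman_id"]) - set(chart_visits["woman_id"])
        if extra:
            raise ValueError(
                f"interview records without matching chart review (3-phase "
                f"nesting violated): {sorted(extra)[:5]}")
        fields = [f for f in _VALIDATED_FIELDS + _OPTIONAL_FIELDS
                  if f in interview_visits.columns]
        iv = interview_visits[["woman_id", "visit_date", *fields]].copy()
        iv.columns = ["woman_id", "visit_date"] + [f"{f}__iv" for f in fields]
        out = out.merge(iv, on=["woman_id", "visit_date"], how="left", indicator=True)
        hit = out["_merge"] == "both"
        for f in fields:
            col = f"{f}__iv"
            if f == "art_drugs":
                unsure = hit & (out[col].astype(str) == "unsure")
                take = hit & ~unsure
                out.loc[take, "art_drugs"] = out.loc[take, col]
                out.loc[take, "art_source"] = "INTERVIEW"
                # unsure: keep chart value, source stays CHART
            else:
                out.loc[hit, f] = out.loc[hit, col]
        out.loc[hit, "contraceptive_source"] = "INTERVIEW"
        out.loc[hit, "pregnancy_source"] = "INTERVIEW"
        out = out.drop(columns=[f"{f}__iv" for f in fields] + ["_merge"])

    # trim observation time outside the EMR window
    emr_days = pd.to_datetime(emr_visits["visit_date"])
    win = emr_days.groupby(emr_visits["woman_id"].values).agg(["min", "max"])
    d = pd.to_datetime(out["visit_date"])
    lo = out["woman_id"].map(win["min"])
    hi = out["woman_id"].map(win["max"])
    keep = d.notna() & lo.notna() & (d >= lo) & (d <= hi)
    n_trim = int((~keep).sum())
    if n_trim:
        logger.info("trimmed %d validated visit(s) outside the EMR window", n_trim)
    return out[keep.values].reset_index(drop=True)
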