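"""Coding of visit-level clinic records into analyzable observation periods.

The analysis unit for pregnancy-incidence estimation is the *observation
period*: a maximal half-open interval ``[start, end)`` within one woman's
follow-up over which her contraceptive category, her ART category, and her
pregnancy status are all constant.  Periods are cut wherever any of the
three change; a period that ends at an estimated conception date carries
``pregnancy = 1``, after which the woman is censored (not at risk) for the
duration of the pregnancy and then re-enters risk time.

Contraceptive methods recorded at a visit are collapsed to a single
category by an effectiveness hierarchy (MEC > implants > DMPA > OCPs >
LEC); ART drug lists are collapsed by anchor class (efavirenz, nevirapine,
protease inhibitors), with an "ART regimen" requiring at least three
drugs.  Conception dates are back-dated from the last menstrual period,
the reported gestational age, or the expected delivery date, in that
order of precedence.

Conventions: half-open day-resolution intervals, years = days / 365.25,
and a new exposure value takes effect on its visit date.
"""
from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# -- category vocabularies ---------------------------------------------------

CONTRACEPTIVE_CATEGORIES = ("MEC", "IMPLANT", "DMPA", "OCP", "LEC", "NONE", "MISSING")
ART_CATEGORIES = ("EFV", "NVP", "PI", "NRTI_ONLY", "COMBINATION", "NO_ART", "MISSING")

#: effectiveness hierarchy, most effective first
CONTRACEPTIVE_HIERARCHY = ("MEC", "IMPLANT", "DMPA", "OCP", "LEC")

_METHOD_TO_CATEGORY = {
    "iud": "MEC",
    "permanent": "MEC",
    "implant_etg": "IMPLANT",
    "implant_lng": "IMPLANT",
    "implant_unknown": "IMPLANT",
    "dmpa": "DMPA",
    "ocp": "OCP",
    "condom": "LEC",
    "natural": "LEC",
    "none": "NONE",
}

EFV_DRUGS = frozenset({"efavirenz"})
NVP_DRUGS = frozenset({"nevirapine"})
PI_DRUGS = frozenset(
    {"lopinavir_r", "atazanavir_r", "darunavir_r", "nelfinavir", "indinavir", "saquinavir"}
)
NRTI_DRUGS = frozenset(
    {"tenofovir", "lamivudine", "zidovudine", "abacavir", "emtricitabine", "stavudine", "didanosine"}
)

OVULATION_OFFSET_DAYS = 14   # LMP -> conception
EDD_OFFSET_DAYS = 266        # conception -> term delivery (38 weeks)
PREGNANCY_CENSOR_DAYS = 266  # fixed not-at-risk window after conception
DAYS_PER_YEAR = 365.25
LOOK_AHEAD_DAYS = 274        # pregnancies reported up to ~9 months past study end

#: covariate columns carried from visits onto periods when present
COVARIATE_COLUMNS = (
    "program", "age", "marital_status", "education", "n_children",
    "who_stage", "cd4", "weight_kg", "bmi", "anti_tb",
)

_EPOCH_YEAR = 1970.0
_MEAN_YEAR_DAYS = 365.2425


def _as_code_set(codes) -> frozenset:
    """Normalize a code field (set, iterable, or ';'-joined string) to a frozenset."""
    if codes is None:
        return frozenset()
    if isinstance(codes, float) and np.isnan(codes):
        return frozenset()
    if isinstance(codes, str):
        return frozenset(c.strip() for c in codes.split(";") if c.strip())
    return frozenset(str(c) for c in codes if str(c))


def assign_contraceptive_category(codes) -> str:
    """Collapse the contraceptive methods recorded at one visit to a category.

    When several methods are documented the most effective wins:
    MEC > IMPLANT > DMPA > OCP > LEC.  An empty record means NONE;
    a record containing only unrecognized labels maps to MISSING.
    """
    s = _as_code_set(codes)
    if not s:
        return "NONE"
    unknown = {c for c in s if c not in _METHOD_TO_CATEGORY}
    if unknown:
        logger.warning("unrecognized contraceptive code(s) %s ignored", sorted(unknown))
    cats = {_METHOD_TO_CATEGORY[c] for c in s - unknown}
    for cat in CONTRACEPTIVE_HIERARCHY:
        if cat in cats:
            return cat
    if "NONE" in cats:
        return "NONE"
    return "MISSING"


def assign_art_category(drugs) -> str:
    """Collapse an antiretroviral drug list to an ART regimen category.

    An ART regimen requires at least a three-drug combination.  Regimens
    containing exactly one of the anchor classes (efavirenz, nevirapine,
    protease inhibitor) take that class; two or more anchors ->
    COMBINATION; three or more NRTIs alone -> NRTI_ONLY.  An empty list
    is NO_ART; fewer than three drugs is not assumed to be NO_ART and is
    coded MISSING.
    """
    s = _as_code_set(drugs)
    if not s:
        return "NO_ART"
    if len(s) < 3:
        return "MISSING"
    anchors = [name for name, cls in (("EFV", EFV_DRUGS), ("NVP", NVP_DRUGS), ("PI", PI_DRUGS))
               if s & cls]
    if len(anchors) >= 2:
        return "COMBINATION"
    if len(anchors) == 1:
        return anchors[0]
    if s <= NRTI_DRUGS:
        return "NRTI_ONLY"
    logger.warning("unrecognized antiretroviral drug(s) %s", sorted(s - NRTI_DRUGS))
    return "MISSING"


class ConceptionDatingError(ValueError):
    """Raised when a pregnancy report carries no usable dating information."""


def estimate_conception_date(report, report_date) -> pd.Timestamp:
    """Back-date the likely conception from a pregnancy report.

    Precedence: last menstrual period (+14 days to ovulation) over
    gestational age (report date - weeks*7 + 14) over expected delivery
    date (-266 days).  The result is clamped to the report date.  When
    available sources disagree by more than 30 days a warning is logged.
    """
    report_date = pd.Timestamp(report_date)
    lmp = report.get("lmp_date")
    ga = report.get("gest_age_weeks")
    edd = report.get("edd_date")
    candidates = {}
    if lmp is not None and not pd.isna(lmp):
        candidates["lmp"] = pd.Timestamp(lmp) + pd.Timedelta(days=OVULATION_OFFSET_DAYS)
    if ga is not None and not pd.isna(ga):
        candidates["gest_age"] = report_date - pd.Timedelta(days=round(float(ga) * 7)) \
            + pd.Timedelta(days=OVULATION_OFFSET_DAYS)
    if edd is not None and not pd.isna(edd):
        candidates["edd"] = pd.Timestamp(edd) - pd.Timedelta(days=EDD_OFFSET_DAYS)
    if not candidates:
        raise ConceptionDatingError(
            f"pregnancy report on {report_date.date()} (woman "
            f"{report.get('woman_id', '?')}) has no LMP, gestational age, or EDD"
        )
    if len(candidates) > 1:
        days = [c.value // 86_400_000_000_000 for c in candidates.values()]
        if max(days) - min(days) > 30:
            logger.warning(
                "conception dating sources diverge by %d days on %s",
                max(days) - min(days), report_date.date(),
            )
    for source in ("lmp", "gest_age", "edd"):
        if source in candidates:
            return min(candidates[source], report_date)
    raise AssertionError("unreachable")


# -- segmentation ------------------------------------------------------------

@dataclass
class CodedCohort:
    """Observation periods plus bookkeeping for one coded data source."""

    periods: pd.DataFrame
    provenance: str
    women_count: int
    total_women_years: float

    def __repr__(self):  # pragma: no cover - cosmetic
        return (f"CodedCohort(provenance={self.provenance!r}, women={self.women_count}, "
                f"periods={len(self.periods)}, women_years={self.total_women_years:.1f})")


def _segment_woman(vdays, cat_c, cat_a, conceptions, censor_ends, obs_end):
    """Segment one woman's observation time (integer days).

    ``vdays`` are strictly increasing visit days with per-visit categories
    ``cat_c``/``cat_a``; ``conceptions``/``censor_ends`` are paired lists of
    candidate pregnancy events.  Returns ``(periods, n_dropped_pre)`` where
    each period is ``(start, end, c, a, preg, conception, snap_local_idx)``
    and ``n_dropped_pre`` counts conceptions dated before the first visit.
    """
    start = vdays[0]
    # exposure change points (value takes effect on its visit day)
    ch_days = [start]
    ch_c = [cat_c[0]]
    ch_a = [cat_a[0]]
    for k in range(1, len(vdays)):
        if cat_c[k] != ch_c[-1] or cat_a[k] != ch_a[-1]:
            ch_days.append(vdays[k])
            ch_c.append(cat_c[k])
            ch_a.append(cat_a[k])

    # clean conception events: sorted, inside [start, obs_end), outside
    # prior censor windows
    kept = []
    dropped_pre = 0
    order = sorted(range(len(conceptions)), key=lambda i: conceptions[i])
    for i in order:
        d, ce = conceptions[i], censor_ends[i]
        if d <= start:
            dropped_pre += 1
            continue
        if d >= obs_end:
            continue
        if kept and d < kept[-1][1]:
            continue  # reported again within a prior pregnancy window
        kept.append((d, max(ce, d + 1)))

    cuts = set(ch_days[1:])
    cuts.update(d for d, _ in kept)
    cuts.update(min(ce, obs_end) for _, ce in kept)
    cuts.add(obs_end)
    conc_at = {d: d for d, _ in kept}

    periods = []
    prev = start
    for cut in sorted(cuts):
        if cut <= prev:
            continue
        s, e = prev, cut
        prev = cut
        if s >= obs_end:
            break
        if any(d <= s < ce for d, ce in kept):
            continue  # inside a pregnancy censor window: not at risk
        j = bisect_right(ch_days, s) - 1
        preg = 1 if e in conc_at else 0
        snap = bisect_right(vdays, s) - 1
        periods.append((s, e, ch_c[j], ch_a[j], preg, e if preg else None, snap))
    return periods, dropped_pre


def _day_ints(dates) -> np.ndarray:
    return pd.to_datetime(dates).values.astype("datetime64[D]").astype(np.int64)


def _categorize_column(values, func) -> np.ndarray:
    """Apply a coding function over the unique raw values of a column."""
    vals = pd.Series(values).fillna("").astype(str)
    uniq = vals.unique()
    mapping = {u: func(u) for u in uniq}
    return vals.map(mapping).values


def code_cohort(
    visits: pd.DataFrame,
    censor_rule: str = "FIXED_38_WEEKS",
    study_end=None,
    look_ahead_days: int = LOOK_AHEAD_DAYS,
    provenance: str = "EMR",
) -> CodedCohort:
    """Convert a visits table into a :class:`CodedCohort` of observation periods.

    Parameters
    ----------
    visits
        One row per clinic encounter with at least ``woman_id``,
        ``visit_date``, ``contraceptive_codes`` and ``art_drugs``; optional
        pregnancy-report columns (``preg_reported``, ``lmp_date``,
        ``gest_age_weeks``, ``edd_date``, ``outcome``, ``outcome_date``) and
        covariates.
    censor_rule
        ``"FIXED_38_WEEKS"`` censors 266 days from conception;
        ``"OUTCOME_RECORDS"`` censors until the recorded pregnancy-outcome
        date when present (falling back to 266 days).
    study_end
        Administrative end of observation.  Visits after it contribute
        pregnancy reports only (within ``look_ahead_days``), never
        exposure time.  Default: the last visit date in the table.

    Women with fewer than two visits on or before ``study_end`` contribute
    no person-time and yield no periods.
    """
    if censor_rule not in ("FIXED_38_WEEKS", "OUTCOME_RECORDS"):
        raise ValueError(f"unknown censor_rule {censor_rule!r}")
    df = visits.copy()
    df["_day"] = _day_ints(df["visit_date"])
    end_day = int(df["_day"].max()) if study_end is None else int(_day_ints([study_end])[0])
    df = df[df["_day"] <= end_day + look_ahead_days]
    df = df.sort_values(["woman_id", "_day"], kind="mergesort")
    df = df.drop_duplicates(subset=["woman_id", "_day"], keep="last").reset_index(drop=True)

    df["_cat_c"] = _categorize_column(df.get("contraceptive_codes"), assign_contraceptive_category)
    df["_cat_a"] = _categorize_column(df.get("art_drugs"), assign_art_category)

    # conception / censor-window end per reported pregnancy
    conc = np.full(len(df), -1, dtype=np.int64)
    cens = np.full(len(df), -1, dtype=np.int64)
    if "preg_reported" in df.columns:
        rep = df["preg_reported"].fillna(0).astype(float).astype(int).values == 1
        if rep.any():
            sub = df.loc[rep]
            lmp = _nullable_days(sub.get("lmp_date"), len(sub))
            edd = _nullable_days(sub.get("edd_date"), len(sub))
            ga = pd.to_numeric(sub["gest_age_weeks"], errors="coerce").values \
                if "gest_age_weeks" in sub.columns else np.full(len(sub), np.nan)
            rday = sub["_day"].values
            c = np.where(
                ~np.isnan(lmp), lmp + OVULATION_OFFSET_DAYS,
                np.where(~np.isnan(ga), rday - np.round(ga * 7) + OVULATION_OFFSET_DAYS,
                         np.where(~np.isnan(edd), edd - EDD_OFFSET_DAYS, np.nan)))
            undatable = np.isnan(c)
            if undatable.any():
                bad = sub.loc[undatable, ["woman_id", "visit_date"]].iloc[0]
                raise ConceptionDatingError(
                    f"pregnancy report without LMP/gestational-age/EDD for woman "
                    f"{bad['woman_id']} at visit {bad['visit_date']}"
                )
            c = np.minimum(c, rday).astype(np.int64)
            ce = c + PREGNANCY_CENSOR_DAYS
            if censor_rule == "OUTCOME_RECORDS" and "outcome_date" in sub.columns:
                od = _nullable_days(sub["outcome_date"], len(sub))
                ce = np.where(~np.isnan(od), od, ce).astype(np.int64)
            conc[np.flatnonzero(rep)] = c
            cens[np.flatnonzero(rep)] = ce

    woman_codes, woman_index = pd.factorize(df["woman_id"])
    days = df["_day"].values
    cat_c = df["_cat_c"].values
    cat_a = df["_cat_a"].values
    bounds = np.searchsorted(woman_codes, np.arange(len(woman_index) + 1))

    rows = []
    snap_rows = []
    n_dropped_pre = 0
    for w in range(len(woman_index)):
        lo, hi = bounds[w], bounds[w + 1]
        obs = lo + np.flatnonzero(days[lo:hi] <= end_day)
        if len(obs) < 2:
            continue
        vdays = days[obs].tolist()
        rep_idx = lo + np.flatnonzero(conc[lo:hi] >= 0)
        conceptions = conc[rep_idx].tolist()
        censor_ends = cens[rep_idx].tolist()
        periods, dpre = _segment_woman(
            vdays, cat_c[obs].tolist(), cat_a[obs].tolist(),
            conceptions, censor_ends, vdays[-1],
        )
        n_dropped_pre += dpre
        wid = woman_index[w]
        for (s, e, c, a, preg, cd, snap) in periods:
            rows.append((wid, s, e, c, a, preg, cd))
            snap_rows.append(obs[snap])

    if n_dropped_pre:
        logger.warning(
            "%d pregnancy report(s) dated before first visit dropped from risk sets",
            n_dropped_pre,
        )

    periods = pd.DataFrame(
        rows, columns=["woman_id", "_start", "_end", "contraceptive", "art",
                       "pregnancy", "_conception"],
    )
    if len(periods):
        periods["start_date"] = periods["_start"].values.astype("datetime64[D]")
        periods["end_date"] = periods["_end"].values.astype("datetime64[D]")
        cd = pd.to_numeric(periods["_conception"], errors="coerce")
        conception = pd.Series(pd.NaT, index=periods.index, dtype="datetime64[ns]")
        mask = cd.notna()
        if mask.any():
            conception.loc[mask] = pd.to_datetime(
                cd[mask].astype(np.int64).values.astype("datetime64[D]"))
        periods["conception_date"] = conception
        periods["exposure_time"] = (periods["_end"] - periods["_start"]) / DAYS_PER_YEAR
        mid = (periods["_start"] + periods["_end"]) / 2.0
        periods["calendar_year"] = _EPOCH_YEAR + mid / _MEAN_YEAR_DAYS
        periods["_snap"] = np.asarray(snap_rows, dtype=np.int64)
        periods = _attach_from_snapshots(periods, df, mid)
        periods = periods.drop(columns=["_snap"])
    else:
        for col in ("start_date", "end_date", "conception_date"):
            periods[col] = pd.Series(dtype="datetime64[ns]")
        periods["exposure_time"] = pd.Series(dtype=float)
        periods["calendar_year"] = pd.Series(dtype=float)

    total_wy = float(periods["exposure_time"].sum()) if len(periods) else 0.0
    return CodedCohort(
        periods=periods.drop(columns=["_start", "_end", "_conception"]),
        provenance=provenance,
        women_count=int(periods["woman_id"].nunique()) if len(periods) else 0,
        total_women_years=total_wy,
    )


def _nullable_days(col, n) -> np.ndarray:
    if col is None:
        return np.full(n, np.nan)
    d = pd.to_datetime(col, errors="coerce")
    out = d.values.astype("datetime64[D]").astype("float64")
    out[d.isna().values] = np.nan
    return out


def _attach_from_snapshots(periods, visits_sorted, mid) -> pd.DataFrame:
    """Copy last-observed covariate values from each period's snapshot visit."""
    present = [c for c in COVARIATE_COLUMNS if c in visits_sorted.columns]
    if not present:
        return periods
    ff = visits_sorted.groupby("woman_id", sort=False)[present].ffill()
    snap = periods["_snap"].values
    for col in present:
        periods[col] = ff[col].values[snap]
    if "age" in present:
        snap_day = visits_sorted["_day"].values[snap]
        periods["age"] = periods["age"] + (mid.values - snap_day) / DAYS_PER_YEAR
    return periods


def segment_periods(visits: pd.DataFrame, censor_rule: str = "FIXED_38_WEEKS",
                    study_end=None) -> pd.DataFrame:
    """Segment one woman's time-ordered visits into observation periods.

    Thin single-woman wrapper around :func:`code_cohort`; raises on
    unsorted input.  Returns the periods DataFrame (empty for a woman
    with fewer than two visits).
    """
    if visits["woman_id"].nunique() > 1:
        raise ValueError("segment_periods expects visits for a single woman")
    d = _day_ints(visits["visit_date"])
    if np.any(np.diff(d) < 0):
        raise ValueError("visits must be sorted by date")
    return code_cohort(visits, censor_rule=censor_rule, study_end=study_end).periods


def attach_covariates(periods: pd.DataFrame, visits: pd.DataFrame) -> pd.DataFrame:
    """Attach covariate snapshots to periods from the nearest visit at or
    before each period start.

    Values are carried forward from the last visit at which they were
    observed; covariates missing at every prior visit stay missing.  The
    ``age`` column (when present) is shifted to the period midpoint, and
    ``calendar_year`` is (re)computed as a continuous year at midpoint.
    """
    v = visits.copy()
    v["_day"] = _day_ints(v["visit_date"])
    v = v.sort_values(["woman_id", "_day"], kind="mergesort").reset_index(drop=True)
    p = periods.copy()
    start = _day_ints(p["start_date"])
    end = _day_ints(p["end_date"])
    order = np.lexsort((start, p["woman_id"].values.astype(str)))

    present = [c for c in COVARIATE_COLUMNS if c in v.columns]
    ff = v.groupby("woman_id", sort=False)[present].ffill()
    snap = np.empty(len(p), dtype=np.int64)
    by_woman = {w: idx.values for w, idx in v.groupby("woman_id").groups.items()}
    vdays = v["_day"].values
    for i in order:
        idx = by_woman[p["woman_id"].iloc[i]]
        pos = np.searchsorted(vdays[idx], start[i], side="right") - 1
        if pos < 0:
            raise ValueError("period starts before the woman's first visit")
        snap[i] = idx[pos]
    mid = (start + end) / 2.0
    for col in present:
        p[col] = ff[col].values[snap]
    if "age" in present:
        p["age"] = p["age"] + (mid - vdays[snap]) / DAYS_PER_YEAR
    p["calendar_year"] = _EPOCH_YEAR + mid / _MEAN_YEAR_DAYS
    return p
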