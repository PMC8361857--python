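"""Synthetic EMR-like cohorts with known true incidence-rate parameters.

The generator emulates the structure of a routine HIV-care EMR: repeated
clinic visits per woman, piecewise-constant contraceptive and ART
exposures that switch at visits, incident pregnancies drawn from a
piecewise-constant Poisson intensity (with a 38-week not-at-risk window
after each conception and conception-date back-dating via LMP /
gestational age / EDD reports), covariates with configurable
completely-at-random missingness, and three error-prone copies of the
exposure and outcome fields: an EMR copy, a chart-review copy, and a
telephone-interview copy, each degraded by its own confusion matrices
(chart and interview errors smaller than EMR errors by default).

Defaults are scaled to a desk-size cohort (2,000 women over a five-year
window) with exposure prevalences chosen so that every contraceptive x
ART x pregnancy validation stratum is populated; the true rate structure
places a log 3.2 efavirenz-vs-nevirapine interaction among implant
users on top of a 0.10 pregnancies/woman-year reference rate.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import (
    CodedCohort,
    DAYS_PER_YEAR,
    EDD_OFFSET_DAYS,
    OVULATION_OFFSET_DAYS,
    PREGNANCY_CENSOR_DAYS,
    code_cohort,
)

__all__ = [
    "TruthConfig",
    "GeneratedStudy",
    "generate_cohort",
    "summarize_cohort",
    "default_misclassification",
    "identity_misclassification",
]

_CONTRA_CODES = {"IMPLANT": "implant_unknown", "DMPA": "dmpa", "MEC": "iud",
                 "NONE": "", "OCP": "ocp", "LEC": "condom"}
_ART_CODES = {
    "EFV": "efavirenz;tenofovir;lamivudine",
    "NVP": "nevirapine;zidovudine;lamivudine",
    "PI": "lopinavir_r;tenofovir;lamivudine",
    "NO_ART": "",
    "UNSURE": "unsure",
}

#: centering constants for covariate effects so the baseline rate keeps its
#: interpretation at "typical covariate values"
_COV_CENTER = {"sqrt_cd4": math.sqrt(428.0), "cd4": 428.0, "age": 32.5,
               "log_bmi": math.log(22.2), "any_children": 0.87, "anti_tb": 0.0}


def default_misclassification() -> dict:
    """Per-phase confusion matrices P(observed | true), EMR noisiest."""
    return {
        "emr": {
            "contraceptive": {
                "IMPLANT": {"IMPLANT": 0.85, "DMPA": 0.075, "NONE": 0.075},
                "DMPA": {"DMPA": 0.88, "IMPLANT": 0.04, "NONE": 0.08},
                "MEC": {"MEC": 0.90, "NONE": 0.10},
                "NONE": {"NONE": 0.92, "IMPLANT": 0.03, "DMPA": 0.05},
            },
            "art": {
                "EFV": {"EFV": 0.93, "NVP": 0.04, "NO_ART": 0.03},
                "NVP": {"NVP": 0.93, "EFV": 0.04, "NO_ART": 0.03},
                "PI": {"PI": 0.92, "NVP": 0.05, "NO_ART": 0.03},
                "NO_ART": {"NO_ART": 0.95, "NVP": 0.03, "EFV": 0.02},
            },
            "pregnancy": {"sensitivity": 0.92, "false_positive_rate": 0.0},
        },
        "chart": {
            "contraceptive": {
                "IMPLANT": {"IMPLANT": 0.98, "NONE": 0.02},
                "DMPA": {"DMPA": 0.98, "NONE": 0.02},
                "MEC": {"MEC": 0.98, "NONE": 0.02},
                "NONE": {"NONE": 0.99, "DMPA": 0.01},
            },
            "art": {
                "EFV": {"EFV": 0.98, "NVP": 0.02},
                "NVP": {"NVP": 0.98, "EFV": 0.02},
                "PI": {"PI": 0.98, "NO_ART": 0.02},
                "NO_ART": {"NO_ART": 0.99, "NVP": 0.01},
            },
            "pregnancy": {"sensitivity": 0.98, "false_positive_rate": 0.0},
        },
        "interview": {
            "contraceptive": {
                "IMPLANT": {"IMPLANT": 0.995, "NONE": 0.005},
                "DMPA": {"DMPA": 0.995, "NONE": 0.005},
                "MEC": {"MEC": 0.995, "NONE": 0.005},
                "NONE": {"NONE": 0.995, "DMPA": 0.005},
            },
            "art": {
                "EFV": {"EFV": 0.95, "UNSURE": 0.045, "NVP": 0.005},
                "NVP": {"NVP": 0.95, "UNSURE": 0.045, "EFV": 0.005},
                "PI": {"PI": 0.95, "UNSURE": 0.05},
                "NO_ART": {"NO_ART": 0.97, "UNSURE": 0.03},
            },
            "pregnancy": {"sensitivity": 0.995, "false_positive_rate": 0.0},
        },
    }


def identity_misclassification() -> dict:
    """Error-free copies in every phase (for no-error identity checks)."""
    cats_c = ("IMPLANT", "DMPA", "MEC", "NONE")
    cats_a = ("EFV", "NVP", "PI", "NO_ART")
    out = {}
    for phase in ("emr", "chart", "interview"):
        out[phase] = {
            "contraceptive": {c: {c: 1.0} for c in cats_c},
            "art": {a: {a: 1.0} for a in cats_a},
            "pregnancy": {"sensitivity": 1.0, "false_positive_rate": 0.0},
        }
    return out


def _default_effects() -> dict:
    # contraceptive effects are compressed relative to real-world failure
    # rates so that every exposure cell keeps a workable number of events
    # in a 2,000-woman scaled-down cohort
    return {
        "IMPLANT": -0.7, "DMPA": -0.5, "MEC": -0.9,
        "EFV": 0.0, "PI": 0.0, "NO_ART": 0.1,
        "IMPLANT:EFV": math.log(3.2),
    }


def _default_missingness() -> dict:
    # marginal covariate missingness spanning the 0.004-0.257 range seen in
    # routine EMR data
    return {"education": 0.257, "n_children": 0.256, "marital_status": 0.136,
            "bmi": 0.092, "cd4": 0.070, "who_stage": 0.007, "weight_kg": 0.004}


@dataclass
class TruthConfig:
    """Generator parameters: the known truth a simulated study must recover.

    ``log_rate_effects`` maps contraceptive categories, ART categories and
    ``"CONTRA:ART"`` interaction keys to true log-rate contributions on top
    of ``log(baseline_rate)`` (reference cell: NONE contraceptive x NVP).
    ``covariate_effects`` maps transform names (``sqrt_cd4``, ``cd4``,
    ``age``, ``log_bmi``, ``any_children``, ``anti_tb``) to log-rate slopes
    applied to centered covariate values.
    """

    n_women: int = 2000
    study_start: str = "2011-01-01"
    study_end: str = "2015-12-31"
    visit_rate: float = 3.0          # mean visits / woman / year
    baseline_rate: float = 0.10      # pregnancies / woman-year, NONE x NVP
    contraceptive_prevalence: dict = field(
        default_factory=lambda: {"IMPLANT": 0.25, "DMPA": 0.25, "MEC": 0.12, "NONE": 0.38})
    art_prevalence: dict = field(
        default_factory=lambda: {"NVP": 0.40, "EFV": 0.32, "PI": 0.08, "NO_ART": 0.20})
    log_rate_effects: dict = field(default_factory=_default_effects)
    covariate_effects: dict = field(default_factory=dict)
    misclassification: dict = field(default_factory=default_misclassification)
    missingness_rates: dict = field(default_factory=_default_missingness)
    exposure_switch_rates: dict = field(
        default_factory=lambda: {"contraceptive": 0.45, "art": 0.25})
    phone_reachability: float = 0.85
    pregnancy_dating_probs: dict = field(
        default_factory=lambda: {"lmp": 0.6, "gest_age": 0.25, "edd": 0.15})
    seed: int = 0

    def __post_init__(self):
        for phase, vars_ in self.misclassification.items():
            for var in ("contraceptive", "art"):
                for true, row in vars_[var].items():
                    tot = sum(row.values())
                    if abs(tot - 1.0) > 1e-9:
                        raise ValueError(
                            f"confusion row {phase}/{var}/{true} sums to {tot}, not 1")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        for k, v in self.missingness_rates.items():
            if not 0 <= v < 1:
                raise ValueError(f"missingness rate for {k} outside [0,1)")
        if self.n_women <= 0:
            raise ValueError("degenerate config: n_women must be positive")
        if pd.Timestamp(self.study_end) <= pd.Timestamp(self.study_start):
            raise ValueError("degenerate config: empty study window")
        if self.visit_rate <= 0:
            raise ValueError("degenerate config: zero visit rate")

    # -- true parameter helpers ------------------------------------------
    def cell_log_rate(self, contraceptive: str, art: str) -> float:
        eff = self.log_rate_effects
        return (math.log(self.baseline_rate) + eff.get(contraceptive, 0.0)
                + eff.get(art, 0.0) + eff.get(f"{contraceptive}:{art}", 0.0))

    def true_log_irr(self, stratum: str, art_a: str, art_b: str = "NVP") -> float:
        """True within-contraceptive-stratum log IRR for ART ``art_a`` vs ``art_b``."""
        return self.cell_log_rate(stratum, art_a) - self.cell_log_rate(stratum, art_b)

    def true_log_irr_contraceptive(self, art: str, c_a: str, c_b: str) -> float:
        return self.cell_log_rate(c_a, art) - self.cell_log_rate(c_b, art)

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TruthConfig":
        base = cls()
        merged = {**base.to_dict(), **d}
        return cls(**merged)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class GeneratedStudy:
    """Gold-standard visits plus the three degraded copies of a cohort."""

    truth_visits: pd.DataFrame
    emr_visits: pd.DataFrame
    chart_visits: pd.DataFrame
    interview_visits: pd.DataFrame
    women: pd.DataFrame          # woman_id, entry_date, reachable
    config: TruthConfig

    def truth_cohort(self, **kw) -> CodedCohort:
        return code_cohort(self.truth_visits, provenance="TRUTH",
                           study_end=self.config.study_end, **kw)

    def emr_cohort(self, **kw) -> CodedCohort:
        return code_cohort(self.emr_visits, provenance="EMR",
                           study_end=self.config.study_end, **kw)


def _cum_table(matrix: dict) -> dict:
    """true -> (labels, cumulative probs) for inverse-CDF draws."""
    out = {}
    for true, row in matrix.items():
        labels = list(row)
        cum = np.cumsum([row[lbl] for lbl in labels])
        cum[-1] = 1.0
        out[true] = (labels, cum)
    return out


def _draw(table, true, u):
    labels, cum = table[true]
    return labels[int(np.searchsorted(cum, u))]


def generate_cohort(config: TruthConfig, seed: int | None = None) -> GeneratedStudy:
    """Simulate one cohort with gold-standard and degraded visit tables.

    Deterministic under a fixed ``(config, seed)``; ``seed`` overrides
    ``config.seed`` so replicate studies can reuse one config.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    start_day = np.datetime64(config.study_start, "D").astype(np.int64)
    end_day = np.datetime64(config.study_end, "D").astype(np.int64)
    span = int(end_day - start_day)
    lookahead_end = end_day + 270

    c_levels = list(config.contraceptive_prevalence)
    c_probs = np.cumsum([config.contraceptive_prevalence[c] for c in c_levels])
    c_probs = c_probs / c_probs[-1]
    a_levels = list(config.art_prevalence)
    a_probs = np.cumsum([config.art_prevalence[a] for a in a_levels])
    a_probs = a_probs / a_probs[-1]

    phases = ("truth", "emr", "chart", "interview")
    conf = {p: {
        "contraceptive": _cum_table(config.misclassification[p]["contraceptive"]),
        "art": _cum_table(config.misclassification[p]["art"]),
        "preg": config.misclassification[p]["pregnancy"],
    } for p in ("emr", "chart", "interview")}

    mean_gap = DAYS_PER_YEAR / config.visit_rate
    sw_c = config.exposure_switch_rates.get("contraceptive", 0.0)
    sw_a = config.exposure_switch_rates.get("art", 0.0)
    dating = list(config.pregnancy_dating_probs)
    dating_cum = np.cumsum([config.pregnancy_dating_probs[k] for k in dating])
    dating_cum = dating_cum / dating_cum[-1]

    cov_eff = config.covariate_effects
    marital_levels = ["legally_married", "never_married", "separated_divorced",
                      "widowed", "living_with_partner"]
    marital_cum = np.cumsum([0.557, 0.126, 0.117, 0.190, 0.010])
    marital_cum /= marital_cum[-1]
    edu_levels = ["some_primary", "completed_primary", "some_secondary",
                  "completed_secondary", "some_college", "completed_college", "none"]
    edu_cum = np.cumsum([0.471, 0.187, 0.157, 0.127, 0.043, 0.010, 0.005])
    edu_cum /= edu_cum[-1]
    who_cum = np.cumsum([0.378, 0.278, 0.288, 0.056])
    who_cum /= who_cum[-1]

    cols = {p: {k: [] for k in (
        "woman_id", "visit_day", "contraceptive_codes", "art_drugs",
        "preg_reported", "lmp_day", "gest_age_weeks", "edd_day",
        "program", "age", "marital_status", "education", "n_children",
        "who_stage", "cd4", "weight_kg", "bmi", "anti_tb")} for p in phases}
    women_rows = []

    for w in range(config.n_women):
        wid = f"W{w:05d}"
        entry = start_day + int(rng.uniform(0, max(span - 183, 1)))
        # visit process: homogeneous, continuing 9 months past study end so
        # late conceptions can still be reported
        vdays = []
        t = float(entry)
        while t <= lookahead_end:
            vdays.append(int(t))
            t += max(1.0, rng.exponential(mean_gap))
        vdays = sorted(set(vdays))
        if len(vdays) < 1:
            continue
        n_v = len(vdays)

        # true exposures: candidate switch at each visit
        cc = [_inv(c_levels, c_probs, rng.random())]
        aa = [_inv(a_levels, a_probs, rng.random())]
        for k in range(1, n_v):
            gap_y = (vdays[k] - vdays[k - 1]) / DAYS_PER_YEAR
            c = cc[-1]
            a = aa[-1]
            if rng.random() < 1.0 - math.exp(-sw_c * gap_y):
                c = _inv(c_levels, c_probs, rng.random())
            if rng.random() < 1.0 - math.exp(-sw_a * gap_y):
                a = _inv(a_levels, a_probs, rng.random())
            cc.append(c)
            aa.append(a)

        # covariates (constant per woman; marginals follow routine-EMR shapes)
        age0 = float(np.clip(rng.normal(32.5, 7.0), 16.0, 45.0))
        cov = {
            "program": "AMPATH" if rng.random() < 0.63 else "FACES",
            "marital_status": _inv(marital_levels, marital_cum, rng.random()),
            "education": _inv(edu_levels, edu_cum, rng.random()),
            "n_children": 0 if rng.random() < 0.126 else int(1 + rng.poisson(1.6)),
            "who_stage": _inv([1, 2, 3, 4], who_cum, rng.random()),
            "cd4": float(rng.lognormal(math.log(428.0), 0.55)),
            "weight_kg": float(np.clip(rng.normal(58.5, 9.5), 35.0, 130.0)),
            "bmi": float(np.clip(rng.normal(22.2, 3.4), 14.0, 45.0)),
            "anti_tb": int(rng.random() < 0.044),
        }
        lin = 0.0
        for term, coef in cov_eff.items():
            lin += coef * (_cov_value(term, cov) - _COV_CENTER.get(term, 0.0))

        # pregnancy process on [entry, min(last visit, study end)]
        risk_end = min(vdays[-1], int(end_day))
        conceptions = []
        t = float(entry)
        k = 0
        while t < risk_end and config.baseline_rate > 0:
            e = rng.exponential(1.0)
            # consume hazard across piecewise-constant segments
            while True:
                while k + 1 < n_v and vdays[k + 1] <= t:
                    k += 1
                seg_end = vdays[k + 1] if k + 1 < n_v else risk_end
                seg_end = min(seg_end, risk_end)
                lam = math.exp(config.cell_log_rate(cc[k], aa[k]) + lin)
                lam_d = lam / DAYS_PER_YEAR
                if seg_end <= t:
                    t = risk_end
                    break
                dur = seg_end - t
                if lam_d * dur >= e:
                    t = t + e / lam_d if lam_d > 0 else risk_end
                    break
                e -= lam_d * dur
                t = seg_end
                if t >= risk_end:
                    break
            if t < risk_end:
                conc = int(t)
                if conc > entry:
                    conceptions.append(conc)
                t = conc + PREGNANCY_CENSOR_DAYS  # not at risk for 38 weeks
            else:
                break

        # spell ids over the visit grid (joint exposure runs); errors are
        # drawn once per spell so a phase's copy is internally consistent
        spell = [0] * n_v
        spell_first = [0]
        for kk in range(1, n_v):
            if (cc[kk], aa[kk]) != (cc[kk - 1], aa[kk - 1]):
                spell[kk] = spell[kk - 1] + 1
                spell_first.append(kk)
            else:
                spell[kk] = spell[kk - 1]
        n_spells = spell[-1] + 1

        obs_c = {}
        obs_a = {}
        for p in ("emr", "chart", "interview"):
            tc = conf[p]["contraceptive"]
            ta = conf[p]["art"]
            oc, oa = [], []
            for s in range(n_spells):
                true_c = cc[spell_first[s]]
                true_a = aa[spell_first[s]]
                oc.append(_draw(tc, true_c, rng.random()) if true_c in tc else true_c)
                oa.append(_draw(ta, true_a, rng.random()) if true_a in ta else true_a)
            obs_c[p] = oc
            obs_a[p] = oa

        # per-phase pregnancy reports: conception -> first visit after it
        reports = {p: {} for p in phases}  # visit index -> conception day
        dating_src = {}
        for conc in conceptions:
            j = _first_visit_after(vdays, conc)
            if j is None:
                continue
            dating_src[conc] = _inv(dating, dating_cum, rng.random())
            reports["truth"][j] = conc
            for p in ("emr", "chart", "interview"):
                if rng.random() < conf[p]["preg"]["sensitivity"]:
                    reports[p][j] = conc

        # covariate masking (per woman, completely at random) for EMR-derived
        # tables; the gold-standard table keeps everything
        masked = dict(cov)
        for name, rate in config.missingness_rates.items():
            if name in masked and rng.random() < rate:
                masked[name] = np.nan

        women_rows.append((wid, entry, bool(rng.random() < config.phone_reachability)))

        vdays_arr = np.asarray(vdays, dtype=np.int64)
        spell_arr = np.asarray(spell, dtype=np.int64)
        ages = age0 + (vdays_arr - entry) / DAYS_PER_YEAR
        for p in phases:
            cvals = cov if p == "truth" else masked
            dst = cols[p]
            if p == "truth":
                ocodes = [_CONTRA_CODES.get(c, c) for c in cc]
                acodes = [_ART_CODES.get(a, a) for a in aa]
            else:
                oc_spell = [_CONTRA_CODES.get(c, c) for c in obs_c[p]]
                oa_spell = [_ART_CODES.get(a, a) for a in obs_a[p]]
                ocodes = [oc_spell[s] for s in spell]
                acodes = [oa_spell[s] for s in spell]
            preg = np.zeros(n_v, dtype=np.int64)
            lmp = np.full(n_v, np.nan)
            gaw = np.full(n_v, np.nan)
            edd = np.full(n_v, np.nan)
            for j, conc in reports[p].items():
                preg[j] = 1
                src = dating_src[conc]
                if src == "lmp":
                    lmp[j] = conc - OVULATION_OFFSET_DAYS
                elif src == "gest_age":
                    gaw[j] = (vdays[j] - conc + OVULATION_OFFSET_DAYS) / 7.0
                else:
                    edd[j] = conc + EDD_OFFSET_DAYS
            dst["woman_id"].append([wid] * n_v)
            dst["visit_day"].append(vdays_arr)
            dst["contraceptive_codes"].append(ocodes)
            dst["art_drugs"].append(acodes)
            dst["preg_reported"].append(preg)
            dst["lmp_day"].append(lmp)
            dst["gest_age_weeks"].append(gaw)
            dst["edd_day"].append(edd)
            dst["age"].append(ages)
            for name in ("program", "marital_status", "education", "n_children",
                         "who_stage", "cd4", "weight_kg", "bmi", "anti_tb"):
                dst[name].append([cvals[name]] * n_v)

    frames = {}
    for p in phases:
        d = cols[p]

        def cat(key, dtype=object):
            # object dtype for label columns: unicode casting would turn a
            # masked np.nan into the string "nan"
            if not d[key]:
                return np.array([], dtype=dtype)
            parts = [np.asarray(chunk, dtype=dtype) for chunk in d[key]]
            return np.concatenate(parts)

        df = pd.DataFrame({
            "woman_id": cat("woman_id"),
            "visit_date": cat("visit_day", np.int64).astype("datetime64[D]"),
            "contraceptive_codes": cat("contraceptive_codes"),
            "art_drugs": cat("art_drugs"),
            "preg_reported": cat("preg_reported", np.int64),
            "lmp_date": _days_to_dates(cat("lmp_day", float)),
            "gest_age_weeks": cat("gest_age_weeks", float),
            "edd_date": _days_to_dates(cat("edd_day", float)),
            "program": cat("program"),
            "age": cat("age", float),
            "marital_status": cat("marital_status"),
            "education": cat("education"),
            "n_children": cat("n_children", float),
            "who_stage": cat("who_stage", float),
            "cd4": cat("cd4", float),
            "weight_kg": cat("weight_kg", float),
            "bmi": cat("bmi", float),
            "anti_tb": cat("anti_tb", float),
        })
        frames[p] = df

    women = pd.DataFrame(women_rows, columns=["woman_id", "_entry", "reachable"])
    women["entry_date"] = women["_entry"].values.astype("datetime64[D]")
    women = women.drop(columns=["_entry"])

    return GeneratedStudy(
        truth_visits=frames["truth"], emr_visits=frames["emr"],
        chart_visits=frames["chart"], interview_visits=frames["interview"],
        women=women, config=config,
    )


def _inv(labels, cum, u):
    return labels[int(np.searchsorted(cum, u))]


def _first_visit_after(vdays, day):
    from bisect import bisect_right
    j = bisect_right(vdays, day)
    return j if j < len(vdays) else None


def _cov_value(term, cov):
    if term == "sqrt_cd4":
        return math.sqrt(cov["cd4"])
    if term == "log_bmi":
        return math.log(cov["bmi"])
    if term == "any_children":
        return float(cov["n_children"] > 0)
    if term in cov:
        return float(cov[term])
    raise KeyError(f"unknown covariate-effect term {term!r}")


def _days_to_dates(days):
    arr = np.asarray(days, dtype="float64")
    out = np.full(len(arr), np.datetime64("NaT"), dtype="datetime64[D]")
    m = ~np.isnan(arr)
    out[m] = arr[m].astype(np.int64).astype("datetime64[D]")
    return out


def summarize_cohort(obj) -> pd.DataFrame:
    """Pregnancy counts and women-years by contraceptive x ART cell.

    Accepts a :class:`GeneratedStudy` (summarizes its gold-standard
    coding), a :class:`CodedCohort`, or a raw periods DataFrame.
    """
    if isinstance(obj, GeneratedStudy):
        periods = obj.truth_cohort().periods
    elif isinstance(obj, CodedCohort):
        periods = obj.periods
    else:
        periods = obj
    if len(periods) == 0:
        return pd.DataFrame(columns=["contraceptive", "art", "pregnancies", "women_years"])
    tab = (periods.groupby(["contraceptive", "art"], observed=True)
           .agg(pregnancies=("pregnancy", "sum"), women_years=("exposure_time", "sum"))
           .reset_index())
    return tab
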