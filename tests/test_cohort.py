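"""Coding oracles: exposure hierarchies, conception dating, segmentation
with 38-week censoring, and covariate snapshots -- all against
hand-enumerated timelines."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from threephase.cohort import (
    CONTRACEPTIVE_HIERARCHY,
    ConceptionDatingError,
    assign_art_category,
    assign_contraceptive_category,
    attach_covariates,
    code_cohort,
    estimate_conception_date,
    segment_periods,
)
from .conftest import make_visits


@pytest.mark.parametrize("codes, expected", [
    ({"implant_lng", "condom"}, "IMPLANT"),
    ({"iud", "implant_etg", "dmpa"}, "MEC"),
    (set(), "NONE"),
    ("", "NONE"),
    ({"none"}, "NONE"),
    ({"dmpa", "ocp"}, "DMPA"),
    ({"ocp", "natural"}, "OCP"),
    ({"condom"}, "LEC"),
    ({"permanent", "condom"}, "MEC"),
    ({"what_is_this"}, "MISSING"),
    ("implant_unknown;condom", "IMPLANT"),
])
def test_contraceptive_hierarchy(codes, expected):
    assert assign_contraceptive_category(codes) == expected


def test_contraceptive_hierarchy_idempotent_under_lower_priority_labels():
    """Adding any label below the winning category never changes the result."""
    lower = {"MEC": ["implant_etg", "dmpa", "ocp", "condom"],
             "IMPLANT": ["dmpa", "ocp", "natural"],
             "DMPA": ["ocp", "condom"],
             "OCP": ["condom", "natural"]}
    label_of = {"MEC": "iud", "IMPLANT": "implant_lng", "DMPA": "dmpa", "OCP": "ocp"}
    for cat, extras in lower.items():
        base = {label_of[cat]}
        for extra in extras:
            assert assign_contraceptive_category(base | {extra}) == cat


@pytest.mark.parametrize("drugs, expected", [
    ({"efavirenz", "tenofovir", "lamivudine"}, "EFV"),
    ({"efavirenz", "lopinavir_r", "tenofovir", "lamivudine"}, "COMBINATION"),
    (set(), "NO_ART"),
    ({"nevirapine", "zidovudine", "lamivudine"}, "NVP"),
    ({"lopinavir_r", "tenofovir", "lamivudine"}, "PI"),
    ({"tenofovir", "lamivudine", "zidovudine"}, "NRTI_ONLY"),
    ({"efavirenz", "nevirapine", "tenofovir"}, "COMBINATION"),
    ({"efavirenz"}, "MISSING"),           # < 3 drugs is not assumed NO_ART
    ({"tenofovir", "lamivudine"}, "MISSING"),
])
def test_art_categories(drugs, expected):
    assert assign_art_category(drugs) == expected


@pytest.mark.parametrize("report, report_date, expected", [
    ({"lmp_date": "2013-01-01"}, "2013-03-01", "2013-01-15"),
    ({"edd_date": "2013-10-08"}, "2013-03-01", "2013-01-15"),
    ({"gest_age_weeks": 8}, "2013-03-12", "2013-01-29"),
    # LMP wins over both alternatives
    ({"lmp_date": "2013-01-01", "gest_age_weeks": 4, "edd_date": "2014-01-01"},
     "2013-03-01", "2013-01-15"),
    # gestational age wins over EDD
    ({"gest_age_weeks": 8, "edd_date": "2013-12-01"}, "2013-03-12", "2013-01-29"),
])
def test_conception_dating_precedence(report, report_date, expected):
    assert estimate_conception_date(report, report_date) == pd.Timestamp(expected)


def test_conception_date_clamped_to_report_date():
    got = estimate_conception_date({"lmp_date": "2013-05-01"}, "2013-05-02")
    assert got <= pd.Timestamp("2013-05-02")


def test_conception_dating_unavailable_names_the_woman():
    with pytest.raises(ConceptionDatingError, match="W1"):
        estimate_conception_date({"woman_id": "W1"}, "2013-01-01")


def _periods(visits, **kw):
    return segment_periods(make_visits(visits), **kw)


# -- hand-enumerated segmentation timelines ---------------------------------

D0 = pd.Timestamp("2012-01-01")


def day(n):
    return (D0 + pd.Timedelta(days=n)).strftime("%Y-%m-%d")


def test_two_visits_no_changes_single_period():
    p = _periods([
        {"woman_id": "A", "visit_date": day(0), "contraceptive_codes": "dmpa"},
        {"woman_id": "A", "visit_date": day(300), "contraceptive_codes": "dmpa"},
    ])
    assert len(p) == 1
    row = p.iloc[0]
    assert (row.contraceptive, row.art, row.pregnancy) == ("DMPA", "NO_ART", 0)
    assert row.exposure_time == pytest.approx(300 / 365.25)


def test_single_visit_contributes_no_person_time():
    p = _periods([{"woman_id": "A", "visit_date": day(0)}])
    assert len(p) == 0


def test_worked_timeline_with_pregnancy_and_38_week_censoring():
    """Implant+NVP -> implant+EFV at day 400, conception day 500, last
    visit day 800: periods [0,400), [400,500) pregnant, censor
    [500,766), resume [766,800)."""
    art_nvp = "nevirapine;zidovudine;lamivudine"
    art_efv = "efavirenz;tenofovir;lamivudine"
    p = _periods([
        {"woman_id": "A", "visit_date": day(0),
         "contraceptive_codes": "implant_etg", "art_drugs": art_nvp},
        {"woman_id": "A", "visit_date": day(400),
         "contraceptive_codes": "implant_etg", "art_drugs": art_efv},
        {"woman_id": "A", "visit_date": day(520),
         "contraceptive_codes": "implant_etg", "art_drugs": art_efv,
         "preg_reported": 1, "lmp_date": day(500 - 14)},
        {"woman_id": "A", "visit_date": day(800),
         "contraceptive_codes": "implant_etg", "art_drugs": art_efv},
    ], censor_rule="FIXED_38_WEEKS")
    assert len(p) == 3
    starts = [(r.start_date - D0).days for r in p.itertuples()]
    ends = [(r.end_date - D0).days for r in p.itertuples()]
    assert starts == [0, 400, 766]
    assert ends == [400, 500, 800]
    assert p["pregnancy"].tolist() == [0, 1, 0]
    assert p["art"].tolist() == ["NVP", "EFV", "EFV"]
    assert (p.iloc[1].conception_date - D0).days == 500


def test_outcome_records_censoring_uses_recorded_outcome_date():
    p = _periods([
        {"woman_id": "A", "visit_date": day(0), "contraceptive_codes": "dmpa"},
        {"woman_id": "A", "visit_date": day(120), "contraceptive_codes": "dmpa",
         "preg_reported": 1, "lmp_date": day(100 - 14),
         "outcome": "miscarriage", "outcome_date": day(180)},
        {"woman_id": "A", "visit_date": day(400), "contraceptive_codes": "dmpa"},
    ], censor_rule="OUTCOME_RECORDS")
    # risk resumes at the miscarriage date (day 180), not day 100+266
    starts = [(r.start_date - D0).days for r in p.itertuples()]
    ends = [(r.end_date - D0).days for r in p.itertuples()]
    assert starts == [0, 180]
    assert ends == [100, 400]
    assert p["pregnancy"].tolist() == [1, 0]


def test_multiple_pregnancies_per_woman():
    p = _periods([
        {"woman_id": "A", "visit_date": day(0)},
        {"woman_id": "A", "visit_date": day(60), "preg_reported": 1,
         "lmp_date": day(50 - 14)},
        {"woman_id": "A", "visit_date": day(700), "preg_reported": 1,
         "lmp_date": day(600 - 14)},
        {"woman_id": "A", "visit_date": day(1000)},
    ])
    assert p["pregnancy"].sum() == 2
    # censor windows [50, 316) and [600, 866)
    starts = [(r.start_date - D0).days for r in p.itertuples()]
    ends = [(r.end_date - D0).days for r in p.itertuples()]
    assert starts == [0, 316, 866]
    assert ends == [50, 600, 1000]


def test_conception_before_first_visit_dropped():
    p = _periods([
        {"woman_id": "A", "visit_date": day(100)},
        {"woman_id": "A", "visit_date": day(200), "preg_reported": 1,
         "lmp_date": day(20 - 14)},
        {"woman_id": "A", "visit_date": day(400)},
    ])
    assert p["pregnancy"].sum() == 0
    assert len(p) == 1


def test_exposure_change_during_censor_window_applies_after():
    p = _periods([
        {"woman_id": "A", "visit_date": day(0), "contraceptive_codes": "dmpa"},
        {"woman_id": "A", "visit_date": day(110), "contraceptive_codes": "dmpa",
         "preg_reported": 1, "lmp_date": day(100 - 14)},
        {"woman_id": "A", "visit_date": day(200), "contraceptive_codes": "implant_lng"},
        {"woman_id": "A", "visit_date": day(600), "contraceptive_codes": "implant_lng"},
    ])
    starts = [(r.start_date - D0).days for r in p.itertuples()]
    assert starts == [0, 366]
    assert p["contraceptive"].tolist() == ["DMPA", "IMPLANT"]


def test_pregnancy_reported_in_lookahead_counts():
    """A conception inside the window reported after study end is kept."""
    v = make_visits([
        {"woman_id": "A", "visit_date": "2015-01-01"},
        {"woman_id": "A", "visit_date": "2015-12-01"},
        {"woman_id": "A", "visit_date": "2016-03-01", "preg_reported": 1,
         "lmp_date": "2015-11-01"},
    ])
    c = code_cohort(v, study_end="2015-12-31")
    assert c.periods["pregnancy"].sum() == 1


def test_visits_after_study_end_contribute_no_exposure_time():
    v = make_visits([
        {"woman_id": "A", "visit_date": "2015-01-01"},
        {"woman_id": "A", "visit_date": "2015-06-01"},
        {"woman_id": "A", "visit_date": "2016-04-01"},
    ])
    c = code_cohort(v, study_end="2015-12-31")
    assert c.total_women_years == pytest.approx(151 / 365.25)


def test_segment_periods_rejects_unsorted_input():
    v = make_visits([
        {"woman_id": "A", "visit_date": day(100)},
        {"woman_id": "A", "visit_date": day(0)},
    ])
    with pytest.raises(ValueError, match="sorted"):
        segment_periods(v)


def test_covariate_snapshots_carry_forward_and_propagate_missing():
    v = make_visits([
        {"woman_id": "A", "visit_date": day(0), "contraceptive_codes": "dmpa"},
        {"woman_id": "A", "visit_date": day(100), "contraceptive_codes": "implant_etg"},
        {"woman_id": "A", "visit_date": day(300), "contraceptive_codes": "implant_etg"},
    ])
    v["who_stage"] = [1.0, 3.0, np.nan]
    v["cd4"] = [np.nan, np.nan, np.nan]
    v["education"] = ["some_primary", None, None]
    c = code_cohort(v)
    p = c.periods
    assert p["who_stage"].tolist() == [1.0, 3.0]        # lookup at period start
    assert p["education"].tolist() == ["some_primary"] * 2  # carried forward
    assert p["cd4"].isna().all()                        # missing stays missing


def test_attach_covariates_matches_code_cohort():
    v = make_visits([
        {"woman_id": "A", "visit_date": day(0), "contraceptive_codes": "dmpa"},
        {"woman_id": "A", "visit_date": day(200), "contraceptive_codes": "implant_etg"},
        {"woman_id": "A", "visit_date": day(500), "contraceptive_codes": "implant_etg"},
    ])
    v["age"] = [30.0, 30.0 + 200 / 365.25, 30.0 + 500 / 365.25]
    v["cd4"] = [410.0, np.nan, 500.0]
    c = code_cohort(v)
    again = attach_covariates(c.periods[["woman_id", "start_date", "end_date",
                                         "contraceptive", "art", "pregnancy",
                                         "exposure_time"]], v)
    assert again["cd4"].tolist() == c.periods["cd4"].tolist()
    # age is evaluated at the period midpoint
    assert again["age"].tolist() == pytest.approx(c.periods["age"].tolist())
    assert again.loc[0, "age"] == pytest.approx(30.0 + 100 / 365.25)


# -- conservation properties -------------------------------------------------

@settings(max_examples=25, deadline=None)
@given(st.lists(st.integers(min_value=1, max_value=400), min_size=1, max_size=6),
       st.lists(st.integers(min_value=0, max_value=2), min_size=1, max_size=6),
       st.integers(min_value=0, max_value=3))
def test_person_time_conservation(gaps, method_idx, n_preg):
    """Risk time plus censored pregnancy windows always equals the span
    from first to last visit, exactly in day arithmetic."""
    days = np.cumsum([0] + gaps)
    methods = ["dmpa", "implant_etg", ""]
    rows = []
    for i, d in enumerate(days):
        rows.append({"woman_id": "A", "visit_date": day(int(d)),
                     "contraceptive_codes": methods[method_idx[min(i, len(method_idx) - 1)]]})
    # sprinkle pregnancy reports at distinct conceptions inside the span
    span = int(days[-1])
    for j in range(n_preg):
        conc = 1 + j * max(span // max(n_preg, 1), 1)
        if conc >= span:
            break
        rows.append({"woman_id": "A", "visit_date": day(int(span)),
                     "preg_reported": 1, "lmp_date": day(conc - 14)})
    v = make_visits(rows)
    c = code_cohort(v)
    p = c.periods
    if len(p) == 0:
        return
    risk_days = ((p["end_date"] - p["start_date"]).dt.days).sum()
    conc_days = sorted((p.loc[p["pregnancy"] == 1, "conception_date"] - D0).dt.days)
    censored = 0
    for cd_ in conc_days:
        censored += min(cd_ + 266, span) - cd_
    assert risk_days + censored == span


def test_pregnancy_count_conservation(small_study):
    """Coded pregnancies equal the dateable conception events inside
    observation time, per the gold-standard copy."""
    truth = small_study.truth_cohort()
    v = small_study.truth_visits
    # independent count: reported conceptions (from dating fields) that fall
    # strictly inside each woman's [first visit, last in-window visit) span
    reports = v[v["preg_reported"] == 1].copy()
    rd = pd.to_datetime(reports["visit_date"])
    conc = pd.to_datetime(reports["lmp_date"]) + pd.Timedelta(days=14)
    ga = pd.to_numeric(reports["gest_age_weeks"])
    conc = conc.fillna(rd - pd.to_timedelta((ga * 7).round(), unit="D")
                       + pd.Timedelta(days=14))
    conc = conc.fillna(pd.to_datetime(reports["edd_date"]) - pd.Timedelta(days=266))
    end = pd.Timestamp(small_study.config.study_end)
    vv = v.copy()
    vv["visit_date"] = pd.to_datetime(vv["visit_date"])
    inwin = vv[vv["visit_date"] <= end]
    lo = inwin.groupby("woman_id")["visit_date"].min()
    hi = inwin.groupby("woman_id")["visit_date"].max()
    n_vis = inwin.groupby("woman_id").size()
    ok = (reports["woman_id"].map(n_vis).fillna(0) >= 2).values
    ok &= (conc > reports["woman_id"].map(lo)).values
    ok &= (conc < reports["woman_id"].map(hi)).values
    # drop conceptions nested inside a previous pregnancy's censor window
    expected = 0
    for _w, grp in pd.DataFrame({"w": reports["woman_id"], "c": conc, "ok": ok}) \
            .groupby("w"):
        last_end = None
        for c_ in sorted(grp.loc[grp["ok"], "c"]):
            if last_end is not None and c_ < last_end:
                continue
            expected += 1
            last_end = c_ + pd.Timedelta(days=266)
    assert truth.periods["pregnancy"].sum() == expected


def test_segmentation_deterministic(small_study):
    a = small_study.emr_cohort().periods
    b = small_study.emr_cohort().periods
    pd.testing.assert_frame_equal(a, b)
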