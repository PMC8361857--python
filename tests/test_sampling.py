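"""Validation-sampling oracles: stratum enumeration, inclusion
probabilities, priority phase-3 selection, p2 estimation, reconciliation
precedence, and brute-force Horvitz-Thompson unbiasedness."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import threephase as tp
from threephase.sampling import (OTHER_STRATUM, all_strata, priority_category,
                                 stratum_label)
from .conftest import make_visits


def periods_frame(rows):
    """rows: (woman, contraceptive, art, pregnancy, years)."""
    recs = []
    for w, c, a, p, t in rows:
        recs.append({"woman_id": w, "contraceptive": c, "art": a,
                     "pregnancy": p, "exposure_time": t})
    return pd.DataFrame(recs)


def test_thirty_two_strata_enumeration():
    s = all_strata()
    assert len(s) == 32
    assert len(set(s)) == 32
    assert stratum_label("IMPLANT", "EFV", 1) in s


def test_single_cell_woman_gets_her_cell():
    p = periods_frame([("A", "IMPLANT", "EFV", 0, 1.0),
                       ("A", "IMPLANT", "EFV", 1, 0.5)])
    s = tp.assign_strata(p)
    assert s.loc[s.woman_id == "A", "stratum"].item() == "IMPLANT|EFV|1"


def test_multi_cell_woman_assigned_to_rarest_cell():
    rows = [("A", "IMPLANT", "EFV", 0, 1.0), ("A", "DMPA", "NVP", 0, 1.0)]
    # make DMPA|NVP|0 common, IMPLANT|EFV|0 rare
    for i in range(5):
        rows.append((f"B{i}", "DMPA", "NVP", 0, 1.0))
    s = tp.assign_strata(periods_frame(rows))
    assert s.loc[s.woman_id == "A", "stratum"].item() == "IMPLANT|EFV|0"


def test_women_outside_grid_get_other_stratum():
    p = periods_frame([("A", "OCP", "NVP", 0, 1.0),
                       ("B", "LEC", "EFV", 0, 1.0),
                       ("C", "IMPLANT", "NVP", 0, 1.0)])
    s = tp.assign_strata(p).set_index("woman_id")["stratum"]
    assert s["A"] == OTHER_STRATUM
    assert s["B"] == OTHER_STRATUM
    assert s["C"] == "IMPLANT|NVP|0"


def test_priority_category_mapping():
    assert priority_category("IMPLANT|EFV|1") == "pregnant-implant"
    assert priority_category("IMPLANT|NVP|0") == "nonpregnant-implant"
    assert priority_category("DMPA|PI|1") == "pregnant-dmpa"
    assert priority_category("NONE|NVP|1") == "other"
    assert priority_category(OTHER_STRATUM) == "other"


def _strata_frame(sizes):
    rows = []
    i = 0
    for stratum, n in sizes.items():
        for _ in range(n):
            rows.append({"woman_id": f"W{i:03d}", "stratum": stratum,
                         "priority_category": priority_category(stratum)})
            i += 1
    return pd.DataFrame(rows)


def test_phase2_counts_and_p1():
    strata = _strata_frame({"IMPLANT|EFV|0": 100, "DMPA|NVP|0": 40})
    design = tp.SamplingDesign(phase2_targets={"IMPLANT|EFV|0": 25,
                                               "DMPA|NVP|0": 1.0})
    a = tp.sample_phase2(strata, design, seed=3)
    g = a.groupby("stratum").agg(n=("sampled_phase2", "sum"), p1=("p1", "first"))
    assert g.loc["IMPLANT|EFV|0", "n"] == 25
    assert g.loc["IMPLANT|EFV|0", "p1"] == pytest.approx(0.25)
    # target = stratum size -> everyone sampled with p1 = 1
    assert g.loc["DMPA|NVP|0", "n"] == 40
    assert g.loc["DMPA|NVP|0", "p1"] == 1.0


def test_phase2_target_capped_at_stratum_size():
    strata = _strata_frame({"IMPLANT|EFV|1": 3})
    design = tp.SamplingDesign(phase2_targets={"IMPLANT|EFV|1": 10})
    a = tp.sample_phase2(strata, design, seed=0)
    assert a["sampled_phase2"].sum() == 3


def test_phase2_deterministic_under_seed():
    strata = _strata_frame({"IMPLANT|EFV|0": 50, "NONE|NVP|0": 50})
    design = tp.SamplingDesign(phase2_targets={}, default_fraction=0.3)
    a = tp.sample_phase2(strata, design, seed=11)
    b = tp.sample_phase2(strata, design, seed=11)
    pd.testing.assert_frame_equal(a, b)
    c = tp.sample_phase2(strata, design, seed=12)
    assert not a["sampled_phase2"].equals(c["sampled_phase2"])


def test_phase3_priority_enumeration():
    """Budget 10 with 6 pregnant-implant and 20 nonpregnant-implant women:
    all six plus four from the next category."""
    strata = _strata_frame({"IMPLANT|EFV|1": 6, "IMPLANT|NVP|0": 20})
    design = tp.SamplingDesign(phase2_targets={"IMPLANT|EFV|1": 1.0,
                                               "IMPLANT|NVP|0": 1.0},
                               phase3_budget=10)
    a = tp.sample_phase2(strata, design, seed=0)
    a = tp.sample_phase3(a, design, seed=1)
    got = a[a.sampled_phase3].groupby("priority_category").size()
    assert got["pregnant-implant"] == 6
    assert got["nonpregnant-implant"] == 4


def test_phase3_budget_covers_everyone():
    strata = _strata_frame({"IMPLANT|EFV|1": 4, "DMPA|NVP|1": 4})
    design = tp.SamplingDesign(phase2_targets={"IMPLANT|EFV|1": 1.0,
                                               "DMPA|NVP|1": 1.0},
                               phase3_budget=100)
    a = tp.sample_phase3(tp.sample_phase2(strata, design, seed=0), design, seed=0)
    assert a["sampled_phase3"].sum() == 8


def test_phase3_respects_reachability_and_empty_categories():
    strata = _strata_frame({"IMPLANT|EFV|1": 5})
    design = tp.SamplingDesign(phase2_targets={"IMPLANT|EFV|1": 1.0},
                               phase3_budget=10)
    a2 = tp.sample_phase2(strata, design, seed=0)
    reach = pd.Series(False, index=strata["woman_id"])
    reach.iloc[:2] = True
    a3 = tp.sample_phase3(a2, design, reachable=reach, seed=0)
    assert a3["sampled_phase3"].sum() == 2
    assert set(a3.loc[a3.sampled_phase3, "woman_id"]) == set(reach[reach].index)


def test_phase3_nesting_invariant(small_emr_periods):
    design = tp.SamplingDesign.default()
    strata = tp.assign_strata(small_emr_periods)
    a = tp.sample_phase3(tp.sample_phase2(strata, design, seed=5), design, seed=6)
    assert (a.loc[a.sampled_phase3, "sampled_phase2"]).all()


def test_p2_saturated_model_recovers_category_fractions():
    strata = _strata_frame({"IMPLANT|EFV|1": 10, "IMPLANT|NVP|0": 40})
    design = tp.SamplingDesign(phase2_targets={"IMPLANT|EFV|1": 1.0,
                                               "IMPLANT|NVP|0": 1.0},
                               phase3_budget=30)
    a = tp.sample_phase3(tp.sample_phase2(strata, design, seed=0), design, seed=1)
    a = tp.fit_p2_model(a)
    p2 = a[a.sampled_phase2].groupby("priority_category")["p2"].first()
    # 10/10 pregnant-implant then 20/40 of the next category
    assert p2["pregnant-implant"] == pytest.approx(1.0, abs=1e-6)
    assert p2["nonpregnant-implant"] == pytest.approx(0.5, abs=1e-6)


def test_p2_intercept_only_limit():
    """With one category, fitted p2 equals the overall selection fraction."""
    strata = _strata_frame({"NONE|NVP|0": 50})
    design = tp.SamplingDesign(phase2_targets={"NONE|NVP|0": 1.0}, phase3_budget=20)
    a = tp.fit_p2_model(tp.sample_phase3(tp.sample_phase2(strata, design, seed=0),
                                         design, seed=1))
    assert a.loc[a.sampled_phase2, "p2"].unique() == pytest.approx([0.4])


def test_weight_consistency(small_emr_periods):
    """weight * p1 * (p2 when interviewed) == 1 to machine precision."""
    design = tp.SamplingDesign.default()
    design.phase3_budget = 10  # keep some phase-2 women uninterviewed
    strata = tp.assign_strata(small_emr_periods)
    a = tp.fit_p2_model(tp.sample_phase3(tp.sample_phase2(strata, design, seed=5),
                                         design, seed=6))
    wc = tp.compute_weights(a, "chart")
    p1 = a.set_index("woman_id")["p1"]
    assert np.allclose(wc * p1.loc[wc.index], 1.0)
    wi = tp.compute_weights(a, "interview")
    p2 = a.set_index("woman_id")["p2"]
    assert np.allclose(wi * p1.loc[wi.index] * p2.loc[wi.index], 1.0)


def test_horvitz_thompson_brute_force_unbiased():
    """On a 6-woman population with a 2-stratum design, the IPW total
    averaged over every possible phase-2 sample equals the population
    total exactly."""
    y = {"W0": 1.0, "W1": 2.0, "W2": 4.0, "W3": 8.0, "W4": 16.0, "W5": 32.0}
    stratum_of = {"W0": "IMPLANT|EFV|1", "W1": "IMPLANT|EFV|1", "W2": "IMPLANT|EFV|1",
                  "W3": "NONE|NVP|0", "W4": "NONE|NVP|0", "W5": "NONE|NVP|0"}
    targets = {"IMPLANT|EFV|1": 2, "NONE|NVP|0": 1}
    members = {s: [w for w, ss in stratum_of.items() if ss == s]
               for s in targets}
    totals = []
    for s1 in itertools.combinations(members["IMPLANT|EFV|1"], 2):
        for s2 in itertools.combinations(members["NONE|NVP|0"], 1):
            sample = list(s1) + list(s2)
            ht = sum(y[w] / (targets[stratum_of[w]] / len(members[stratum_of[w]]))
                     for w in sample)
            totals.append(ht)
    assert np.mean(totals) == pytest.approx(sum(y.values()), abs=1e-12)
    # and the package's sampler realizes exactly these inclusion probabilities
    strata = pd.DataFrame({"woman_id": list(y),
                           "stratum": [stratum_of[w] for w in y],
                           "priority_category": "other"})
    a = tp.sample_phase2(strata, tp.SamplingDesign(phase2_targets=targets), seed=9)
    w = tp.compute_weights(a, "chart")
    assert sorted(np.round(w.values, 12).tolist()) in ([1.5, 1.5, 3.0],)
    assert a["sampled_phase2"].sum() == 3


# -- reconciliation ----------------------------------------------------------

def _phase_visits(c_codes, a_drugs, preg=0, lmp=None):
    return make_visits([
        {"woman_id": "A", "visit_date": "2012-01-01",
         "contraceptive_codes": c_codes, "art_drugs": a_drugs},
        {"woman_id": "A", "visit_date": "2013-01-01",
         "contraceptive_codes": c_codes, "art_drugs": a_drugs,
         "preg_reported": preg, "lmp_date": lmp},
    ])


ART_NVP = "nevirapine;zidovudine;lamivudine"
ART_EFV = "efavirenz;tenofovir;lamivudine"


def test_reconcile_all_phases_agree_is_identity():
    emr = _phase_visits("dmpa", ART_NVP)
    out = tp.reconcile(emr, emr.copy(), emr.copy())
    assert (out["contraceptive_codes"] == "dmpa").all()
    assert (out["art_drugs"] == ART_NVP).all()


def test_reconcile_interview_overrides_emr_and_chart():
    emr = _phase_visits("dmpa", ART_NVP)
    chart = _phase_visits("dmpa", ART_NVP)
    interview = _phase_visits("implant_etg", ART_NVP)
    out = tp.reconcile(emr, chart, interview)
    assert (out["contraceptive_codes"] == "implant_etg").all()
    assert (out["contraceptive_source"] == "INTERVIEW").all()


def test_reconcile_art_unsure_falls_back_to_chart():
    emr = _phase_visits("dmpa", ART_NVP)
    chart = _phase_visits("dmpa", ART_EFV)
    interview = _phase_visits("dmpa", "unsure")
    out = tp.reconcile(emr, chart, interview)
    assert (out["art_drugs"] == ART_EFV).all()
    assert (out["art_source"] == "CHART").all()
    # the contraceptive still takes the interview value
    assert (out["contraceptive_source"] == "INTERVIEW").all()


def test_reconcile_trims_time_outside_emr_window():
    emr = _phase_visits("dmpa", ART_NVP)  # 2012-01-01 .. 2013-01-01
    chart = make_visits([
        {"woman_id": "A", "visit_date": "2011-06-01", "contraceptive_codes": "dmpa"},
        {"woman_id": "A", "visit_date": "2012-06-01", "contraceptive_codes": "dmpa"},
        {"woman_id": "A", "visit_date": "2014-01-01", "contraceptive_codes": "dmpa"},
    ])
    out = tp.reconcile(emr, chart)
    assert out["visit_date"].tolist() == ["2012-06-01"]


def test_reconcile_rejects_interview_without_chart():
    emr = _phase_visits("dmpa", ART_NVP)
    chart = emr.copy()
    interview = emr.copy()
    interview["woman_id"] = "B"
    with pytest.raises(ValueError, match="nesting"):
        tp.reconcile(emr, chart, interview)


def test_reconcile_pregnancy_precedence():
    emr = _phase_visits("dmpa", ART_NVP, preg=0)
    chart = _phase_visits("dmpa", ART_NVP, preg=0)
    interview = _phase_visits("dmpa", ART_NVP, preg=1, lmp="2012-10-01")
    out = tp.reconcile(emr, chart, interview)
    assert out["preg_reported"].sum() == 1
    assert (out["pregnancy_source"] == "INTERVIEW").all()
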