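"""Shared fixtures: hand-built visit tables and small generated studies."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import threephase as tp


def make_visits(rows):
    """Build a visits DataFrame from compact per-visit dicts.

    Each row needs ``woman_id`` and ``visit_date``; every other column is
    optional (contraceptive_codes/art_drugs default to empty).
    """
    base = {"woman_id": None, "visit_date": None, "contraceptive_codes": "",
            "art_drugs": "", "preg_reported": 0, "lmp_date": None,
            "gest_age_weeks": None, "edd_date": None, "outcome": None,
            "outcome_date": None}
    recs = [{**base, **r} for r in rows]
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def small_study():
    """A 400-woman study with the default (error-prone) configuration."""
    cfg = tp.TruthConfig(n_women=400, seed=42)
    return tp.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_emr_periods(small_study):
    return small_study.emr_cohort().periods
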