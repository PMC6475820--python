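"""CRQ detection, eligibility/washout filters, interest labels, summaries."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from querysignal.cohort import (
    CohortConfig,
    CohortSummary,
    build_cohort,
    cohort_summary,
    is_crq,
    is_indicator,
    is_self_identified,
)
from conftest import make_log
from oracles import brute_cohort, random_log

CFG = CohortConfig()  # October 2017 index, 9-month washout, Sept 1 history cutoff


@pytest.mark.parametrize(
    "text,expected",
    [
        ("celiac disease symptoms", True),
        ("gluten free pancakes", True),
        ("best pizza near me", False),
        ("celiacs in the family", True),   # prefix at word start
        ("glutenfree bread", True),
        ("eggluten something", False),     # not at a word start
        ("", False),
    ],
)
def test_is_crq(text, expected):
    assert is_crq(text) is expected


@pytest.mark.parametrize(
    "text,expected",
    [
        ("marsh score 3b meaning", True),
        ("ttg iga normal range", True),
        ("tissue transglutaminase test", True),
        ("celiac recipes", False),
        ("attgc sequence", False),  # "ttg" must be a standalone word
    ],
)
def test_is_indicator(text, expected):
    assert is_indicator(text) is expected


@pytest.mark.parametrize(
    "text,expected",
    [
        ("i have celiac disease can i eat rice", True),
        ("i was diagnosed with celiac last year", True),
        ("do i have celiac", False),
        ("how do i know if i have celiac", False),
        ("gluten free bread", False),
        ("i have celiacs", True),
    ],
)
def test_is_self_identified(text, expected):
    assert is_self_identified(text) is expected


def test_build_cohort_admits_and_labels():
    """A user with history, an October first CRQ, and two CRQ days is sustained."""
    df = make_log(
        [
            ("u1", "2017-02-03T08:00:00", "weather"),
            ("u1", "2017-10-05T09:00:00", "celiac symptoms"),
            ("u1", "2017-10-09T10:00:00", "gluten free bread"),
        ]
    )
    members, report = build_cohort(df, CFG)
    assert len(members) == 1
    m = members[0]
    assert m.t0 == pd.Timestamp("2017-10-05T09:00:00")
    assert m.crq_day_count == 2
    assert m.interest == "sustained"
    assert report.n_members == 1


def test_build_cohort_exclusions():
    df = make_log(
        [
            # no history before Sept 1
            ("u_nohist", "2017-10-02T09:00:00", "celiac"),
            # CRQ during washout (March) and again in October
            ("u_washout", "2017-01-15T09:00:00", "weather"),
            ("u_washout", "2017-03-01T09:00:00", "gluten intolerance"),
            ("u_washout", "2017-10-05T09:00:00", "celiac"),
            # history but no October CRQ
            ("u_nocrq", "2017-02-01T09:00:00", "weather"),
        ]
    )
    members, report = build_cohort(df, CFG)
    assert members == []
    assert report.excluded_no_history == 1
    assert report.excluded_washout_crq == 1
    assert report.excluded_no_index_crq == 1


def test_empty_log_empty_cohort():
    members, report = build_cohort(make_log([]), CFG)
    assert members == [] and report.n_members == 0


def test_first_crq_tie_broken_by_file_order():
    df = make_log(
        [
            ("u1", "2017-01-02T08:00:00", "history query"),
            ("u1", "2017-10-05T09:00:00", "celiac first in file"),
            ("u1", "2017-10-05T09:00:00", "gluten second in file"),
        ]
    )
    members, _ = build_cohort(df, CFG)
    assert members[0].t0 == pd.Timestamp("2017-10-05T09:00:00")
    assert members[0].interest == "passing"


def test_partition_and_oracle_on_random_logs():
    """build_cohort equals the literal three-criterion scan; labels partition."""
    rng = np.random.default_rng(42)
    for _ in range(10):
        df = random_log(rng, n_users=15, n_queries=150)
        members, _ = build_cohort(df, CFG)
        expected = brute_cohort(df, CFG)
        got = {(m.user_id, m.t0, m.interest, m.crq_day_count) for m in members}
        want = {(m.user_id, m.t0, m.interest, m.crq_day_count) for m in expected}
        assert got == want
        n_pass = sum(m.interest == "passing" for m in members)
        n_sus = sum(m.interest == "sustained" for m in members)
        assert n_pass + n_sus == len(members)


def test_washout_monotonicity():
    """Shrinking the washout can only grow the cohort; extending only shrink it."""
    rng = np.random.default_rng(7)
    df = random_log(rng, n_users=25, n_queries=400)
    sizes = []
    for months in (0, 3, 9):
        cfg = CohortConfig(washout_months=months)
        members, _ = build_cohort(df, cfg)
        sizes.append(len(members))
    assert sizes[0] >= sizes[1] >= sizes[2]


def test_summary_counts_and_rounding():
    members, _ = build_cohort(
        make_log(
            [
                ("a", "2017-03-01T08:00:00", "weather"),
                ("a", "2017-10-02T08:00:00", "celiac"),
                ("b", "2017-03-01T08:00:00", "weather"),
                ("b", "2017-10-02T08:00:00", "celiac"),
                ("b", "2017-10-04T08:00:00", "gluten free flour"),
                ("b", "2017-10-05T08:00:00", "marsh score meaning"),
            ]
        ),
        CFG,
    )
    s = cohort_summary(members)
    d = s.as_dict()
    assert d["n_total"] == 2 and d["n_sustained"] == 1
    assert d["pct_sustained"] == 50
    assert d["pct_indicator_sustained"] == 100.0


def test_summary_from_counts_is_pure_arithmetic():
    s = CohortSummary.from_counts(n_total=200, n_sustained=14, n_indicator_sustained=3)
    d = s.as_dict()
    assert d["pct_sustained"] == 7
    assert d["pct_passing"] == 93
    assert d["pct_indicator_sustained"] == round(100 * 3 / 14, 1)


def test_empty_summary_percentages_undefined():
    d = cohort_summary([]).as_dict()
    assert d["n_total"] == 0
    assert d["pct_passing"] is None and d["pct_sustained"] is None


def test_config_validation():
    with pytest.raises(ValueError):
        CohortConfig(index_start=date(2017, 11, 1), index_end=date(2017, 10, 1))
    with pytest.raises(ValueError):
        CohortConfig(history_cutoff=date(2017, 10, 15))
    assert CFG.washout_start == date(2017, 1, 1)
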