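"""Query-ratio statistics and event-anchored temporal profiles."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from querysignal.cohort import CohortMember
from querysignal.ingest import LogSpan
from querysignal.lexicon import Lexicon
from querysignal.signal import (
    WindowSpec,
    count_in_window,
    query_ratio,
    query_ratio_table,
    rank_concepts,
    temporal_profile,
    QueryRatioResult,
)
from conftest import SPAN_2017, make_log
from oracles import brute_query_ratio, random_log, random_members

LEX = Lexicon(category="symptom", entries={"headache": ["headache", "head ache"],
                                           "diarrhea": ["diarrhea", "loose stools"]})


def _member(uid, t0):
    return CohortMember(user_id=uid, t0=pd.Timestamp(t0), interest="passing",
                        crq_day_count=1, indicator_positive=False, self_identified=False)


def test_count_in_window_before():
    m = _member("u1", "2017-05-20T12:00:00")
    df = make_log(
        [
            ("u1", "2017-05-17T12:00:00", "headache remedy"),     # t0 - 3d
            ("u1", "2017-05-10T12:00:00", "bad headache"),        # t0 - 10d
            ("u1", "2017-05-20T12:00:00", "headache at t0"),      # exactly t0
            ("u1", "2017-05-22T12:00:00", "headache after"),      # after window
        ]
    )
    w = WindowSpec(14)
    assert count_in_window(m, df, LEX, "headache", w.before(m.t0), closed="left") == 2
    assert count_in_window(m, df, LEX, "headache", w.after(m.t0), closed="right") == 1


def test_index_query_in_neither_window():
    m = _member("u1", "2017-05-20T12:00:00")
    df = make_log([("u1", "2017-05-20T12:00:00", "gluten bloating headache")])
    w = WindowSpec(14)
    before = count_in_window(m, df, LEX, "headache", w.before(m.t0), closed="left")
    after = count_in_window(m, df, LEX, "headache", w.after(m.t0), closed="right")
    assert before == 0 and after == 0


def test_query_ratio_arithmetic_and_min_support():
    m = _member("u1", "2017-05-20T12:00:00")
    rows = [("u1", "2017-05-15T12:00:00", "headache") for _ in range(4)]
    rows += [("u1", "2017-05-25T12:00:00", "headache") for _ in range(2)]
    df = make_log(rows)
    res = query_ratio([m], df, LEX, "headache", WindowSpec(14), min_support=2, span=SPAN_2017)
    assert (res.n_before, res.n_after) == (4, 2)
    assert res.qr == 2.0
    res2 = query_ratio([m], df, LEX, "headache", WindowSpec(14), min_support=3, span=SPAN_2017)
    assert res2.qr is None and not res2.defined


def test_unknown_concept_raises():
    with pytest.raises(KeyError):
        query_ratio([], make_log([]), LEX, "nonexistent", span=SPAN_2017)


def test_union_denominator_never_exceeds_one():
    rng = np.random.default_rng(5)
    df = random_log(rng, n_users=10, n_queries=300)
    members = random_members(rng, df, n=6)
    for res in query_ratio_table(members, df, LEX, WindowSpec(14), min_support=1,
                                 denominator="union", span=SPAN_2017):
        if res.defined:
            assert res.qr <= 1.0


def test_rank_concepts_tie_rules():
    def r(cid, qr, nb):
        return QueryRatioResult(cid, "symptom", nb, 10, qr, 1)

    results = [r("b", 1.5, 5), r("a", 2.0, 1), r("c", 1.5, 10), r("d", 1.5, 9),
               QueryRatioResult("undef", "symptom", 3, 0, None, 1)]
    ranked = rank_concepts(results, top_k=3)
    assert [x.concept_id for x in ranked] == ["a", "c", "d"]
    assert rank_concepts([], top_k=5) == []


def test_query_ratio_matches_bruteforce_oracle():
    rng = np.random.default_rng(11)
    for _ in range(10):
        df = random_log(rng, n_users=12, n_queries=250)
        members = random_members(rng, df, n=8)
        for cid in ("headache", "diarrhea"):
            res = query_ratio(members, df, LEX, cid, WindowSpec(14), min_support=1,
                              span=SPAN_2017)
            nb, na = brute_query_ratio(members, df, LEX, cid, WindowSpec(14), SPAN_2017)
            assert (res.n_before, res.n_after) == (nb, na)


def test_window_shift_invariance():
    """Shifting every timestamp and t0 by a constant leaves counts unchanged."""
    rng = np.random.default_rng(3)
    df = random_log(rng, n_users=10, n_queries=200, span=LogSpan(date(2017, 1, 1), date(2017, 9, 30)))
    members = random_members(rng, df, n=5)
    shift = pd.Timedelta(days=17, hours=5)
    df2 = df.copy()
    df2["timestamp"] = df2["timestamp"] + shift
    members2 = [
        CohortMember(m.user_id, m.t0 + shift, m.interest, m.crq_day_count,
                     m.indicator_positive, m.self_identified)
        for m in members
    ]
    span2 = LogSpan(date(2017, 1, 18), date(2017, 11, 17))
    for cid in ("headache", "diarrhea"):
        a = query_ratio(members, df, LEX, cid, WindowSpec(14), min_support=1, span=SPAN_2017)
        b = query_ratio(members2, df2, LEX, cid, WindowSpec(14), min_support=1, span=span2)
        assert (a.n_before, a.n_after) == (b.n_before, b.n_after)


def _uniform_profile_log(rng, n_users, days_around, rate, concept_prob):
    """Users with queries at constant rate around a fixed t0; returns (df, members)."""
    rows = []
    members = []
    t0 = pd.Timestamp("2017-06-01T00:00:00")
    for u in range(n_users):
        uid = f"p{u:03d}"
        n = rng.poisson(rate * 2 * days_around)
        offs = (rng.random(n) * 2 * days_around) - days_around
        hits = rng.random(n) < concept_prob
        for off, hit in zip(offs, hits):
            ts = t0 + pd.Timedelta(days=float(off))
            rows.append((uid, ts.isoformat(), "headache relief" if hit else "weather"))
        members.append(_member(uid, t0))
    return make_log(rows), members


def test_temporal_profile_null_is_flat():
    rng = np.random.default_rng(19)
    df, members = _uniform_profile_log(rng, n_users=60, days_around=30, rate=6.0,
                                       concept_prob=0.1)
    prof = temporal_profile(members, df, LEX, "headache", day_range=30)
    assert abs(prof.mean_ratio() - 1.0) < 0.1


def test_temporal_profile_detects_burst():
    """Tripling the concept rate on days [-5, -1] lifts those ratios above earlier days."""
    rng = np.random.default_rng(23)
    df, members = _uniform_profile_log(rng, n_users=60, days_around=30, rate=6.0,
                                       concept_prob=0.08)
    extra_rows = []
    for m in members:
        n = rng.poisson(2 * 0.16 * 5)  # extra concept queries over the burst days
        offs = -5 + rng.random(n) * 5
        for off in offs:
            ts = m.t0 + pd.Timedelta(days=float(off))
            extra_rows.append((m.user_id, ts.isoformat(), "headache"))
    df2 = pd.concat([df, make_log(extra_rows)], ignore_index=True)
    df2 = df2.sort_values(["user_id", "timestamp"], kind="stable", ignore_index=True)
    prof = temporal_profile(members, df2, LEX, "headache", day_range=30)
    assert prof.mean_ratio(-5, -1) > prof.mean_ratio(-30, -6)


def test_temporal_profile_unqueried_concept_is_empty():
    df = make_log([("u1", "2017-06-01T10:00:00", "weather")])
    prof = temporal_profile([_member("u1", "2017-06-01T00:00:00")], df, LEX,
                            "diarrhea", day_range=5)
    assert prof.empty
    assert prof.table["ratio"].isna().all()


def test_day_binning_day_zero_contains_t0():
    m = _member("u1", "2017-06-01T00:00:00")
    df = make_log(
        [
            ("u1", "2017-06-01T12:00:00", "headache"),   # day 0
            ("u1", "2017-05-31T23:00:00", "headache"),   # day -1
        ]
    )
    prof = temporal_profile([m], df, LEX, "headache", day_range=2)
    t = prof.table.set_index("day")
    assert t.loc[0, "n_concept"] == 1
    assert t.loc[-1, "n_concept"] == 1
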