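"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — literal re-readings of the
definitions (regex scans, per-user double loops) — and shares no code path
with the package internals it checks.
"""

from __future__ import annotations

import re
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from querysignal.cohort import CohortConfig, CohortMember
from querysignal.ingest import LogSpan
from querysignal.lexicon import Lexicon
from querysignal.signal import WindowSpec


def brute_match(norm_text: str, lexicon: Lexicon) -> set[str]:
    """O(phrases x positions) word-boundary scan over every synonym."""
    found = set()
    padded = f" {norm_text} "
    for cid, phrases in lexicon.entries.items():
        for phrase in phrases:
            if f" {phrase} " in padded:
                found.add(cid)
                break
    return found


def brute_is_crq(norm_text: str) -> bool:
    return any(w.startswith("celiac") or w.startswith("gluten") for w in norm_text.split())


def brute_cohort(records: pd.DataFrame, config: CohortConfig) -> list[CohortMember]:
    """Literal per-user application of the three eligibility criteria."""
    members = []
    for uid, sub in records.groupby("user_id"):
        rows = list(zip(sub["timestamp"], sub["norm_text"]))
        has_history = any(t.date() <= config.history_cutoff for t, _ in rows)
        if not has_history:
            continue
        crqs = [(t, txt) for t, txt in rows if brute_is_crq(txt)]
        index_crqs = [t for t, _ in crqs if config.index_start <= t.date() <= config.index_end]
        if not index_crqs:
            continue
        washout_crqs = [
            t for t, _ in crqs if config.washout_start <= t.date() < config.index_start
        ]
        if washout_crqs:
            continue
        t0 = min(index_crqs)
        days = len({t.date() for t, _ in crqs})
        members.append(
            CohortMember(
                user_id=uid,
                t0=pd.Timestamp(t0),
                interest="sustained" if days > 1 else "passing",
                crq_day_count=days,
                indicator_positive=False,
                self_identified=False,
            )
        )
    return members


def brute_query_ratio(
    members: list[CohortMember],
    records: pd.DataFrame,
    lexicon: Lexicon,
    concept_id: str,
    window: WindowSpec,
    span: LogSpan,
) -> tuple[int, int]:
    """Double loop over (member, query); complete-windows truncation."""
    nb = na = 0
    start = pd.Timestamp(span.start_instant)
    end_excl = pd.Timestamp(span.end_instant_exclusive)
    for m in members:
        if m.t0 - window.delta < start or m.t0 + window.delta >= end_excl:
            continue
        sub = records[records["user_id"] == m.user_id]
        for t, txt in zip(sub["timestamp"], sub["norm_text"]):
            if concept_id not in brute_match(txt, lexicon):
                continue
            if m.t0 - window.delta <= t < m.t0:
                nb += 1
            elif m.t0 < t <= m.t0 + window.delta:
                na += 1
    return nb, na


_WORDS = [
    "celiac", "gluten", "bread", "weather", "pizza", "headache", "diarrhea",
    "stools", "loose", "recipe", "news", "flu", "score", "free", "pain",
]


def random_log(
    rng: np.random.Generator,
    n_users: int = 20,
    n_queries: int = 200,
    span: LogSpan | None = None,
) -> pd.DataFrame:
    """A small random word-soup log (includes CRQ-triggering words)."""
    if span is None:
        span = LogSpan(date(2017, 1, 1), date(2017, 10, 31))
    uids = [f"r{u:03d}" for u in rng.integers(0, n_users, size=n_queries)]
    secs = rng.integers(0, span.n_days * 86400, size=n_queries)
    base = datetime.combine(span.start, datetime.min.time())
    stamps = [base + timedelta(seconds=int(s)) for s in secs]
    texts = [
        " ".join(rng.choice(_WORDS, size=rng.integers(1, 5)))
        for _ in range(n_queries)
    ]
    df = pd.DataFrame(
        {
            "user_id": uids,
            "timestamp": pd.to_datetime(stamps),
            "raw_text": texts,
            "norm_text": texts,
            "zip_code": "",
        }
    )
    return df.sort_values(["user_id", "timestamp"], kind="stable", ignore_index=True)


def random_members(
    rng: np.random.Generator, records: pd.DataFrame, n: int = 10
) -> list[CohortMember]:
    """Members with random index times, for window statistics oracles."""
    uids = sorted(records["user_id"].unique())
    if not uids:
        return []
    chosen = rng.choice(uids, size=min(n, len(uids)), replace=False)
    lo = records["timestamp"].min()
    hi = records["timestamp"].max()
    span_s = max(int((hi - lo).total_seconds()), 1)
    members = []
    for uid in sorted(chosen):
        t0 = lo + pd.Timedelta(seconds=int(rng.integers(0, span_s)))
        members.append(
            CohortMember(
                user_id=uid, t0=t0, interest="passing", crq_day_count=1,
                indicator_positive=False, self_identified=False,
            )
        )
    return members
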