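"""Cohort construction: CRQ detection, eligibility/washout filters, labels.

A celiac-related query (CRQ) is any query containing a word that *begins*
with "celiac" or "gluten" ("celiacs", "glutenfree" count; "eggluten" does
not).  A user enters the cohort iff

(a) they have at least one query of any kind on or before the history
    cutoff (observable history),
(b) their first CRQ inside the index period exists (the index event, t0),
(c) they have no CRQ during the washout window immediately before the index
    period.

Members are labelled *passing* (all CRQs on a single calendar day) or
*sustained* (CRQs on more than one day, a proxy for having the condition or
caring for a patient), and flagged for diagnosis-indicator queries
("marsh score", "tissue transglutaminase", ...) and first-person
self-identification ("i have celiac", excluding interrogatives such as
"do i have celiac").
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import pandas as pd

__all__ = [
    "CohortConfig",
    "CohortMember",
    "ExclusionReport",
    "CohortSummary",
    "is_crq",
    "is_indicator",
    "is_self_identified",
    "build_cohort",
    "cohort_summary",
    "write_cohort",
    "read_cohort",
]

# Word starting with either stem, at start of text or after a space.
_CRQ_RE = re.compile(r"(?:^| )(?:celiac|gluten)")

#: Diagnosis-indicator phrases (normalized), including the TTG acronym.
INDICATOR_PHRASES = (
    "marsh score",
    "duodenal biopsy",
    "intestinal biopsy",
    "beyond celiac",
    "celiac disease foundation",
    "tissue transglutaminase",
    "ttg",
    "gliadin antibody",
    "celiac clinical trials",
    "celiac trials",
    "gluten trials",
)

_SELF_ID_PHRASES = ("i have celiac", "i was diagnosed with celiac")

#: Interrogative triggers that veto a self-identification match when they
#: occur anywhere before the matched phrase in the same query.
_INTERROGATIVES = frozenset(
    {"do", "does", "did", "could", "can", "might", "may", "should", "how", "what", "why", "when"}
)


def is_crq(norm_text: str) -> bool:
    """True iff some word of the normalized text starts with "celiac" or "gluten"."""
    return _CRQ_RE.search(norm_text) is not None


def is_indicator(norm_text: str) -> bool:
    """True iff a diagnosis-indicator phrase occurs at word boundaries."""
    padded = f" {norm_text} "
    return any(f" {p} " in padded for p in INDICATOR_PHRASES)


def is_self_identified(norm_text: str) -> bool:
    """True iff the query asserts first-person celiac status.

    Matches "i have celiac" / "i was diagnosed with celiac" (the final word
    may continue, so "i have celiacs" counts), unless an interrogative
    trigger word ("do", "how", ...) occurs anywhere before the matched
    phrase, which marks questions like "do i have celiac".
    """
    start = None
    for phrase in _SELF_ID_PHRASES:
        pos = 0
        while True:
            idx = norm_text.find(phrase, pos)
            if idx < 0:
                break
            if idx == 0 or norm_text[idx - 1] == " ":  # word boundary at the start
                start = idx if start is None else min(start, idx)
                break
            pos = idx + 1
    if start is None:
        return False
    return not any(w in _INTERROGATIVES for w in norm_text[:start].split())


@dataclass(frozen=True)
class CohortConfig:
    """Eligibility parameters for cohort construction.

    The defaults mirror the study design: index period October 2017, nine
    CRQ-free months before it, observable history by September 1, 2017, and
    14-day before/after analysis windows.
    """

    index_start: date = date(2017, 10, 1)
    index_end: date = date(2017, 10, 31)
    washout_months: int = 9
    history_cutoff: date = date(2017, 9, 1)
    window_days: int = 14

    def __post_init__(self) -> None:
        if self.index_start > self.index_end:
            raise ValueError("index_start must not be after index_end")
        if self.history_cutoff > self.index_start:
            raise ValueError("history_cutoff must be on or before index_start")
        if self.washout_months < 0:
            raise ValueError("washout_months must be >= 0")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")

    @property
    def washout_start(self) -> date:
        """First day of the washout window (washout ends at index_start)."""
        ts = pd.Timestamp(self.index_start) - pd.DateOffset(months=self.washout_months)
        return ts.date()


@dataclass(frozen=True)
class CohortMember:
    """A user admitted by the eligibility filters."""

    user_id: str
    t0: pd.Timestamp
    interest: str  # "passing" or "sustained"
    crq_day_count: int
    indicator_positive: bool
    self_identified: bool


@dataclass
class ExclusionReport:
    """Per-criterion exclusion tallies (criteria applied in order a, b, c)."""

    n_users_seen: int = 0
    excluded_no_history: int = 0
    excluded_no_index_crq: int = 0
    excluded_washout_crq: int = 0
    n_members: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def build_cohort(
    records: pd.DataFrame, config: CohortConfig
) -> tuple[list[CohortMember], ExclusionReport]:
    """Apply the three eligibility criteria user-by-user.

    ``records`` is a log frame sorted by (user_id, timestamp); the stable
    sort order makes the first-CRQ tie-break (file order at equal
    timestamps) deterministic.  Returns members sorted by user_id, plus an
    exclusion report.  An empty log yields an empty cohort.
    """
    report = ExclusionReport()
    members: list[CohortMember] = []
    if records.empty:
        return members, report

    df = records
    crq_mask = df["norm_text"].str.contains(_CRQ_RE)
    dates = df["timestamp"].dt.date

    idx_start = config.index_start
    idx_end = config.index_end
    washout_start = config.washout_start

    # Per-user aggregates, computed vectorized then assembled per user.
    first_date = dates.groupby(df["user_id"]).min()
    report.n_users_seen = len(first_date)

    crq = df.loc[crq_mask.to_numpy(), ["user_id", "timestamp", "norm_text"]]
    crq_dates = crq["timestamp"].dt.date

    in_index = (crq_dates >= idx_start) & (crq_dates <= idx_end)
    in_washout = (crq_dates >= washout_start) & (crq_dates < idx_start)

    # first CRQ within the index period: records are stably sorted, so the
    # group's first row is the earliest instant with file-order tie-break.
    first_index_crq = crq.loc[in_index.to_numpy()].groupby("user_id")["timestamp"].first()
    has_washout_crq = crq.loc[in_washout.to_numpy()].groupby("user_id").size()
    crq_day_count = crq_dates.groupby(crq["user_id"]).nunique()

    # memoize the per-text predicates over distinct texts (logs repeat heavily)
    uniq = pd.unique(df["norm_text"])
    ind_cache = {t: is_indicator(t) for t in uniq}
    self_cache = {t: is_self_identified(t) for t in uniq}
    ind_mask = df["norm_text"].map(ind_cache)
    self_mask = df["norm_text"].map(self_cache)
    has_indicator = ind_mask.groupby(df["user_id"]).any()
    has_self_id = self_mask.groupby(df["user_id"]).any()

    for user_id, fdate in first_date.items():
        if fdate > config.history_cutoff:
            report.excluded_no_history += 1
            continue
        t0 = first_index_crq.get(user_id)
        if t0 is None:
            report.excluded_no_index_crq += 1
            continue
        if has_washout_crq.get(user_id, 0) > 0:
            report.excluded_washout_crq += 1
            continue
        days = int(crq_day_count[user_id])
        members.append(
            CohortMember(
                user_id=user_id,
                t0=t0,
                interest="sustained" if days > 1 else "passing",
                crq_day_count=days,
                indicator_positive=bool(has_indicator[user_id]),
                self_identified=bool(has_self_id[user_id]),
            )
        )
    report.n_members = len(members)
    return members, report


def _pct(numer: int, denom: int, decimals: int) -> float | None:
    if denom == 0:
        return None
    return round(100.0 * numer / denom, decimals) if decimals else float(round(100.0 * numer / denom))


@dataclass
class CohortSummary:
    """Counts and rounded rates for the passing/sustained split.

    Interest-split percentages are rounded to the nearest integer;
    indicator-positive rates to one decimal; self-identification rates to
    two decimals.  All rates come with explicit denominators (the interest
    class for within-class rates, the whole cohort for overall rates).
    """

    n_total: int
    n_passing: int
    n_sustained: int
    n_indicator_passing: int
    n_indicator_sustained: int
    n_self_identified_passing: int
    n_self_identified_sustained: int

    @property
    def n_self_identified_total(self) -> int:
        return self.n_self_identified_passing + self.n_self_identified_sustained

    @property
    def n_indicator_total(self) -> int:
        return self.n_indicator_passing + self.n_indicator_sustained

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_passing": self.n_passing,
            "n_sustained": self.n_sustained,
            "pct_passing": _pct(self.n_passing, self.n_total, 0),
            "pct_sustained": _pct(self.n_sustained, self.n_total, 0),
            "n_indicator_passing": self.n_indicator_passing,
            "n_indicator_sustained": self.n_indicator_sustained,
            "pct_indicator_passing": _pct(self.n_indicator_passing, self.n_passing, 1),
            "pct_indicator_sustained": _pct(self.n_indicator_sustained, self.n_sustained, 1),
            "n_self_identified_passing": self.n_self_identified_passing,
            "n_self_identified_sustained": self.n_self_identified_sustained,
            "n_self_identified_total": self.n_self_identified_total,
            "pct_self_identified_passing": _pct(self.n_self_identified_passing, self.n_passing, 2),
            "pct_self_identified_sustained": _pct(
                self.n_self_identified_sustained, self.n_sustained, 2
            ),
            "pct_self_identified_total": _pct(self.n_self_identified_total, self.n_total, 2),
        }

    @classmethod
    def from_counts(
        cls,
        n_total: int,
        n_sustained: int,
        n_indicator_sustained: int = 0,
        n_indicator_passing: int = 0,
        n_self_identified_sustained: int = 0,
        n_self_identified_passing: int = 0,
    ) -> "CohortSummary":
        return cls(
            n_total=n_total,
            n_passing=n_total - n_sustained,
            n_sustained=n_sustained,
            n_indicator_passing=n_indicator_passing,
            n_indicator_sustained=n_indicator_sustained,
            n_self_identified_passing=n_self_identified_passing,
            n_self_identified_sustained=n_self_identified_sustained,
        )


def cohort_summary(members: list[CohortMember]) -> CohortSummary:
    """Summarize a cohort into counts and rounded percentages."""
    passing = [m for m in members if m.interest == "passing"]
    sustained = [m for m in members if m.interest == "sustained"]
    return CohortSummary(
        n_total=len(members),
        n_passing=len(passing),
        n_sustained=len(sustained),
        n_indicator_passing=sum(m.indicator_positive for m in passing),
        n_indicator_sustained=sum(m.indicator_positive for m in sustained),
        n_self_identified_passing=sum(m.self_identified for m in passing),
        n_self_identified_sustained=sum(m.self_identified for m in sustained),
    )


def write_cohort(members: list[CohortMember], path: str | Path) -> None:
    """Write a cohort table (TSV with header)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("user_id\tt0\tinterest\tcrq_day_count\tindicator_positive\tself_identified\n")
        for m in members:
            fh.write(
                f"{m.user_id}\t{m.t0.strftime('%Y-%m-%dT%H:%M:%S')}\t{m.interest}\t"
                f"{m.crq_day_count}\t{int(m.indicator_positive)}\t{int(m.self_identified)}\n"
            )


def read_cohort(path: str | Path) -> list[CohortMember]:
    """Read a cohort table written by :func:`write_cohort`."""
    df = pd.read_csv(path, sep="\t", dtype={"user_id": str})
    return [
        CohortMember(
            user_id=row.user_id,
            t0=pd.Timestamp(row.t0),
            interest=row.interest,
            crq_day_count=int(row.crq_day_count),
            indicator_positive=bool(row.indicator_positive),
            self_identified=bool(row.self_identified),
        )
        for row in df.itertuples()
    ]
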