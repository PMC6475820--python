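"""Before/after query-ratio statistics and event-anchored temporal profiles.

For every cohort member the index event t0 (first CRQ) anchors two disjoint
windows of ``w`` days: before = [t0 − w, t0) and after = (t0, t0 + w]; the
index query itself belongs to neither.  The query ratio (QR) for a concept
is the pooled count of concept-matching queries in the before-windows
divided by the pooled count in the after-windows — a QR above 1 means the
concept was searched more in the run-up to the index event than after it.

Pooling sums raw counts over members (not a mean of per-user ratios, which
are mostly 0/0 on sparse logs).  By default members whose windows are not
fully contained in the log span are excluded ("complete-windows"
truncation), so late-index adopters do not systematically deflate the
after-window denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from querysignal.cohort import CohortMember
from querysignal.ingest import LogSpan
from querysignal.lexicon import Lexicon, match_concept_ids_bulk

__all__ = [
    "WindowSpec",
    "QueryRatioResult",
    "TemporalProfile",
    "count_in_window",
    "query_ratio",
    "query_ratio_table",
    "rank_concepts",
    "temporal_profile",
    "plot_temporal_profile",
]

TruncationPolicy = Literal["complete-windows", "all"]
Denominator = Literal["after", "union"]


@dataclass(frozen=True)
class WindowSpec:
    """Half-window length for before/after analyses (default 14 days)."""

    w: int = 14

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("window length must be >= 1 day")

    @property
    def delta(self) -> pd.Timedelta:
        return pd.Timedelta(days=self.w)

    def before(self, t0: pd.Timestamp) -> tuple[pd.Timestamp, pd.Timestamp]:
        """Half-open interval [t0 - w, t0)."""
        return t0 - self.delta, t0

    def after(self, t0: pd.Timestamp) -> tuple[pd.Timestamp, pd.Timestamp]:
        """Half-open interval (t0, t0 + w]."""
        return t0, t0 + self.delta

    def is_complete(self, t0: pd.Timestamp, span: LogSpan) -> bool:
        """Both windows fully contained in the log span."""
        return (
            t0 - self.delta >= pd.Timestamp(span.start_instant)
            and t0 + self.delta < pd.Timestamp(span.end_instant_exclusive)
        )


@dataclass(frozen=True)
class QueryRatioResult:
    """Per-concept pooled before/after counts and their ratio.

    ``qr`` is None (undefined) when the denominator has fewer than
    ``min_support`` pooled counts; undefined ratios are excluded from
    rankings rather than topping them.
    """

    concept_id: str
    category: str
    n_before: int
    n_after: int
    qr: float | None
    n_users_contributing: int

    @property
    def defined(self) -> bool:
        return self.qr is not None

    @property
    def standard_error(self) -> float | None:
        """Delta-method SE of the ratio, treating both counts as Poisson."""
        if self.qr is None or self.n_before == 0 or self.n_after == 0:
            return None
        return self.qr * math.sqrt(1.0 / self.n_before + 1.0 / self.n_after)


def _user_groups(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {uid: sub for uid, sub in records.groupby("user_id", sort=False)}


def count_in_window(
    member: CohortMember,
    user_records: pd.DataFrame,
    lexicon: Lexicon,
    concept_id: str,
    interval: tuple[pd.Timestamp, pd.Timestamp],
    closed: str = "left",
) -> int:
    """Count the member's queries in ``interval`` whose matches contain the concept.

    ``closed`` is "left" for the before-window [start, end) and "right" for
    the after-window (start, end].  Queries that are themselves CRQs still
    count when they also match the concept.
    """
    ts = user_records["timestamp"]
    if closed == "left":
        mask = (ts >= interval[0]) & (ts < interval[1])
    elif closed == "right":
        mask = (ts > interval[0]) & (ts <= interval[1])
    else:
        raise ValueError("closed must be 'left' or 'right'")
    if not mask.any():
        return 0
    sets = match_concept_ids_bulk(user_records.loc[mask.to_numpy(), "norm_text"], lexicon)
    return int(sum(concept_id in s for s in sets))


def _pooled_window_counts(
    members: list[CohortMember],
    records: pd.DataFrame,
    lexicon: Lexicon,
    window: WindowSpec,
    span: LogSpan | None,
    truncation_policy: TruncationPolicy,
) -> tuple[dict[str, int], dict[str, int], dict[str, set[str]], dict[str, int]]:
    """Pool before/after concept counts over admitted members.

    Returns (n_before, n_after, contributing users, n_at_t0) keyed by
    concept id; n_at_t0 counts index-instant queries, needed only for the
    union-denominator variant.
    """
    if span is None:
        span = _infer_span(records)
    groups = _user_groups(records)
    n_before: dict[str, int] = {}
    n_after: dict[str, int] = {}
    n_t0: dict[str, int] = {}
    users: dict[str, set[str]] = {}
    cache: dict[str, frozenset[str]] = {}
    for member in members:
        if truncation_policy == "complete-windows" and not window.is_complete(member.t0, span):
            continue
        sub = groups.get(member.user_id)
        if sub is None:
            continue
        ts = sub["timestamp"]
        lo, t0, hi = member.t0 - window.delta, member.t0, member.t0 + window.delta
        in_any = (ts >= lo) & (ts <= hi)
        if not in_any.any():
            continue
        win = sub.loc[in_any.to_numpy()]
        sets = match_concept_ids_bulk(win["norm_text"], lexicon, cache=cache)
        for t, concepts in zip(win["timestamp"], sets):
            if not concepts:
                continue
            if t < t0:
                bucket = n_before
            elif t > t0:
                bucket = n_after
            else:
                bucket = n_t0
            for cid in concepts:
                bucket[cid] = bucket.get(cid, 0) + 1
                if bucket is not n_t0:
                    users.setdefault(cid, set()).add(member.user_id)
    return n_before, n_after, users, n_t0


def _infer_span(records: pd.DataFrame) -> LogSpan:
    if records.empty:
        raise ValueError("cannot infer a log span from an empty record set")
    dates = records["timestamp"].dt.date
    return LogSpan(start=dates.min(), end=dates.max())


def query_ratio_table(
    members: list[CohortMember],
    records: pd.DataFrame,
    lexicon: Lexicon,
    window: WindowSpec = WindowSpec(),
    min_support: int = 10,
    truncation_policy: TruncationPolicy = "complete-windows",
    denominator: Denominator = "after",
    span: LogSpan | None = None,
    laplace: bool = False,
) -> list[QueryRatioResult]:
    """Query-ratio results for every concept in the lexicon.

    ``denominator="after"`` is the headline statistic (before / after);
    ``"union"`` divides by the count over the whole [t0 − w, t0 + w] range
    (including the index instant) instead.  With ``laplace`` a +0.5
    additive smoothing is applied to both counts of the ratio.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    nb, na, users, nt0 = _pooled_window_counts(
        members, records, lexicon, window, span, truncation_policy
    )
    results = []
    for cid in lexicon.concept_ids:
        b = nb.get(cid, 0)
        a = na.get(cid, 0)
        denom = a if denominator == "after" else b + a + nt0.get(cid, 0)
        if denom >= min_support:
            qr = (b + 0.5) / (denom + 0.5) if laplace else b / denom
        else:
            qr = None
        results.append(
            QueryRatioResult(
                concept_id=cid,
                category=lexicon.category,
                n_before=b,
                n_after=a,
                qr=qr,
                n_users_contributing=len(users.get(cid, ())),
            )
        )
    return results


def query_ratio(
    members: list[CohortMember],
    records: pd.DataFrame,
    lexicon: Lexicon,
    concept_id: str,
    window: WindowSpec = WindowSpec(),
    min_support: int = 10,
    truncation_policy: TruncationPolicy = "complete-windows",
    denominator: Denominator = "after",
    span: LogSpan | None = None,
    laplace: bool = False,
) -> QueryRatioResult:
    """Query ratio for a single concept (see :func:`query_ratio_table`)."""
    if concept_id not in lexicon:
        raise KeyError(f"unknown concept {concept_id!r} for category {lexicon.category!r}")
    table = query_ratio_table(
        members, records, lexicon, window, min_support, truncation_policy, denominator, span, laplace
    )
    return next(r for r in table if r.concept_id == concept_id)


def rank_concepts(
    results: list[QueryRatioResult], top_k: int | None = 10
) -> list[QueryRatioResult]:
    """Rank defined results descending by QR.

    Ties broken by larger pooled before-count, then lexicographic concept
    id.  Undefined ratios (below min_support) are filtered out.
    """
    defined = [r for r in results if r.defined]
    ranked = sorted(defined, key=lambda r: (-r.qr, -r.n_before, r.concept_id))
    return ranked if top_k is None else ranked[:top_k]


@dataclass
class TemporalProfile:
    """Event-anchored per-day concept-query fractions, normalized.

    ``table`` has one row per day offset d in [-D, D] with columns
    ``day`` (floor of the signed day difference from t0, so d = 0 covers
    [t0, t0 + 1 day)), ``n_concept``, ``n_all`` and ``ratio``.  ``ratio`` is
    the day's concept fraction divided by the overall concept fraction
    across the profile range; values above 1 mean the concept is more
    common at that offset than expected.  Rows where no queries fall (or a
    concept never queried at all) leave ``ratio`` as NaN.
    """

    concept_id: str
    table: pd.DataFrame
    baseline: float

    @property
    def empty(self) -> bool:
        return self.baseline == 0.0

    def mean_ratio(self, day_lo: int | None = None, day_hi: int | None = None) -> float:
        """Mean of defined ratios over an (inclusive) offset range."""
        t = self.table
        mask = t["ratio"].notna()
        if day_lo is not None:
            mask &= t["day"] >= day_lo
        if day_hi is not None:
            mask &= t["day"] <= day_hi
        return float(t.loc[mask, "ratio"].mean())


def temporal_profile(
    members: list[CohortMember],
    records: pd.DataFrame,
    lexicon: Lexicon,
    concept_id: str,
    day_range: int = 30,
) -> TemporalProfile:
    """Pool members' queries by whole-day offset from t0 and normalize.

    Day offsets are floor((t - t0) / 1 day) restricted to [-D, D].  The
    baseline is the concept's overall query fraction across the profile
    range, so under a constant concept rate every defined ratio is ≈ 1.
    """
    if day_range < 1:
        raise ValueError("day_range must be >= 1")
    if concept_id not in lexicon:
        raise KeyError(f"unknown concept {concept_id!r} for category {lexicon.category!r}")
    D = day_range
    days = np.arange(-D, D + 1)
    n_all = np.zeros(2 * D + 1, dtype=np.int64)
    n_concept = np.zeros(2 * D + 1, dtype=np.int64)
    groups = _user_groups(records)
    one_day = pd.Timedelta(days=1)
    cache: dict[str, frozenset[str]] = {}
    for member in members:
        sub = groups.get(member.user_id)
        if sub is None:
            continue
        offs = ((sub["timestamp"] - member.t0) // one_day).to_numpy()
        in_range = (offs >= -D) & (offs <= D)
        if not in_range.any():
            continue
        offs = offs[in_range]
        sets = match_concept_ids_bulk(sub.loc[in_range, "norm_text"], lexicon, cache=cache)
        hits = np.fromiter((concept_id in s for s in sets), dtype=bool, count=len(offs))
        np.add.at(n_all, offs + D, 1)
        np.add.at(n_concept, offs[hits] + D, 1)

    total_all = int(n_all.sum())
    total_concept = int(n_concept.sum())
    baseline = total_concept / total_all if total_all else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_all > 0, n_concept / np.maximum(n_all, 1), np.nan)
        ratio = frac / baseline if baseline > 0 else np.full_like(frac, np.nan)
    table = pd.DataFrame(
        {"day": days, "n_concept": n_concept, "n_all": n_all, "ratio": ratio}
    )
    return TemporalProfile(concept_id=concept_id, table=table, baseline=baseline)


def plot_temporal_profile(profile: TemporalProfile, ax=None):
    """Plot an event-anchored profile (ratio vs day offset) and return the Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = profile.table
    ax.plot(t["day"], t["ratio"], marker="o", ms=3, lw=1)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("days from first celiac-related query")
    ax.set_ylabel("normalized query fraction")
    ax.set_title(profile.concept_id)
    return ax
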