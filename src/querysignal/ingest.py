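"""Reading, validating and normalizing per-user query-log records.

The on-disk format is a headerless UTF-8 TSV with four columns:
``user_id``, ISO-8601 timestamp (``YYYY-MM-DDTHH:MM:SS``), query text, and an
optional 5-character zip code.  Records are carried in memory as a pandas
DataFrame with one row per query, sorted by ``(user_id, timestamp)`` with a
stable sort so that ties at identical timestamps preserve file order (this
makes the downstream "first celiac-related query" deterministic).

Timestamps are timezone-naive and interpreted in a single log-local clock;
all day-level logic uses calendar dates taken from that clock.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "QueryRecord",
    "LogSpan",
    "RejectionReport",
    "IngestError",
    "normalize_text",
    "read_query_log",
    "records_to_dataframe",
    "write_query_log",
    "LOG_COLUMNS",
]

#: Column order of the in-memory query-log DataFrame.
LOG_COLUMNS = ["user_id", "timestamp", "raw_text", "norm_text", "zip_code"]

_NON_ALNUM = re.compile(r"[^0-9a-z]+")


class IngestError(RuntimeError):
    """Fatal problem while reading a query log."""


def normalize_text(raw: str) -> str:
    """Normalize free query text.

    Lowercases, replaces every maximal run of non-alphanumeric characters
    (punctuation, hyphens, whitespace) by a single space, and strips leading
    and trailing spaces.  The map is idempotent, and collapsing hyphens means
    "gluten-free" and "gluten free" normalize identically, so phrase matching
    hits both surface forms.
    """
    return _NON_ALNUM.sub(" ", raw.lower()).strip()


@dataclass(frozen=True)
class QueryRecord:
    """One search event."""

    user_id: str
    timestamp: datetime
    raw_text: str
    norm_text: str
    zip_code: str | None = None


@dataclass(frozen=True)
class LogSpan:
    """Inclusive calendar-date span covered by a query log."""

    start: date
    end: date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"LogSpan start {self.start} is after end {self.end}")

    def contains(self, d: date) -> bool:
        return self.start <= d <= self.end

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    @property
    def start_instant(self) -> datetime:
        """First instant of the span (midnight of the start date)."""
        return datetime.combine(self.start, datetime.min.time())

    @property
    def end_instant_exclusive(self) -> datetime:
        """First instant *after* the span (midnight following the end date)."""
        return datetime.combine(self.end + timedelta(days=1), datetime.min.time())


@dataclass
class RejectionReport:
    """Per-reason tallies of log lines dropped during ingest."""

    n_lines: int = 0
    n_accepted: int = 0
    wrong_column_count: int = 0
    bad_timestamp: int = 0
    out_of_span: int = 0
    empty_text: int = 0

    @property
    def n_rejected(self) -> int:
        return self.wrong_column_count + self.bad_timestamp + self.out_of_span + self.empty_text

    def as_dict(self) -> dict:
        return {
            "n_lines": self.n_lines,
            "n_accepted": self.n_accepted,
            "n_rejected": self.n_rejected,
            "wrong_column_count": self.wrong_column_count,
            "bad_timestamp": self.bad_timestamp,
            "out_of_span": self.out_of_span,
            "empty_text": self.empty_text,
        }


def read_query_log(
    path: str | Path,
    span: LogSpan,
    header: bool = False,
) -> tuple[pd.DataFrame, RejectionReport]:
    """Read a TSV query log into the pipeline's data model.

    Parameters
    ----------
    path
        TSV file with columns user_id, timestamp, query text, zip code.
    span
        Accepted calendar-date range; records dated outside it are counted
        and dropped.
    header
        If True, skip one header line.

    Returns
    -------
    (DataFrame, RejectionReport)
        The frame has columns :data:`LOG_COLUMNS`, stably sorted by
        ``(user_id, timestamp)``.  Accepted + rejected always equals the
        number of data lines read.

    Raises
    ------
    IngestError
        If the file cannot be read, or more than half of its lines are
        rejected (which usually means a wrong dialect).
    """
    path = Path(path)
    try:
        raw = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise IngestError(f"cannot read query log {path}: {exc}") from exc

    report = RejectionReport()
    users: list[str] = []
    stamps: list[datetime] = []
    raws: list[str] = []
    norms: list[str] = []
    zips: list[str] = []

    lines = raw.splitlines()
    if header and lines:
        lines = lines[1:]
    for line in lines:
        report.n_lines += 1
        parts = line.split("\t")
        if len(parts) != 4:
            report.wrong_column_count += 1
            continue
        user_id, ts_text, text, zip_code = parts
        try:
            ts = datetime.fromisoformat(ts_text)
        except ValueError:
            report.bad_timestamp += 1
            continue
        if not span.contains(ts.date()):
            report.out_of_span += 1
            continue
        norm = normalize_text(text)
        if not norm:
            report.empty_text += 1
            continue
        report.n_accepted += 1
        users.append(user_id)
        stamps.append(ts)
        raws.append(text)
        norms.append(norm)
        zips.append(zip_code)

    if report.n_lines and report.n_rejected > 0.5 * report.n_lines:
        raise IngestError(
            f"{report.n_rejected}/{report.n_lines} lines rejected reading {path}; "
            "this looks like the wrong file dialect"
        )

    df = pd.DataFrame(
        {
            "user_id": pd.Series(users, dtype="object"),
            "timestamp": pd.to_datetime(stamps),
            "raw_text": pd.Series(raws, dtype="object"),
            "norm_text": pd.Series(norms, dtype="object"),
            "zip_code": pd.Series(zips, dtype="object"),
        }
    )
    df = df.sort_values(["user_id", "timestamp"], kind="stable", ignore_index=True)
    return df, report


def records_to_dataframe(records: Iterable[QueryRecord]) -> pd.DataFrame:
    """Build the standard log frame from :class:`QueryRecord` objects."""
    rows = list(records)
    df = pd.DataFrame(
        {
            "user_id": [r.user_id for r in rows],
            "timestamp": pd.to_datetime([r.timestamp for r in rows]),
            "raw_text": [r.raw_text for r in rows],
            "norm_text": [r.norm_text for r in rows],
            "zip_code": [r.zip_code if r.zip_code is not None else "" for r in rows],
        }
    )
    return df.sort_values(["user_id", "timestamp"], kind="stable", ignore_index=True)


def write_query_log(df: pd.DataFrame, path: str | Path) -> None:
    """Write a log frame back to the on-disk TSV format (round-trip safe)."""
    path = Path(path)
    ts = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    zips = df["zip_code"].fillna("").astype(str)
    with open(path, "w", encoding="utf-8") as fh:
        for u, t, q, z in zip(df["user_id"], ts, df["raw_text"], zips):
            fh.write(f"{u}\t{t}\t{q}\t{z}\n")
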