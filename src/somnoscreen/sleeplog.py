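"""Data model and I/O for 14-day sleep logs.

A sleep log is a parent/teacher diary of a child's sleep over 14 consecutive
days.  Internally each log is rasterized onto a binary epoch grid: 14 logical
days x 288 five-minute epochs, state 0 = asleep, 1 = awake.  A logical day is
anchored at 03:00 local time and covers decimal hours [3.0, 27.0), so both the
morning wake-up window (3-10 h) and the evening bed-time window (18-26 h) fall
inside a single logical day and times after midnight are represented on a
24h-extended scale (e.g. 1:27 am -> 25.45).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Grid geometry
N_DAYS = 14
EPOCH_MINUTES = 5
EPOCHS_PER_DAY = 288          # 24 h at 5-min resolution
DAY_START_HOUR = 3.0          # logical day covers [3.0, 27.0)
DAY_END_HOUR = 27.0
MINUTES_PER_DAY = EPOCHS_PER_DAY * EPOCH_MINUTES

ASLEEP = 0
AWAKE = 1
MISSING = -1

# Screening default: reject a log with more than this many missing days.
DEFAULT_MAX_MISSING_DAYS = 3


class SleepLogError(Exception):
    """Base class for sleep-log data errors."""


class SleepLogParseError(SleepLogError):
    """A CSV row could not be parsed."""


class SleepLogValidationError(SleepLogError):
    """Intervals are contradictory or fall outside the recorded span."""


_TIME_RE = re.compile(r"^(\d{1,2}):(\d{2})$")


def parse_clock_time(text: str) -> float:
    """Parse "HH:MM" to decimal hours in [0, 24)."""
    m = _TIME_RE.match(str(text).strip())
    if not m:
        raise SleepLogParseError(f"malformed time {text!r} (expected HH:MM)")
    hh, mm = int(m.group(1)), int(m.group(2))
    if hh >= 24 or mm >= 60:
        raise SleepLogParseError(f"clock time out of range: {text!r}")
    return hh + mm / 60.0


def format_clock_time(hours: float) -> str:
    """Decimal hours (possibly on the 24h-extended scale) to "HH:MM"."""
    total = int(round((hours % 24.0) * 60))
    return f"{total // 60:02d}:{total % 60:02d}"


@dataclass(frozen=True)
class SleepInterval:
    """One contiguous sleep period, anchored to the calendar date it starts on.

    ``start`` is in [0, 24); ``end`` may exceed 24 when the interval runs into
    the next calendar day.
    """

    child_id: str
    date: dt.date
    start: float
    end: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.start < 24.0):
            raise SleepLogValidationError(
                f"{self.child_id} {self.date}: start {self.start} not in [0, 24)")
        dur = self.end - self.start
        if dur <= 0:
            raise SleepLogValidationError(
                f"{self.child_id} {self.date}: non-positive duration "
                f"({self.start} -> {self.end})")
        if dur > 24.0:
            raise SleepLogValidationError(
                f"{self.child_id} {self.date}: duration {dur:.2f} h exceeds 24 h")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class DailyFlags:
    """Per-day diary flags: breakfast eaten, woke by self, reported night wakings."""

    child_id: str
    date: dt.date
    breakfast: int | None = None
    self_awake: int | None = None
    reported_night_wakings: int | None = None


@dataclass(frozen=True)
class ChildMeta:
    child_id: str
    age_months: int
    start_date: dt.date
    sex: str | None = None


@dataclass
class SleepLog:
    """A child's rasterized 14-day sleep record."""

    child_id: str
    age_months: int
    start_date: dt.date
    grid: np.ndarray                      # (14, 288) int8; 0/1/MISSING
    flags: list[DailyFlags | None]        # one entry per logical day
    sex: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.shape != (N_DAYS, EPOCHS_PER_DAY):
            raise SleepLogValidationError(
                f"grid shape {self.grid.shape} != ({N_DAYS}, {EPOCHS_PER_DAY})")
        if len(self.flags) != N_DAYS:
            raise SleepLogValidationError("flags must have one entry per day")
        bad = ~np.isin(self.grid, (ASLEEP, AWAKE, MISSING))
        if bad.any():
            raise SleepLogValidationError("grid states must be 0, 1 or missing")

    @property
    def missing_days(self) -> list[int]:
        return [d for d in range(N_DAYS) if (self.grid[d] == MISSING).all()]

    @property
    def day_dates(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(days=d) for d in range(N_DAYS)]


@dataclass
class Cohort:
    """Ordered collection of sleep logs with optional binary quality labels.

    Label convention: 1 = no severe sleep disorder, 0 = severe disorder.
    """

    logs: list[SleepLog]
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [log.child_id for log in self.logs]
        if len(set(ids)) != len(ids):
            raise SleepLogValidationError("duplicate child_id in cohort")

    def __len__(self) -> int:
        return len(self.logs)

    def __iter__(self):
        return iter(self.logs)


@dataclass
class ValidationReport:
    child_id: str
    complete: bool
    missing_days: list[dt.date]
    issues: list[str]


# ---------------------------------------------------------------------------
# CSV readers (see module docs for the schemas)
# ---------------------------------------------------------------------------

def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SleepLogParseError(f"{what}: missing column(s) {missing}")


def read_intervals(path) -> list[SleepInterval]:
    """Read sleep intervals from CSV: child_id,date,start,end,next_day."""
    df = _read_csv(path)
    _require_columns(df, ("child_id", "date", "start", "end", "next_day"),
                     "intervals")
    out: list[SleepInterval] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            date = dt.date.fromisoformat(str(row.date).strip())
            start = parse_clock_time(row.start)
            end = parse_clock_time(row.end)
            next_day = int(row.next_day)
            if next_day not in (0, 1):
                raise SleepLogParseError(f"next_day must be 0/1, got {row.next_day!r}")
            if next_day:
                end += 24.0
            elif end <= start:
                raise SleepLogParseError(
                    f"end {row.end} <= start {row.start} without next_day marker")
            out.append(SleepInterval(str(row.child_id), date, start, end))
        except (SleepLogError, ValueError) as exc:
            raise SleepLogParseError(f"intervals row {i}: {exc}") from exc
    return out


def _parse_optional_int(value, what: str, row: int, binary: bool = False) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if text == "" or text.lower() == "nan":
        return None
    try:
        v = int(float(text))
    except ValueError as exc:
        raise SleepLogParseError(f"daily row {row}: bad {what} {value!r}") from exc
    if binary and v not in (0, 1):
        raise SleepLogParseError(f"daily row {row}: {what} must be 0/1, got {v}")
    if not binary and v < 0:
        raise SleepLogParseError(f"daily row {row}: {what} must be >= 0, got {v}")
    return v


def read_daily(path) -> list[DailyFlags]:
    """Read daily flags from CSV: child_id,date,breakfast,self_awake,night_wakings."""
    df = _read_csv(path)
    _require_columns(df, ("child_id", "date", "breakfast", "self_awake",
                          "night_wakings"), "daily")
    out: list[DailyFlags] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            date = dt.date.fromisoformat(str(row.date).strip())
        except ValueError as exc:
            raise SleepLogParseError(f"daily row {i}: bad date {row.date!r}") from exc
        out.append(DailyFlags(
            child_id=str(row.child_id),
            date=date,
            breakfast=_parse_optional_int(row.breakfast, "breakfast", i, binary=True),
            self_awake=_parse_optional_int(row.self_awake, "self_awake", i, binary=True),
            reported_night_wakings=_parse_optional_int(
                row.night_wakings, "night_wakings", i),
        ))
    return out


def read_children(path) -> list[ChildMeta]:
    """Read child metadata from CSV: child_id,age_months,sex,start_date."""
    df = _read_csv(path)
    _require_columns(df, ("child_id", "age_months", "sex", "start_date"), "children")
    out: list[ChildMeta] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            age = int(float(row.age_months))
            start = dt.date.fromisoformat(str(row.start_date).strip())
        except ValueError as exc:
            raise SleepLogParseError(f"children row {i}: {exc}") from exc
        sex = None
        if isinstance(row.sex, str) and row.sex.strip():
            sex = row.sex.strip()
        out.append(ChildMeta(str(row.child_id), age, start, sex))
    return out


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def build_log(meta: ChildMeta,
              intervals: list[SleepInterval],
              flags: list[DailyFlags] | None = None) -> SleepLog:
    """Rasterize one child's intervals and flags onto the 14x288 epoch grid.

    A 5-minute epoch is asleep iff its half-open window is fully covered by
    recorded sleep; partial coverage counts as awake.  Interval times are
    resolved on a 1-minute mask (diary times are whole minutes, so this is
    exact).  A logical day with no interval rows and no flag row dated on it
    is marked missing.  Overlapping intervals are contradictory records and
    raise; an interval running past the final day's 27:00 grid edge is
    clipped, one entirely outside the 14-day span raises.
    """
    flags = flags or []
    intervals = [iv for iv in intervals if iv.child_id == meta.child_id]
    flags = [f for f in flags if f.child_id == meta.child_id]

    span_minutes = N_DAYS * MINUTES_PER_DAY          # from 03:00 of start_date
    coverage = np.zeros(span_minutes, dtype=np.int16)

    recorded_dates: set[dt.date] = set()
    for iv in intervals:
        offset_days = (iv.date - meta.start_date).days
        s = round((offset_days * 24.0 + iv.start - DAY_START_HOUR) * 60)
        e = round((offset_days * 24.0 + iv.end - DAY_START_HOUR) * 60)
        if e <= 0 or s >= span_minutes:
            raise SleepLogValidationError(
                f"{meta.child_id}: interval {iv.date} "
                f"{format_clock_time(iv.start)}-{format_clock_time(iv.end)} "
                f"outside the {N_DAYS}-day span starting {meta.start_date}")
        coverage[max(s, 0):min(e, span_minutes)] += 1
        recorded_dates.add(iv.date)

    if (coverage > 1).any():
        first = int(np.argmax(coverage > 1))
        when = meta.start_date + dt.timedelta(hours=DAY_START_HOUR + first / 60.0)
        raise SleepLogValidationError(
            f"{meta.child_id}: overlapping sleep intervals around {when}")

    asleep = coverage.astype(bool).reshape(N_DAYS, EPOCHS_PER_DAY, EPOCH_MINUTES)
    grid = np.where(asleep.all(axis=2), ASLEEP, AWAKE).astype(np.int8)

    flags_by_date = {f.date: f for f in flags}
    day_flags: list[DailyFlags | None] = []
    for d in range(N_DAYS):
        date = meta.start_date + dt.timedelta(days=d)
        day_flags.append(flags_by_date.get(date))
        if date not in recorded_dates and date not in flags_by_date:
            grid[d, :] = MISSING

    return SleepLog(child_id=meta.child_id, age_months=meta.age_months,
                    start_date=meta.start_date, grid=grid, flags=day_flags,
                    sex=meta.sex)


def build_cohort(children: list[ChildMeta],
                 intervals: list[SleepInterval],
                 flags: list[DailyFlags],
                 labels: dict[str, int] | None = None) -> Cohort:
    """Group interval/flag rows by child and rasterize each log."""
    by_child_iv: dict[str, list[SleepInterval]] = {}
    for iv in intervals:
        by_child_iv.setdefault(iv.child_id, []).append(iv)
    by_child_fl: dict[str, list[DailyFlags]] = {}
    for f in flags:
        by_child_fl.setdefault(f.child_id, []).append(f)
    logs = [build_log(meta, by_child_iv.get(meta.child_id, []),
                      by_child_fl.get(meta.child_id, []))
            for meta in children]
    return Cohort(logs=logs, labels=dict(labels or {}))


def validate_log(log: SleepLog) -> ValidationReport:
    """Report missing days and out-of-range flags; never raises."""
    issues: list[str] = []
    missing = [log.start_date + dt.timedelta(days=d) for d in log.missing_days]
    for date in missing:
        issues.append(f"day {date} has no recorded data")
    for f in log.flags:
        if f is None:
            continue
        for name in ("breakfast", "self_awake"):
            v = getattr(f, name)
            if v is not None and v not in (0, 1):
                issues.append(f"day {f.date}: non-binary flag {name}={v}")
        if (f.reported_night_wakings is not None
                and f.reported_night_wakings < 0):
            issues.append(f"day {f.date}: negative night_wakings")
    return ValidationReport(child_id=log.child_id, complete=not missing,
                            missing_days=missing, issues=issues)


# ---------------------------------------------------------------------------
# Writers (used by the simulator and the CLI round trip)
# ---------------------------------------------------------------------------

def intervals_to_frame(intervals: list[SleepInterval]) -> pd.DataFrame:
    rows = []
    for iv in intervals:
        rows.append({
            "child_id": iv.child_id,
            "date": iv.date.isoformat(),
            "start": format_clock_time(iv.start),
            "end": format_clock_time(iv.end),
            "next_day": int(iv.end >= 24.0),
        })
    return pd.DataFrame(rows, columns=["child_id", "date", "start", "end", "next_day"])


def flags_to_frame(flags: list[DailyFlags]) -> pd.DataFrame:
    rows = []
    for f in flags:
        rows.append({
            "child_id": f.child_id,
            "date": f.date.isoformat(),
            "breakfast": f.breakfast,
            "self_awake": f.self_awake,
            "night_wakings": f.reported_night_wakings,
        })
    return pd.DataFrame(rows, columns=["child_id", "date", "breakfast",
                                       "self_awake", "night_wakings"])


def children_to_frame(children: list[ChildMeta]) -> pd.DataFrame:
    rows = [{"child_id": c.child_id, "age_months": c.age_months,
             "sex": c.sex or "", "start_date": c.start_date.isoformat()}
            for c in children]
    return pd.DataFrame(rows, columns=["child_id", "age_months", "sex", "start_date"])
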