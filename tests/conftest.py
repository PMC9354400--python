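"""Shared fixtures: programmatically built sleep logs and cohorts."""

from __future__ import annotations

import datetime as dt

import pytest

from somnoscreen.sleeplog import (ChildMeta, DailyFlags, SleepInterval,
                                  build_log)

START = dt.date(2014, 9, 1)


def make_regular_log(child_id: str = "c1", age_months: int = 30,
                     bed: float = 21.0, wake: float = 7.0,
                     nap: tuple[float, float] | None = None,
                     night_gap: tuple[float, float] | None = None,
                     breakfast: int = 1, self_awake_days: int = 14,
                     reported_wakings=None, skip_days: set[int] = frozenset()):
    """A log with identical days: nightly sleep bed->wake(+24h), optional
    daily nap, optional nightly awake gap (decimal hours, 24h-extended)."""
    intervals, flags = [], []
    if 0 not in skip_days:
        # tail of the night in progress when the diary starts
        intervals.append(SleepInterval(child_id, START, 3.0, wake))
    for d in range(14):
        if d in skip_days:
            continue
        date = START + dt.timedelta(days=d)
        if nap is not None:
            intervals.append(SleepInterval(child_id, date, *nap))
        segments = [(bed, wake + 24.0)]
        if night_gap is not None:
            g0, g1 = night_gap
            segments = [(bed, g0), (g1, wake + 24.0)]
        for s, e in segments:
            if s >= 24.0:
                intervals.append(SleepInterval(
                    child_id, date + dt.timedelta(days=1), s - 24.0, e - 24.0))
            else:
                intervals.append(SleepInterval(child_id, date, s, e))
        rw = None
        if reported_wakings is not None:
            rw = reported_wakings[d]
        flags.append(DailyFlags(child_id, date, breakfast=breakfast,
                                self_awake=int(d < self_awake_days),
                                reported_night_wakings=rw))
    meta = ChildMeta(child_id, age_months, START)
    return build_log(meta, intervals, flags)


@pytest.fixture
def regular_log():
    """Nightly 21:00-07:00 sleeper, no naps, breakfast daily, self-awake 7/14."""
    return make_regular_log(self_awake_days=7)
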