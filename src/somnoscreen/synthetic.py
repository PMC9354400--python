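"""Labeled synthetic cohorts of 14-day sleep logs.

The study population this emulates is children 0-83 months in Japanese
childcare facilities whose parents kept a 14-day sleep diary.  Each simulated
child has a habitual (latent) bed time and wake time drawn from the age
group's class profile; the 14 individual nights then scatter around those
habits with a day-to-day SD, which is what the sigmoid variation parameters
pick up.  Night wakings are Poisson-counted awake gaps inside the night,
evening naps and the breakfast / self-awake diary flags are Bernoulli draws.

Class labels are encoded at the generative-parameter level: the severe class
(label 0) violates at least one clinical severity criterion — habitual sleep
onset after 22:30, more than three night wakings per night, under 8 h of
sleep, or day-to-day schedule variation above one hour — while the non-severe
class (label 1) is centered on observed population means (wake 6.84, bed
21.44 for the modal 19-47 month group, shifted by age following the known
developmental gradients: younger children sleep earlier, longer, nap more and
wake more at night).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np

from . import sleeplog
from .sleeplog import ChildMeta, Cohort, DailyFlags, SleepInterval, SleepLog

DEFAULT_START_DATE = dt.date(2014, 9, 1)

LABEL_NON_SEVERE = 1
LABEL_SEVERE = 0


class SimulationError(Exception):
    """Profile is degenerate or cannot produce a valid log."""


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one age group x class cell.

    Times are decimal hours (bed times on the 24h-extended scale); SDs in
    hours.  ``*_between_sd`` is the spread of habitual times across children;
    ``*_day_sd`` the day-to-day spread within a child, the quantity the
    sigmoid variation parameter |d| tracks (|d| ~ day_sd*sqrt(3)/pi).
    """

    group_id: int
    label: int
    bed_mean: float
    wake_mean: float
    bed_day_sd: float = 0.45
    wake_day_sd: float = 0.45
    bed_between_sd: float = 0.45
    wake_between_sd: float = 0.40
    onset_latency: float = 0.0            # hours from lights-out to sleep
    night_waking_rate: float = 0.1        # expected wakings/night (Poisson)
    waking_duration_min: float = 10.0
    evening_nap_prob: float = 0.1         # episodes/day (Bernoulli)
    nap_duration_min: float = 45.0
    breakfast_prob: float = 0.95
    self_awake_prob: float = 0.7

    def __post_init__(self) -> None:
        if not (18.0 < self.bed_mean < 26.0):
            raise SimulationError(f"bed_mean {self.bed_mean} outside (18, 26)")
        if not (3.0 < self.wake_mean < 10.0):
            raise SimulationError(f"wake_mean {self.wake_mean} outside (3, 10)")
        for name in ("bed_day_sd", "wake_day_sd", "bed_between_sd",
                     "wake_between_sd", "night_waking_rate", "onset_latency"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        for name in ("evening_nap_prob", "breakfast_prob", "self_awake_prob"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise SimulationError(f"{name} must be in [0, 1]")


# Age gradients for the non-severe class, anchored on the 19-47 month group
# (wake 6.84, bed 21.44): younger -> earlier bed, more night wakings, more
# naps, larger day-to-day spread, less breakfast routine.
_NON_SEVERE_BASE: dict[int, dict] = {
    0: dict(bed_mean=20.40, wake_mean=6.30, bed_day_sd=0.60, wake_day_sd=0.60,
            night_waking_rate=2.0, evening_nap_prob=0.50, breakfast_prob=0.50,
            self_awake_prob=0.80),
    1: dict(bed_mean=20.60, wake_mean=6.40, bed_day_sd=0.55, wake_day_sd=0.55,
            night_waking_rate=1.5, evening_nap_prob=0.45, breakfast_prob=0.60,
            self_awake_prob=0.80),
    2: dict(bed_mean=20.80, wake_mean=6.50, bed_day_sd=0.55, wake_day_sd=0.55,
            night_waking_rate=1.0, evening_nap_prob=0.35, breakfast_prob=0.80,
            self_awake_prob=0.78),
    3: dict(bed_mean=20.95, wake_mean=6.60, bed_day_sd=0.50, wake_day_sd=0.50,
            night_waking_rate=0.7, evening_nap_prob=0.25, breakfast_prob=0.92,
            self_awake_prob=0.78),
    4: dict(bed_mean=21.10, wake_mean=6.70, bed_day_sd=0.48, wake_day_sd=0.48,
            night_waking_rate=0.4, evening_nap_prob=0.18, breakfast_prob=0.95,
            self_awake_prob=0.75),
    5: dict(bed_mean=21.44, wake_mean=6.84, bed_day_sd=0.45, wake_day_sd=0.45,
            night_waking_rate=0.12, evening_nap_prob=0.10, breakfast_prob=0.95,
            self_awake_prob=0.70),
    6: dict(bed_mean=21.50, wake_mean=6.90, bed_day_sd=0.40, wake_day_sd=0.38,
            night_waking_rate=0.05, evening_nap_prob=0.04, breakfast_prob=0.97,
            self_awake_prob=0.62),
    7: dict(bed_mean=21.55, wake_mean=6.95, bed_day_sd=0.38, wake_day_sd=0.35,
            night_waking_rate=0.05, evening_nap_prob=0.03, breakfast_prob=0.97,
            self_awake_prob=0.60),
    8: dict(bed_mean=21.60, wake_mean=7.00, bed_day_sd=0.38, wake_day_sd=0.35,
            night_waking_rate=0.04, evening_nap_prob=0.02, breakfast_prob=0.97,
            self_awake_prob=0.58),
}

# Severe-class overrides: habitual sleep onset after 22:30 (criterion: sleep
# onset insomnia), > 3 wakings/night (fragmentation) and day-to-day variation
# above one hour; breakfast/self-awake routines degrade with the rhythm.
_SEVERE_OVERRIDES = dict(bed_mean=23.0, bed_day_sd=1.10, wake_day_sd=1.10,
                         night_waking_rate=3.5, waking_duration_min=15.0,
                         evening_nap_prob=0.35, breakfast_prob=0.70,
                         self_awake_prob=0.45)


def default_profiles() -> dict[tuple[int, int], GroupProfile]:
    """(group_id, label) -> profile for all nine groups and both classes."""
    profiles: dict[tuple[int, int], GroupProfile] = {}
    for gid, base in _NON_SEVERE_BASE.items():
        profiles[(gid, LABEL_NON_SEVERE)] = GroupProfile(
            group_id=gid, label=LABEL_NON_SEVERE, **base)
        severe = {**base, **_SEVERE_OVERRIDES}
        profiles[(gid, LABEL_SEVERE)] = GroupProfile(
            group_id=gid, label=LABEL_SEVERE, **severe)
    return profiles


@dataclass
class SimulationConfig:
    """Cohort composition: (group_id, label) -> number of children."""

    sizes: dict[tuple[int, int], int]
    seed: int = 0
    start_date: dt.date = DEFAULT_START_DATE
    n_days: int = sleeplog.N_DAYS
    profile_overrides: dict[tuple[int, int], dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_days != sleeplog.N_DAYS:
            raise SimulationError("only 14-day logs are supported")
        for key, n in self.sizes.items():
            if n < 0:
                raise SimulationError(f"negative sample size for {key}")


def _truncated_normal(rng, mean, sd, lo, hi):
    """Normal draw clipped to (lo, hi); a clipped draw is pinned to the edge."""
    v = rng.normal(mean, sd) if sd > 0 else mean
    return float(np.clip(v, lo + 1e-6, hi - 1e-6))


def simulate_child(profile: GroupProfile, child_id: str, age_months: int,
                   seed=None,
                   start_date: dt.date = DEFAULT_START_DATE
                   ) -> tuple[SleepLog, int]:
    """One 14-day log drawn from a profile; deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    n_days = sleeplog.N_DAYS

    bed_mu = _truncated_normal(rng, profile.bed_mean, profile.bed_between_sd,
                               18.0, 26.0)
    wake_mu = _truncated_normal(rng, profile.wake_mean, profile.wake_between_sd,
                                3.0, 10.0)
    # wake[d] = waking on the morning of day d (d = 0..14, last clipped away);
    # bed[d] = sleep onset on the evening of day d.
    wakes = [_truncated_normal(rng, wake_mu, profile.wake_day_sd, 3.0, 10.0)
             for _ in range(n_days + 1)]
    beds = [_truncated_normal(rng, bed_mu + profile.onset_latency,
                              profile.bed_day_sd, 18.0, 26.0)
            for _ in range(n_days)]

    intervals: list[SleepInterval] = []
    flags: list[DailyFlags] = []
    for d in range(n_days):
        date = start_date + dt.timedelta(days=d)
        day_intervals: list[tuple[float, float]] = []
        if d == 0:
            # tail of the night in progress when the diary starts
            day_intervals.append((3.0, wakes[0]))
        # evening nap
        if rng.random() < profile.evening_nap_prob:
            nap_len = profile.nap_duration_min / 60.0
            nap_start = rng.uniform(15.0, 19.0 - nap_len)
            nap_end = min(nap_start + nap_len, beds[d] - 0.25)
            if nap_end - nap_start >= 1.0 / 12.0:
                day_intervals.append((nap_start, nap_end))
        # the night starting this evening
        night_start = beds[d]
        night_end = wakes[d + 1] + 24.0
        if night_end <= night_start:
            raise SimulationError(
                f"{child_id} day {d}: wake {night_end - 24:.2f} precedes "
                f"bed {night_start:.2f}")
        n_wakings = rng.poisson(profile.night_waking_rate)
        gap_len = profile.waking_duration_min / 60.0
        gaps: list[tuple[float, float]] = []
        lo, hi = night_start + 0.5, night_end - 0.5 - gap_len
        if n_wakings > 0 and hi > lo:
            starts = np.sort(rng.uniform(lo, hi, size=n_wakings))
            last_end = -np.inf
            for s in starts:
                if s >= last_end + 1.0 / 12.0:
                    gaps.append((s, s + gap_len))
                    last_end = s + gap_len
        pos = night_start
        for gs, ge in gaps:
            day_intervals.append((pos, gs))
            pos = ge
        day_intervals.append((pos, night_end))

        for s, e in day_intervals:
            s_round = round(s * 60) / 60.0
            e_round = round(e * 60) / 60.0
            if e_round - s_round < 1.0 / 60.0:
                continue
            if d == n_days - 1 and s_round >= 27.0:
                continue          # past the final day's grid edge

            if s_round >= 24.0:
                intervals.append(SleepInterval(child_id, date + dt.timedelta(days=1),
                                               s_round - 24.0, e_round - 24.0))
            else:
                intervals.append(SleepInterval(child_id, date, s_round, e_round))

        flags.append(DailyFlags(
            child_id=child_id, date=date,
            breakfast=int(rng.random() < profile.breakfast_prob),
            self_awake=int(rng.random() < profile.self_awake_prob),
            reported_night_wakings=len(gaps)))

    meta = ChildMeta(child_id=child_id, age_months=age_months,
                     start_date=start_date)
    log = sleeplog.build_log(meta, intervals, flags)
    return log, profile.label


def _group_age(gid: int, rng) -> int:
    lo, hi = sleeplog_age_range(gid)
    return int(rng.integers(lo, hi + 1))


def sleeplog_age_range(gid: int) -> tuple[int, int]:
    from .bank import AGE_GROUPS
    return AGE_GROUPS[gid]


def simulate_cohort(config: SimulationConfig,
                    profiles: dict[tuple[int, int], GroupProfile] | None = None
                    ) -> Cohort:
    """Reproducible labeled cohort; per-child seeds are derived from the
    global seed and the child's (group, label, index), so results do not
    depend on cohort ordering."""
    profiles = dict(profiles or default_profiles())
    for key, overrides in config.profile_overrides.items():
        profiles[key] = replace(profiles[key], **overrides)

    logs: list[SleepLog] = []
    labels: dict[str, int] = {}
    for (gid, label) in sorted(config.sizes):
        n = config.sizes[(gid, label)]
        if n == 0:
            continue
        profile = profiles[(gid, label)]
        for i in range(n):
            child_id = f"g{gid}c{label}_{i:04d}"
            child_seed = [config.seed, gid, label, i]
            age = _group_age(gid, np.random.default_rng(child_seed + [1]))
            log, lab = simulate_child(profile, child_id, age,
                                      seed=child_seed,
                                      start_date=config.start_date)
            logs.append(log)
            labels[child_id] = lab
    return Cohort(logs=logs, labels=labels)


def cohort_summary(cohort: Cohort) -> dict:
    """Counts per (group, label) cell plus single-class warnings."""
    from .bank import assign_age_group
    counts: dict[str, int] = {}
    for log in cohort.logs:
        gid = assign_age_group(log.age_months)
        label = cohort.labels.get(log.child_id)
        counts[f"group{gid}_label{label}"] = counts.get(
            f"group{gid}_label{label}", 0) + 1
    labels = set(cohort.labels.values())
    return {"n_children": len(cohort.logs), "cells": counts,
            "single_class": len(labels) < 2}
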