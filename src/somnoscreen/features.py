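"""The ten per-child sleep variables extracted from a 14-day log.

The two timing variables (wake-up time, bed time) and their day-to-day
variations come from fitting a four-parameter logistic

    y(x) = a + (b - a) / (1 + exp((c - x) / d))

to the sleep-wake rate curve: the per-epoch mean of the awake state (1 =
awake) over the observed days.  ``c`` is the point-symmetry time — the clock
time at which sleep and wake are equally likely — and ``d`` is the slope
parameter.  For a child with a perfectly regular schedule the rate curve is a
step function and |d| -> 0; day-to-day spread in the transition time widens
the curve and grows |d| (for normally distributed times with SD sigma the
logistic match gives |d| ~ sigma*sqrt(3)/pi).  Wake-up fits are rising
(d > 0), bed-time fits falling (d < 0) by convention, so the reported bed-time
variation is negative.

Nonlinear least squares on the averaged curve frequently fails to converge
from poor starting points, so the estimate is stabilized by refitting
``n_repeats`` times with a small uniform jitter added to every rate value and
averaging the converged fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .sleeplog import (ASLEEP, AWAKE, DAY_START_HOUR, EPOCHS_PER_DAY, MISSING,
                       N_DAYS, SleepLog)

EPOCH_HOURS = 1.0 / 12.0

WAKE_WINDOW = (3.0, 10.0)
BED_WINDOW = (18.0, 26.0)
NOCTURNAL_WINDOW = (19.0, 33.0)    # 19:00 -> 09:00 next day
EVENING_NAP_WINDOW = (15.0, 19.0)

DEFAULT_N_REPEATS = 100
DEFAULT_JITTER_EPS = 0.01
MIN_CONVERGED_FRACTION = 0.5

FEATURE_NAMES = (
    "wake_up_time",
    "wake_up_time_variation",
    "bed_time",
    "bed_time_variation",
    "total_sleep_duration",
    "nocturnal_sleep_duration",
    "night_wakings",
    "evening_nap",
    "breakfast",
    "self_awake",
)


class FeatureError(Exception):
    """A feature could not be computed from the log."""


class SigmoidFitError(FeatureError):
    def __init__(self, message: str, converged_fraction: float = 0.0):
        super().__init__(message)
        self.converged_fraction = converged_fraction


@dataclass
class RateCurve:
    window: tuple[float, float]
    times: np.ndarray          # epoch-start grid, 5-min steps
    rates: np.ndarray          # mean awake state per epoch, in [0, 1]


@dataclass
class SigmoidFit:
    a: float
    b: float
    c: float                   # transition time, decimal hours
    d: float                   # slope/variation, hours; sign per direction
    n_repeats: int
    converged_fraction: float
    residual_rms: float


@dataclass
class FeatureVector:
    wake_up_time: float
    wake_up_time_variation: float
    bed_time: float
    bed_time_variation: float
    total_sleep_duration: float
    nocturnal_sleep_duration: float
    night_wakings: float
    evening_nap: float
    breakfast: float
    self_awake: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


# ---------------------------------------------------------------------------
# Rate curves
# ---------------------------------------------------------------------------

def _window_rows(log: SleepLog, window: tuple[float, float]) -> np.ndarray:
    """Per-day awake states over a window within [3, 33); MISSING where unknown.

    Hours >= 27 are read from the following day's grid, so windows extending
    past 27:00 exist only for days 0..12.
    """
    w0, w1 = window
    if not (DAY_START_HOUR <= w0 < w1 <= 33.0):
        raise FeatureError(f"window {window} outside [3, 33)")
    i0 = round((w0 - DAY_START_HOUR) * 12)
    n = round((w1 - w0) * 12)
    if w1 <= 27.0:
        return log.grid[:, i0:i0 + n]
    rows = []
    for d in range(N_DAYS - 1):
        ext = np.concatenate([log.grid[d], log.grid[d + 1]])
        rows.append(ext[i0:i0 + n])
    return np.asarray(rows)


def average_state_curve(log: SleepLog, window: tuple[float, float]) -> RateCurve:
    """Mean awake state per 5-min epoch over the non-missing days."""
    rows = _window_rows(log, window)
    valid = ~(rows == MISSING).any(axis=1)
    if not valid.any():
        raise FeatureError(f"no observed day covers window {window}")
    rates = rows[valid].mean(axis=0).astype(float)
    times = window[0] + np.arange(rows.shape[1]) * EPOCH_HOURS
    return RateCurve(window=window, times=times, rates=rates)


# ---------------------------------------------------------------------------
# Sigmoid fitting
# ---------------------------------------------------------------------------

def sigmoid(x: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    return a + (b - a) * expit((x - c) / d)


def _residual_and_jac(x: np.ndarray, y: np.ndarray):
    def residual(p):
        return sigmoid(x, *p) - y

    def jac(p):
        a, b, c, d = p
        s = expit((x - c) / d)
        sp = s * (1.0 - s)
        return np.column_stack([
            1.0 - s,
            s,
            -(b - a) * sp / d,
            -(b - a) * sp * (x - c) / d ** 2,
        ])

    return residual, jac


def _fit_once(x, y, p0, lower, upper):
    residual, jac = _residual_and_jac(x, y)
    p0 = np.clip(p0, lower, upper)
    try:
        res = least_squares(residual, p0, jac=jac, bounds=(lower, upper),
                            method="trf", xtol=1e-8, ftol=1e-8, gtol=1e-8,
                            max_nfev=100)
    except (ValueError, np.linalg.LinAlgError):
        return None
    if not (res.success and np.all(np.isfinite(res.x))):
        return None
    return res.x


def fit_sigmoid(curve: RateCurve, direction: str,
                n_repeats: int = DEFAULT_N_REPEATS,
                jitter_eps: float = DEFAULT_JITTER_EPS,
                seed=None) -> SigmoidFit:
    """Jitter-averaged four-parameter logistic fit to a rate curve.

    Each repeat adds i.i.d. uniform jitter on [-jitter_eps, +jitter_eps] to
    every rate value and refits; the reported parameters are the mean over
    converged repeats.  ``direction`` enforces the sign of d ("rising" for
    wake fits, "falling" for bed fits).  Raises SigmoidFitError if the curve
    shows no transition or fewer than half the repeats converge.
    """
    if direction not in ("rising", "falling"):
        raise ValueError(f"direction must be rising/falling, got {direction!r}")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    x = np.asarray(curve.times, dtype=float)
    y = np.asarray(curve.rates, dtype=float)
    if np.ptp(y) < 0.1:
        raise SigmoidFitError(
            f"rate curve on {curve.window} is nearly constant "
            f"(range {np.ptp(y):.3f}); no sleep-wake transition to fit")

    w0, w1 = curve.window
    rising = direction == "rising"
    # Asymptote roles follow the sign of d: with d > 0, a is the early-time
    # asymptote; with d < 0 the roles swap, so (a0, b0) = (0, 1) serves both
    # a rising 0->1 and a falling 1->0 curve.
    a0, b0 = 0.0, 1.0
    if rising:
        crossings = np.nonzero(y >= 0.5)[0]
        lower = np.array([-0.2, -0.2, w0, 1e-4])
        upper = np.array([1.2, 1.2, w1, 2.0])
        d0 = 0.25
    else:
        crossings = np.nonzero(y <= 0.5)[0]
        lower = np.array([-0.2, -0.2, w0, -2.0])
        upper = np.array([1.2, 1.2, w1, -1e-4])
        d0 = -0.25
    c0 = x[crossings[0]] if crossings.size else 0.5 * (w0 + w1)
    p0 = np.array([a0, b0, c0, d0])

    base = _fit_once(x, y, p0, lower, upper)
    start = base if base is not None else p0

    rng = np.random.default_rng(seed)
    fits = []
    for _ in range(n_repeats):
        yj = y + rng.uniform(-jitter_eps, jitter_eps, size=y.shape)
        p = _fit_once(x, yj, start, lower, upper)
        if p is not None:
            fits.append(p)
    frac = len(fits) / n_repeats
    if frac < MIN_CONVERGED_FRACTION:
        raise SigmoidFitError(
            f"sigmoid fit on {curve.window}: only {frac:.0%} of "
            f"{n_repeats} jittered repeats converged", converged_fraction=frac)
    a, b, c, d = np.mean(fits, axis=0)
    rms = float(np.sqrt(np.mean((sigmoid(x, a, b, c, d) - y) ** 2)))
    return SigmoidFit(a=float(a), b=float(b), c=float(c), d=float(d),
                      n_repeats=n_repeats, converged_fraction=frac,
                      residual_rms=rms)


def wake_time_features(log: SleepLog, n_repeats: int = DEFAULT_N_REPEATS,
                       jitter_eps: float = DEFAULT_JITTER_EPS,
                       seed=None) -> tuple[float, float]:
    """(wake_up_time, wake_up_time_variation): rising fit on the 3-10 h window."""
    curve = average_state_curve(log, WAKE_WINDOW)
    fit = fit_sigmoid(curve, "rising", n_repeats, jitter_eps, seed)
    return fit.c, fit.d


def bed_time_features(log: SleepLog, n_repeats: int = DEFAULT_N_REPEATS,
                      jitter_eps: float = DEFAULT_JITTER_EPS,
                      seed=None) -> tuple[float, float]:
    """(bed_time, bed_time_variation): falling fit on the 18-26 h window.

    Bed times after midnight stay on the 24h-extended scale (1:27 am -> 25.45).
    """
    curve = average_state_curve(log, BED_WINDOW)
    fit = fit_sigmoid(curve, "falling", n_repeats, jitter_eps, seed)
    return fit.c, fit.d


# ---------------------------------------------------------------------------
# Duration and count features
# ---------------------------------------------------------------------------

def _observed_days(log: SleepLog) -> np.ndarray:
    valid = ~(log.grid == MISSING).all(axis=1)
    if not valid.any():
        raise FeatureError("log has no observed days")
    return log.grid[valid]


def total_sleep_duration(log: SleepLog) -> float:
    """Mean asleep hours per 24-h logical day, over non-missing days."""
    rows = _observed_days(log)
    return float((rows == ASLEEP).sum(axis=1).mean() * EPOCH_HOURS)


def _nocturnal_rows(log: SleepLog) -> np.ndarray:
    """Awake-state rows for the 13 complete nocturnal windows (19:00-09:00)."""
    rows = _window_rows(log, NOCTURNAL_WINDOW)
    valid = ~(rows == MISSING).any(axis=1)
    if not valid.any():
        raise FeatureError("no complete nocturnal window observed")
    return rows[valid]


def nocturnal_sleep_duration(log: SleepLog) -> float:
    """Mean asleep hours per night in 19:00-09:00, over complete nights."""
    rows = _nocturnal_rows(log)
    return float((rows == ASLEEP).sum(axis=1).mean() * EPOCH_HOURS)


def _count_runs(mask: np.ndarray) -> int:
    """Number of maximal runs of True."""
    if not mask.any():
        return 0
    return int(mask[0]) + int((mask[1:] & ~mask[:-1]).sum())


def night_wakings(log: SleepLog) -> float:
    """Mean number of awakenings during nocturnal sleep.

    Prefers the parent-reported per-night counts when present for at least
    half the nights; otherwise counts maximal awake runs strictly between
    sleep onset and final awakening in each complete 19:00-09:00 window.
    """
    reported = [f.reported_night_wakings for f in log.flags
                if f is not None and f.reported_night_wakings is not None]
    if len(reported) >= N_DAYS / 2:
        return float(np.mean(reported))

    counts = []
    for row in _nocturnal_rows(log):
        asleep_idx = np.nonzero(row == ASLEEP)[0]
        if asleep_idx.size == 0:
            counts.append(0)
            continue
        onset, final = asleep_idx[0], asleep_idx[-1]
        inner = row[onset:final + 1] == AWAKE
        counts.append(_count_runs(inner))
    return float(np.mean(counts))


def evening_nap(log: SleepLog) -> float:
    """Mean number of sleep episodes intersecting 15:00-19:00, per day."""
    i0 = round((EVENING_NAP_WINDOW[0] - DAY_START_HOUR) * 12)
    i1 = round((EVENING_NAP_WINDOW[1] - DAY_START_HOUR) * 12)
    counts = []
    for row in _observed_days(log):
        asleep = row == ASLEEP
        # count maximal asleep runs that have at least one epoch in the window
        starts = np.nonzero(asleep & ~np.concatenate(([False], asleep[:-1])))[0]
        n = 0
        for s in starts:
            e = s
            while e + 1 < row.size and asleep[e + 1]:
                e += 1
            if s < i1 and e >= i0:
                n += 1
        counts.append(n)
    return float(np.mean(counts))


def _flag_rate(log: SleepLog, name: str) -> float:
    values = [getattr(f, name) for f in log.flags
              if f is not None and getattr(f, name) is not None]
    if not values:
        raise FeatureError(f"no {name} flags recorded")
    return float(np.mean(values))


def breakfast_rate(log: SleepLog) -> float:
    return _flag_rate(log, "breakfast")


def self_awake_rate(log: SleepLog) -> float:
    return _flag_rate(log, "self_awake")


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def extract_features(log: SleepLog, n_repeats: int = DEFAULT_N_REPEATS,
                     jitter_eps: float = DEFAULT_JITTER_EPS,
                     seed=None) -> FeatureVector:
    """All ten variables from one log; deterministic for a given seed."""
    ss = np.random.SeedSequence(seed)
    wake_seed, bed_seed = ss.spawn(2)
    values: dict[str, float] = {}

    def compute(name, fn):
        try:
            values[name] = fn()
        except FeatureError as exc:
            raise FeatureError(f"{name}: {exc}") from exc

    compute("wake_up_time", lambda: wake_time_features(
        log, n_repeats, jitter_eps, wake_seed))
    values["wake_up_time"], values["wake_up_time_variation"] = values["wake_up_time"]
    compute("bed_time", lambda: bed_time_features(
        log, n_repeats, jitter_eps, bed_seed))
    values["bed_time"], values["bed_time_variation"] = values["bed_time"]
    compute("total_sleep_duration", lambda: total_sleep_duration(log))
    compute("nocturnal_sleep_duration", lambda: nocturnal_sleep_duration(log))
    compute("night_wakings", lambda: night_wakings(log))
    compute("evening_nap", lambda: evening_nap(log))
    compute("breakfast", lambda: breakfast_rate(log))
    compute("self_awake", lambda: self_awake_rate(log))
    return FeatureVector(**values)
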