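"""Per-age-group Fisher classification functions for sleep-disorder screening.

Children aged 0-83 months are split into nine developmental age groups.  For
each supported group (1-8) the bank holds one pair of Fisher linear
classification functions: y0 scores the "severe sleep disorder" class, y1 the
"no severe disorder" class.  Each score is an affine function of a subset of
the ten sleep-log variables; a child is judged 1 (no severe disorder) iff
y1 > y0, with the measure-zero tie y1 == y0 resolved to 0 so that borderline
cases are flagged for clinical review.

Group 0 (0-2 months) has no classifier: newborn sleep is too irregular and
the reference sample too small, so screening that group raises and the child
should be referred for direct review.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureVector

# group id -> inclusive month range
AGE_GROUPS: dict[int, tuple[int, int]] = {
    0: (0, 2),
    1: (3, 5),
    2: (6, 9),
    3: (10, 14),
    4: (15, 18),
    5: (19, 47),
    6: (48, 59),
    7: (60, 71),
    8: (72, 83),
}

CONSTANT_ROW = "(constant)"

# Human-readable table labels accepted in bank files alongside field names.
VARIABLE_LABELS: dict[str, str] = {
    "Wake up time": "wake_up_time",
    "Wake up time variation": "wake_up_time_variation",
    "Bed time": "bed_time",
    "Bed time variation": "bed_time_variation",
    "Total sleep duration": "total_sleep_duration",
    "Nocturnal sleep duration": "nocturnal_sleep_duration",
    "Night wakings": "night_wakings",
    "Evening nap": "evening_nap",
    "Breakfast": "breakfast",
    "Self-awake": "self_awake",
}


class BankError(Exception):
    """Classifier bank is malformed or cannot be applied."""


class UnsupportedAgeError(BankError):
    """Age outside 0-83 months."""


class UnsupportedGroupError(BankError):
    """No classifier exists for this age group (group 0)."""


def assign_age_group(age_months: int) -> int:
    """Map an age in months to its developmental group id."""
    age = int(age_months)
    for gid, (lo, hi) in AGE_GROUPS.items():
        if lo <= age <= hi:
            return gid
    raise UnsupportedAgeError(
        f"age {age_months} months outside the supported 0-83 month range")


@dataclass(frozen=True)
class FisherClassifier:
    group_id: int
    variables: tuple[str, ...]
    coef_y0: np.ndarray
    coef_y1: np.ndarray
    const_y0: float
    const_y1: float

    def __post_init__(self) -> None:
        if not (len(self.variables) == len(self.coef_y0) == len(self.coef_y1)):
            raise BankError(f"group {self.group_id}: coefficient length mismatch")

    def scores(self, features) -> tuple[float, float]:
        return fisher_scores(self, features)


@dataclass(frozen=True)
class Judgment:
    child_id: str
    group_id: int
    y0: float
    y1: float
    label: int                  # 1 = no severe disorder, 0 = severe

    @property
    def margin(self) -> float:
        return self.y1 - self.y0


def _as_mapping(features) -> dict[str, float]:
    if isinstance(features, FeatureVector):
        return features.as_dict()
    return dict(features)


def fisher_scores(classifier: FisherClassifier, features) -> tuple[float, float]:
    """Evaluate both Fisher functions at a feature vector."""
    mapping = _as_mapping(features)
    try:
        x = np.array([mapping[v] for v in classifier.variables], dtype=float)
    except KeyError as exc:
        raise BankError(
            f"group {classifier.group_id}: feature {exc.args[0]!r} missing") from exc
    y0 = float(classifier.coef_y0 @ x + classifier.const_y0)
    y1 = float(classifier.coef_y1 @ x + classifier.const_y1)
    return y0, y1


def classify(features, age_months: int,
             bank: dict[int, FisherClassifier],
             child_id: str = "") -> Judgment:
    """Judge one child: 1 iff y1 > y0 (ties -> 0, flagged for review)."""
    gid = assign_age_group(age_months)
    if gid not in bank:
        raise UnsupportedGroupError(
            f"age group {gid} ({AGE_GROUPS[gid][0]}-{AGE_GROUPS[gid][1]} months) "
            "has no classifier; refer for clinical review")
    clf = bank[gid]
    y0, y1 = fisher_scores(clf, features)
    return Judgment(child_id=child_id, group_id=gid, y0=y0, y1=y1,
                    label=int(y1 > y0))


# ---------------------------------------------------------------------------
# Bank I/O
# ---------------------------------------------------------------------------

def _canonical_variable(name: str) -> str:
    name = name.strip()
    if name in FEATURE_NAMES or name == CONSTANT_ROW:
        return name
    if name in VARIABLE_LABELS:
        return VARIABLE_LABELS[name]
    raise BankError(f"unknown variable name {name!r} in bank file")


def load_bank(path=None) -> dict[int, FisherClassifier]:
    """Load a classifier bank CSV; with no path, the packaged default bank.

    Schema: ``group_id,variable,coef_y0,coef_y1`` with one ``(constant)`` row
    per group for the intercepts.  Variable order within a group is preserved.
    """
    if path is None:
        ref = resources.files("somnoscreen").joinpath("data/fisher_bank.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    required = {"group_id", "variable", "coef_y0", "coef_y1"}
    if not required.issubset(df.columns):
        raise BankError(f"bank file missing column(s) {sorted(required - set(df.columns))}")

    bank: dict[int, FisherClassifier] = {}
    for gid, sub in df.groupby("group_id", sort=True):
        gid = int(gid)
        if gid not in AGE_GROUPS:
            raise BankError(f"bank contains unknown group id {gid}")
        variables, c0, c1 = [], [], []
        const = None
        for row in sub.itertuples(index=False):
            name = _canonical_variable(str(row.variable))
            if name == CONSTANT_ROW:
                const = (float(row.coef_y0), float(row.coef_y1))
            else:
                variables.append(name)
                c0.append(float(row.coef_y0))
                c1.append(float(row.coef_y1))
        if const is None:
            raise BankError(f"group {gid}: missing '(constant)' row")
        if not variables:
            raise BankError(f"group {gid}: no discriminant variables")
        bank[gid] = FisherClassifier(
            group_id=gid, variables=tuple(variables),
            coef_y0=np.array(c0), coef_y1=np.array(c1),
            const_y0=const[0], const_y1=const[1])
    return bank


def save_bank(bank: dict[int, FisherClassifier], path) -> None:
    rows = []
    for gid in sorted(bank):
        clf = bank[gid]
        for v, a0, a1 in zip(clf.variables, clf.coef_y0, clf.coef_y1):
            rows.append({"group_id": gid, "variable": v,
                         "coef_y0": repr(float(a0)), "coef_y1": repr(float(a1))})
        rows.append({"group_id": gid, "variable": CONSTANT_ROW,
                     "coef_y0": repr(clf.const_y0), "coef_y1": repr(clf.const_y1)})
    pd.DataFrame(rows, columns=["group_id", "variable", "coef_y0", "coef_y1"]
                 ).to_csv(path, index=False)
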