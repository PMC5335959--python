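"""Evidence fusion over observation windows and days, plus classification.

The day is partitioned into ``24 / interval_hours`` half-open observation
windows.  Within each window every relevant appliance contributes one BBA
(event branch if it switched on at least once, no-event branch otherwise);
Dempster's rule fuses them into the window's mass.  Fusing the window
masses over the day yields the daily mass; accumulated evidence narrows
the [bel, pl] ignorance band, so daily scores are sharper than any single
window's.

Classification compares a threshold against the h1 (normal) belief
interval: below bel the day is NORMAL, above pl it is ABNORMAL, and inside
the band the evidence is insufficient to say either — an explicit
INDETERMINATE verdict rather than a forced binary call.  Inactivity
therefore tends to be muffled into indeterminacy instead of raising a
false alarm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date as Date, datetime, timedelta
from enum import Enum
from pathlib import Path
from typing import Sequence

import pandas as pd

from .bba import CertaintyConstants, UsageProbabilityTable, assign_mass
from .dst import (
    BeliefInterval,
    Hypothesis,
    MassFunction,
    combine_all,
    interval as dst_interval,
    truncate2,
)
from .events import EventLog


@dataclass(frozen=True)
class ScoringConfig:
    """Observation-window length, certainty constants, decision threshold."""

    interval_hours: int = 6
    c0: float = 0.9
    c1: float = 0.1
    threshold: float = 0.5
    train_fraction: float = 0.6

    def __post_init__(self) -> None:
        if 24 % self.interval_hours != 0:
            raise ValueError(f"interval_hours must divide 24, got {self.interval_hours}")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError(f"threshold must lie in [0,1], got {self.threshold}")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie strictly between 0 and 1")

    @property
    def certainty(self) -> CertaintyConstants:
        return CertaintyConstants(self.c0, self.c1)

    @property
    def n_intervals(self) -> int:
        return 24 // self.interval_hours


class Classification(Enum):
    NORMAL = "NORMAL"
    ABNORMAL = "ABNORMAL"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class IntervalScore:
    """Fused evidence for one observation window of one day."""

    date: Date
    interval_index: int
    mass: MassFunction
    interval: BeliefInterval  # for h1 (normal)


@dataclass(frozen=True)
class DailyScore:
    """Evidence accumulated over all of a day's observation windows."""

    date: Date
    mass: MassFunction
    interval: BeliefInterval  # for h1 (normal)
    classification: Classification


def classify(interval: BeliefInterval, threshold: float) -> Classification:
    """Compare the threshold against the [bel, pl] band for h1.

    NORMAL when the threshold lies at or below both bounds, ABNORMAL when
    at or above both; inside the band nothing can be concluded.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0,1], got {threshold}")
    if threshold <= interval.bel:
        return Classification.NORMAL
    if threshold >= interval.pl:
        return Classification.ABNORMAL
    return Classification.INDETERMINATE


def _presence_index(log: EventLog, interval_hours: int) -> set[tuple[str, Date, int]]:
    """(appliance, date, interval) triples with at least one event."""
    return {
        (e.appliance_id, e.timestamp.date(), e.timestamp.hour // interval_hours)
        for e in log.events
    }


def _interval_mass(
    presence: set[tuple[str, Date, int]],
    appliances: Sequence[str],
    table: UsageProbabilityTable,
    config: ScoringConfig,
    date: Date,
    interval_index: int,
) -> MassFunction:
    masses = []
    for appliance in appliances:
        p = table.entries.get((appliance, date.weekday(), interval_index), 0.0)
        present = (appliance, date, interval_index) in presence
        if not present and p == 0.0:
            # silence in a bin the appliance never used in training carries
            # no routine information: contribute nothing (vacuous).  An
            # event in such a bin, by contrast, is maximal abnormal
            # evidence via the event branch below.
            continue
        masses.append(assign_mass(p, present, config.certainty))
    if not masses:
        return MassFunction.vacuous()
    return combine_all(masses)


def score_interval(
    test_log: EventLog,
    table: UsageProbabilityTable,
    config: ScoringConfig,
    date: Date,
    interval_index: int,
) -> IntervalScore:
    """Fuse one window: a BBA per relevant appliance, combined by Dempster's rule."""
    if table.interval_hours != config.interval_hours:
        raise ValueError(
            f"table trained with interval_hours={table.interval_hours}, "
            f"config requests {config.interval_hours}"
        )
    if not (0 <= interval_index < config.n_intervals):
        raise ValueError(f"interval_index {interval_index} out of range")
    appliances = sorted(a for a, info in test_log.registry.items() if info.relevant)
    if not appliances:
        warnings.warn("no relevant appliances; returning vacuous evidence", stacklevel=2)
        mass = MassFunction.vacuous()
    else:
        presence = _presence_index(test_log, config.interval_hours)
        mass = _interval_mass(presence, appliances, table, config, date, interval_index)
    return IntervalScore(date, interval_index, mass, dst_interval(mass, Hypothesis.H1_NORMAL))


def score_day(
    test_log: EventLog,
    table: UsageProbabilityTable,
    config: ScoringConfig,
    date: Date,
) -> DailyScore:
    """Accumulate all of a day's window masses into a single daily verdict."""
    interval_scores = [
        score_interval(test_log, table, config, date, i) for i in range(config.n_intervals)
    ]
    mass = combine_all([s.mass for s in interval_scores])
    iv = dst_interval(mass, Hypothesis.H1_NORMAL)
    return DailyScore(date, mass, iv, classify(iv, config.threshold))


def score_period(
    test_log: EventLog,
    table: UsageProbabilityTable,
    config: ScoringConfig,
) -> tuple[list[DailyScore], list[IntervalScore]]:
    """Score every day of the test span; returns (daily scores, interval scores)."""
    if table.interval_hours != config.interval_hours:
        raise ValueError(
            f"table trained with interval_hours={table.interval_hours}, "
            f"config requests {config.interval_hours}"
        )
    appliances = sorted(a for a, info in test_log.registry.items() if info.relevant)
    presence = _presence_index(test_log, config.interval_hours)
    daily: list[DailyScore] = []
    per_interval: list[IntervalScore] = []
    for date in test_log.dates():
        day_masses = []
        for idx in range(config.n_intervals):
            if appliances:
                m = _interval_mass(presence, appliances, table, config, date, idx)
            else:
                m = MassFunction.vacuous()
            per_interval.append(
                IntervalScore(date, idx, m, dst_interval(m, Hypothesis.H1_NORMAL))
            )
            day_masses.append(m)
        mass = combine_all(day_masses)
        iv = dst_interval(mass, Hypothesis.H1_NORMAL)
        daily.append(DailyScore(date, mass, iv, classify(iv, config.threshold)))
    return daily, per_interval


def calibrate_threshold(
    train_scores: Sequence[DailyScore], false_alarm_budget: float = 0.05
) -> float:
    """Pick the largest threshold keeping the ABNORMAL rate within budget.

    Sweeps the 0..1 grid at 0.01 resolution over self-scores of the
    training period (which is normal by assumption); the highest threshold
    whose abnormal fraction stays at or below ``false_alarm_budget`` is the
    most sensitive setting compatible with the budget.
    """
    if not train_scores:
        raise ValueError("no training scores to calibrate against")
    if not (0.0 <= false_alarm_budget <= 1.0):
        raise ValueError("false_alarm_budget must lie in [0,1]")
    pls = [s.interval.pl for s in train_scores]
    best = 0.0
    for step in range(101):
        theta = step / 100.0
        abnormal = sum(1 for pl in pls if theta >= pl)
        if abnormal / len(pls) <= false_alarm_budget:
            best = theta
    return best


# ---------------------------------------------------------------------------
# Score table output
# ---------------------------------------------------------------------------

def scores_to_frame(
    daily: Sequence[DailyScore], per_interval: Sequence[IntervalScore] = ()
) -> pd.DataFrame:
    """Tidy score table; daily rows carry an empty interval_index."""
    rows = []
    for s in per_interval:
        rows.append(
            {
                "date": s.date.isoformat(),
                "interval_index": s.interval_index,
                "bel": s.interval.bel,
                "pl": s.interval.pl,
                "classification": "",
                "bel_2dec": truncate2(s.interval.bel),
                "pl_2dec": truncate2(s.interval.pl),
            }
        )
    for s in daily:
        rows.append(
            {
                "date": s.date.isoformat(),
                "interval_index": "",
                "bel": s.interval.bel,
                "pl": s.interval.pl,
                "classification": s.classification.value,
                "bel_2dec": truncate2(s.interval.bel),
                "pl_2dec": truncate2(s.interval.pl),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["date", "interval_index", "bel", "pl", "classification", "bel_2dec", "pl_2dec"],
    )


def write_scores_csv(
    daily: Sequence[DailyScore],
    path: str | Path,
    per_interval: Sequence[IntervalScore] = (),
) -> None:
    """Write scores as CSV: full-precision bel/pl plus 2-decimal display columns."""
    scores_to_frame(daily, per_interval).to_csv(path, index=False)


def read_scores_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"classification": str}, keep_default_na=False)
    df["interval_index"] = df["interval_index"].replace("", pd.NA)
    return df


def weekly_mean_belief(daily: Sequence[DailyScore]) -> pd.Series:
    """Calendar-week (Mon-Sun) mean of daily bel(h1); indexed by week start."""
    s = pd.Series(
        [d.interval.bel for d in daily],
        index=pd.to_datetime([d.date for d in daily]),
    )
    weekly = s.groupby(s.index.to_period("W-SUN")).mean()
    weekly.index = weekly.index.start_time.date
    return weekly
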