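"""Learned usage probabilities and their conversion to basic belief assignments.

Training bins switch-on events by (appliance, day of week, intra-day
interval) and estimates, for each bin, the probability that the appliance
is used at least once in that interval on that weekday:

    P = (# training days of that weekday with >= 1 event in the interval)
        / (# training days of that weekday)

Presence counting (rather than raw occurrence counting) keeps P a genuine
probability even when an appliance fires several times per interval.

At test time each (appliance, interval) observation is weighed into a BBA
by two certainty constants:

    event observed:   m(h1) = P*C0,      m(h2) = (1-P)*C0,  m(h3) = 1-C0
    no event:         m(h1) = (1-P)*C1,  m(h2) = P*C1,      m(h3) = 1-C1

With the defaults C0 = 0.9 and C1 = 0.1 an observed switch-on leaves 10%
uncertainty while an absent one leaves 90%: human behaviour is
non-deterministic, so not using an appliance is weak evidence of anything,
whereas using it is informative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import pandas as pd

from .dst import MassFunction

WEEKDAY_NAMES = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]


@dataclass(frozen=True)
class CertaintyConstants:
    """Certainty attached to the trained probability on event arrival (C0)
    and in absence of an event (C1); both in [0, 1]."""

    c0: float = 0.9
    c1: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.c0 <= 1.0 and 0.0 <= self.c1 <= 1.0):
            raise ValueError(f"certainty constants must lie in [0,1], got {self}")


@dataclass
class UsageProbabilityTable:
    """Trained P(use in interval) per (appliance, weekday, interval).

    ``entries`` maps (appliance_id, weekday 0=Mon..6=Sun, interval_index)
    to a probability; missing keys mean P = 0.  ``weekday_day_counts``
    records how many training days of each weekday supported the estimate.
    """

    interval_hours: int
    entries: dict[tuple[str, int, int], float]
    weekday_day_counts: dict[int, int]
    appliance_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if 24 % self.interval_hours != 0:
            raise ValueError(f"interval_hours must divide 24, got {self.interval_hours}")
        n = self.n_intervals
        for (appliance, weekday, idx), p in self.entries.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of range for {(appliance, weekday, idx)}: {p}")
            if not (0 <= weekday <= 6 and 0 <= idx < n):
                raise ValueError(f"bin out of range: {(appliance, weekday, idx)}")
        if not self.appliance_ids:
            self.appliance_ids = {a for a, _, _ in self.entries}

    @property
    def n_intervals(self) -> int:
        return 24 // self.interval_hours

    def interval_index(self, timestamp: datetime) -> int:
        return timestamp.hour // self.interval_hours

    def lookup(self, appliance_id: str, timestamp: datetime) -> float:
        """P for the (weekday, interval) bin containing ``timestamp``."""
        if appliance_id not in self.appliance_ids:
            raise KeyError(f"appliance {appliance_id!r} not in trained table")
        key = (appliance_id, timestamp.weekday(), self.interval_index(timestamp))
        return self.entries.get(key, 0.0)


def train_usage_table(
    train_log, interval_hours: int = 6, laplace: bool = False
) -> UsageProbabilityTable:
    """Estimate per-bin presence probabilities from a training event log.

    Every appliance in the log's registry gets a row set; appliances with
    no training events keep all-zero probabilities (an event from such an
    appliance at test time is then maximal abnormal evidence).  Spans
    shorter than one full week leave some weekdays unestimated and trigger
    a warning.

    ``laplace`` switches on add-one smoothing, P = (c+1)/(n+2), pulling
    never-seen bins off exact zero; off by default because a hard zero is
    what makes unexpected appliance activity maximally informative.
    """
    if 24 % interval_hours != 0:
        raise ValueError(f"interval_hours must divide 24, got {interval_hours}")
    if not train_log.events:
        raise ValueError("training log contains no events")
    if train_log.n_days < 7:
        warnings.warn(
            f"training span of {train_log.n_days} days is shorter than one week; "
            "some weekdays have no training data",
            stacklevel=2,
        )

    weekday_day_counts = {wd: 0 for wd in range(7)}
    for d in train_log.dates():
        weekday_day_counts[d.weekday()] += 1

    df = train_log.to_frame()
    df["date"] = df["timestamp"].dt.date
    df["weekday"] = df["timestamp"].dt.weekday
    df["interval"] = df["timestamp"].dt.hour // interval_hours
    # presence semantics: several events in one (appliance, day, interval) count once
    presence = df.drop_duplicates(["appliance_id", "date", "interval"])
    counts = presence.groupby(["appliance_id", "weekday", "interval"]).size()

    entries: dict[tuple[str, int, int], float] = {}
    if laplace:
        lookup = {
            (str(a), int(w), int(i)): int(c) for (a, w, i), c in counts.items()
        }
        for appliance in train_log.registry:
            for weekday, n_wd in weekday_day_counts.items():
                if n_wd == 0:
                    continue
                for idx in range(24 // interval_hours):
                    c = lookup.get((appliance, weekday, idx), 0)
                    entries[(appliance, weekday, idx)] = (c + 1.0) / (n_wd + 2.0)
    else:
        for (appliance, weekday, idx), c in counts.items():
            n_wd = weekday_day_counts[weekday]
            if n_wd == 0:
                continue
            entries[(str(appliance), int(weekday), int(idx))] = float(c) / n_wd

    unseen = set(train_log.registry) - {a for a, _, _ in entries}
    if unseen:
        warnings.warn(
            f"appliances with no training events (all-zero usage rows): {sorted(unseen)}",
            stacklevel=2,
        )
    return UsageProbabilityTable(
        interval_hours=interval_hours,
        entries=entries,
        weekday_day_counts=weekday_day_counts,
        appliance_ids=set(train_log.registry),
    )


def assign_mass(p: float, event_present: bool, c: CertaintyConstants) -> MassFunction:
    """Weigh a trained usage probability into a BBA for one observation.

    The event branch commits C0 of the mass according to P, the no-event
    branch commits only C1 (mirrored: habitual-but-missing usage is weak
    abnormal evidence); the remainder is ignorance on h3.  The three
    masses sum to one algebraically.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"usage probability must lie in [0,1], got {p}")
    if event_present:
        return MassFunction(p * c.c0, (1.0 - p) * c.c0, 1.0 - c.c0)
    return MassFunction((1.0 - p) * c.c1, p * c.c1, 1.0 - c.c1)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_usage_table_csv(table: UsageProbabilityTable, path: str | Path) -> None:
    """Write the table as CSV with a leading ``# interval_hours=`` comment.

    Includes day-count metadata lines so a round-trip is exact.
    """
    with open(path, "w") as fh:
        fh.write(f"# interval_hours={table.interval_hours}\n")
        counts = ",".join(str(table.weekday_day_counts.get(wd, 0)) for wd in range(7))
        fh.write(f"# weekday_day_counts={counts}\n")
        fh.write(f"# appliances={';'.join(sorted(table.appliance_ids))}\n")
        fh.write("appliance_id,weekday,interval_index,probability\n")
        for (appliance, weekday, idx), p in sorted(table.entries.items()):
            fh.write(f"{appliance},{WEEKDAY_NAMES[weekday]},{idx},{p!r}\n")


def read_usage_table_csv(path: str | Path) -> UsageProbabilityTable:
    interval_hours = None
    weekday_day_counts = {wd: 0 for wd in range(7)}
    appliance_ids: set[str] = set()
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, value = line[1:].strip().partition("=")
            if key == "interval_hours":
                interval_hours = int(value)
            elif key == "weekday_day_counts":
                weekday_day_counts = {wd: int(v) for wd, v in enumerate(value.split(","))}
            elif key == "appliances":
                appliance_ids = set(value.split(";")) if value else set()
    if interval_hours is None:
        raise ValueError(f"{path} lacks the '# interval_hours=' header comment")
    df = pd.read_csv(path, skiprows=header_lines, dtype={"appliance_id": str})
    wd_index = {name: i for i, name in enumerate(WEEKDAY_NAMES)}
    entries = {
        (str(r.appliance_id), wd_index[r.weekday], int(r.interval_index)): float(r.probability)
        for r in df.itertuples(index=False)
    }
    return UsageProbabilityTable(
        interval_hours=interval_hours,
        entries=entries,
        weekday_day_counts=weekday_day_counts,
        appliance_ids=appliance_ids or {a for a, _, _ in entries},
    )
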