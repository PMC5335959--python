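"""Appliance switch-on event streams: reading, validation, filtering, splitting.

The only observable the scorer consumes is the timestamp at which a
manually operated appliance is switched on.  Appliances with continuous or
automatic consumption (fridge, freezer) carry no information about human
activity and are excluded via a per-appliance ``relevant`` flag in the
registry.  Durations of use are deliberately ignored: an appliance left
running implies no activity, whereas switching it on does.

Timestamps are timezone-naive local time at minute resolution.  Days are
half-open ``[00:00, 24:00)``; an event at exactly midnight belongs to the
day it timestamps.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M"


class EventDataError(ValueError):
    """Malformed or inconsistent event input."""


@dataclass(frozen=True)
class ApplianceEvent:
    """A single switch-on instant of one appliance."""

    appliance_id: str
    timestamp: datetime


@dataclass(frozen=True)
class ApplianceInfo:
    """Registry entry: identifier, human label and relevance flag."""

    appliance_id: str
    label: str = ""
    relevant: bool = True


@dataclass
class EventLog:
    """A time-ordered switch-on event stream with its appliance registry.

    ``span`` is the pair of first and last calendar dates covered; it
    defaults to the dates of the first and last event but may be wider
    (e.g. a monitored period with silent leading/trailing days).
    """

    household_id: str
    registry: dict[str, ApplianceInfo]
    events: list[ApplianceEvent]
    span: tuple[date, date] | None = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.timestamp)
        unknown = sorted({e.appliance_id for e in self.events} - set(self.registry))
        if unknown:
            raise EventDataError(
                f"events reference appliance ids absent from registry: {unknown}"
            )
        if self.span is None:
            if self.events:
                self.span = (self.events[0].timestamp.date(), self.events[-1].timestamp.date())
        else:
            first, last = self.span
            if first > last:
                raise EventDataError(f"span start {first} after span end {last}")
            for e in self.events:
                if not (first <= e.timestamp.date() <= last):
                    raise EventDataError(
                        f"event at {e.timestamp} outside declared span {self.span}"
                    )

    @property
    def n_days(self) -> int:
        if self.span is None:
            return 0
        return (self.span[1] - self.span[0]).days + 1

    def dates(self) -> list[date]:
        """All calendar dates in the span, including event-free ones."""
        if self.span is None:
            return []
        first, last = self.span
        return [first + timedelta(days=i) for i in range(self.n_days)]

    def to_frame(self) -> pd.DataFrame:
        """Events as a tidy DataFrame (appliance_id, timestamp)."""
        return pd.DataFrame(
            {
                "appliance_id": pd.Series(
                    [e.appliance_id for e in self.events], dtype=str
                ),
                "timestamp": pd.Series(
                    [e.timestamp for e in self.events], dtype="datetime64[ns]"
                ),
            }
        )


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------

def read_registry_csv(path: str | Path) -> dict[str, ApplianceInfo]:
    """Read an appliance registry CSV with header ``appliance_id,label,relevant``."""
    df = pd.read_csv(path, dtype={"appliance_id": str, "label": str})
    required = {"appliance_id", "label", "relevant"}
    if not required.issubset(df.columns):
        raise EventDataError(
            f"registry {path} must have columns {sorted(required)}, got {list(df.columns)}"
        )
    if df["appliance_id"].duplicated().any():
        dups = sorted(df.loc[df["appliance_id"].duplicated(), "appliance_id"].unique())
        raise EventDataError(f"duplicate appliance ids in registry: {dups}")
    registry = {}
    for row in df.itertuples(index=False):
        registry[row.appliance_id] = ApplianceInfo(
            appliance_id=row.appliance_id,
            label="" if pd.isna(row.label) else str(row.label),
            relevant=bool(int(row.relevant)),
        )
    return registry


def write_registry_csv(registry: dict[str, ApplianceInfo], path: str | Path) -> None:
    pd.DataFrame(
        {
            "appliance_id": list(registry),
            "label": [a.label for a in registry.values()],
            "relevant": [int(a.relevant) for a in registry.values()],
        }
    ).to_csv(path, index=False)


def read_event_csv(
    path: str | Path,
    registry_path: str | Path,
    household_id: str | None = None,
) -> EventLog:
    """Read a switch-on event CSV (header ``timestamp,appliance_id``) plus registry.

    Events are validated against the registry and sorted by timestamp.
    Unknown appliance ids, malformed timestamps (with the offending line
    number) and empty files all raise :class:`EventDataError`.
    """
    registry = read_registry_csv(registry_path)
    df = pd.read_csv(path, dtype={"appliance_id": str})
    if df.empty:
        raise EventDataError(f"event file {path} contains no events")
    required = {"timestamp", "appliance_id"}
    if not required.issubset(df.columns):
        raise EventDataError(
            f"event file {path} must have columns {sorted(required)}, got {list(df.columns)}"
        )
    parsed = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if parsed.isna().any():
        bad = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise EventDataError(
            f"malformed timestamp {df['timestamp'].iloc[bad]!r} "
            f"at line {bad + 2} of {path}"
        )
    unknown = sorted(set(df["appliance_id"]) - set(registry))
    if unknown:
        raise EventDataError(f"unknown appliance ids in {path}: {unknown}")
    events = [
        ApplianceEvent(a, ts.to_pydatetime().replace(second=0, microsecond=0))
        for a, ts in zip(df["appliance_id"], parsed)
    ]
    if household_id is None:
        household_id = Path(path).stem
    return EventLog(household_id=household_id, registry=registry, events=events)


def write_event_csv(log: EventLog, path: str | Path) -> None:
    """Write the event stream as ``timestamp,appliance_id`` CSV (minute precision)."""
    with open(path, "w") as fh:
        fh.write("timestamp,appliance_id\n")
        for e in log.events:
            fh.write(f"{e.timestamp.strftime(TIMESTAMP_FORMAT)},{e.appliance_id}\n")


# ---------------------------------------------------------------------------
# Switch-on edge detection from raw power channels
# ---------------------------------------------------------------------------

def read_power_series(path: str | Path) -> pd.DataFrame:
    """Read a plain-text power channel: one ``unix_seconds watts`` pair per line."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["unix_seconds", "watts"],
        dtype={"unix_seconds": np.int64, "watts": float},
    )
    df["timestamp"] = pd.to_datetime(df["unix_seconds"], unit="s")
    return df[["timestamp", "watts"]]


def detect_switch_on_events(
    power_series: pd.DataFrame | Sequence[tuple[datetime, float]],
    appliance_id: str,
    on_threshold_watts: float = 10.0,
    min_off_minutes: float = 5.0,
) -> list[ApplianceEvent]:
    """Extract switch-on events as rising edges through a watt threshold.

    An event fires at the first sample at or above ``on_threshold_watts``
    after the channel has been below the threshold for at least
    ``min_off_minutes`` (debounce against brief dips and sensor flicker).
    The series must be time-ordered; the first sample, if already on,
    counts as a switch-on (the off-period before the recording is unknown
    but at least as long as any debounce).
    """
    if on_threshold_watts <= 0:
        raise ValueError("on_threshold_watts must be > 0")
    if min_off_minutes < 0:
        raise ValueError("min_off_minutes must be >= 0")
    if isinstance(power_series, pd.DataFrame):
        times = list(power_series["timestamp"])
        watts = list(power_series["watts"])
    else:
        times = [t for t, _ in power_series]
        watts = [w for _, w in power_series]
    for a, b in zip(times, times[1:]):
        if b < a:
            raise EventDataError(f"power series timestamps not monotone at {b}")

    events: list[ApplianceEvent] = []
    # None = "off for an unknown but unbounded period" (before the recording)
    off_since: datetime | None = None
    was_on = False
    debounce = timedelta(minutes=min_off_minutes)
    for t, w in zip(times, watts):
        on = w >= on_threshold_watts
        if on and not was_on:
            if off_since is None or (t - off_since) >= debounce:
                ts = pd.Timestamp(t).to_pydatetime().replace(second=0, microsecond=0)
                events.append(ApplianceEvent(appliance_id, ts))
            was_on = True
        elif not on:
            if was_on:
                off_since = t
            was_on = False
    return events


# ---------------------------------------------------------------------------
# Filtering and chronological splitting
# ---------------------------------------------------------------------------

def filter_relevant(log: EventLog) -> EventLog:
    """Keep only events of appliances flagged relevant; restrict the registry.

    Emits a warning when nothing survives (a log with no manually operated
    appliances carries no activity information).
    """
    keep = {a for a, info in log.registry.items() if info.relevant}
    events = [e for e in log.events if e.appliance_id in keep]
    if not events:
        warnings.warn(
            f"no relevant appliance events remain in household {log.household_id}",
            stacklevel=2,
        )
    registry = {a: info for a, info in log.registry.items() if a in keep}
    return EventLog(log.household_id, registry, events, span=log.span)


def suggest_auto_cyclers(
    log: EventLog,
    day_coverage: float = 0.9,
    max_median_gap_hours: float = 2.0,
) -> set[str]:
    """Heuristically flag fridge-like automatic cyclers.

    Returns appliance ids with events on more than ``day_coverage`` of the
    log's days AND a median inter-event gap below ``max_median_gap_hours``.
    Relevance remains a manual registry decision; this helper only suggests
    candidates and is not applied anywhere by default.
    """
    suspects: set[str] = set()
    n_days = log.n_days
    if n_days == 0:
        return suspects
    df = log.to_frame()
    for appliance, grp in df.groupby("appliance_id"):
        days_used = grp["timestamp"].dt.date.nunique()
        if days_used / n_days <= day_coverage:
            continue
        gaps = grp["timestamp"].sort_values().diff().dropna()
        if len(gaps) and gaps.median() < timedelta(hours=max_median_gap_hours):
            suspects.add(str(appliance))
    return suspects


def split_train_test(log: EventLog, train_fraction: float = 0.6) -> tuple[EventLog, EventLog]:
    """Chronological split on whole calendar days.

    The training log receives the first ``floor(train_fraction * n_days)``
    days of the span; the test log the remainder.  No day appears in both.
    The earlier portion is used for training because routines drift over
    time and the model must learn the starting routine.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n_days = log.n_days
    if n_days < 2:
        raise EventDataError(f"span of {n_days} day(s) is too short to split")
    # epsilon guards against cases like floor((120/220) * 220) -> 119
    n_train = int(np.floor(train_fraction * n_days + 1e-9))
    if n_train == 0 or n_train == n_days:
        raise EventDataError(
            f"train_fraction {train_fraction} leaves an empty partition over {n_days} days"
        )
    first, last = log.span
    cutoff = first + timedelta(days=n_train)  # first test day
    train_events = [e for e in log.events if e.timestamp.date() < cutoff]
    test_events = [e for e in log.events if e.timestamp.date() >= cutoff]
    train = EventLog(log.household_id, dict(log.registry), train_events,
                     span=(first, cutoff - timedelta(days=1)))
    test = EventLog(log.household_id, dict(log.registry), test_events,
                    span=(cutoff, last))
    return train, test
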