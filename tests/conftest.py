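"""Shared fixtures: tiny hand-checkable event logs and mass-function helpers."""

from __future__ import annotations

import itertools
from datetime import date, datetime

import pytest

from routinescore import ApplianceEvent, ApplianceInfo, EventLog, MassFunction


# The printed two-appliance worked example: appliance X strongly supports a
# normal pattern, Y moderately; fusing them must give (70/78, 6/78, 2/78).
@pytest.fixture
def mass_x() -> MassFunction:
    return MassFunction(0.8, 0.1, 0.1)


@pytest.fixture
def mass_y() -> MassFunction:
    return MassFunction(0.6, 0.2, 0.2)


def joint_combine(masses: list[MassFunction]) -> MassFunction:
    """Independent single-pass Dempster combination oracle.

    Enumerates all 3^N focal-element tuples, multiplies their masses,
    intersects the chosen sets, and normalizes once at the end.  Used to
    cross-check the iterative fold; deliberately brute force.
    """
    sets = {"h1": frozenset({1}), "h2": frozenset({2}), "h3": frozenset({1, 2})}
    acc = {frozenset({1}): 0.0, frozenset({2}): 0.0, frozenset({1, 2}): 0.0}
    conflict = 0.0
    for combo in itertools.product(sets.items(), repeat=len(masses)):
        weight = 1.0
        inter = frozenset({1, 2})
        for (name, s), m in zip(combo, masses):
            weight *= getattr(m, name)
            inter = inter & s
        if not inter:
            conflict += weight
        else:
            acc[inter] += weight
    total = sum(acc.values())
    if total <= 0:
        raise ValueError("total conflict")
    return MassFunction(
        acc[frozenset({1})] / total,
        acc[frozenset({2})] / total,
        acc[frozenset({1, 2})] / total,
    )


@pytest.fixture
def joint_oracle():
    return joint_combine


def make_log(
    rows: list[tuple[str, str]],
    registry: dict[str, bool] | None = None,
    household_id: str = "toy",
    span: tuple[date, date] | None = None,
) -> EventLog:
    """Build an EventLog from (appliance_id, 'YYYY-MM-DDTHH:MM') rows."""
    events = [
        ApplianceEvent(a, datetime.strptime(ts, "%Y-%m-%dT%H:%M")) for a, ts in rows
    ]
    if registry is None:
        registry = {a: True for a, _ in rows}
    reg = {a: ApplianceInfo(a, a.title(), rel) for a, rel in registry.items()}
    return EventLog(household_id=household_id, registry=reg, events=events, span=span)


@pytest.fixture
def toy_log_builder():
    return make_log
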