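"""Gaussian-mixture union-probability baseline for daily routine scoring.

The baseline models, per appliance and per day of the week, the time of
day at which the appliance is used as a 1-D Gaussian mixture (component
count chosen by BIC), together with a usage prevalence (fraction of that
weekday's training days with at least one event).  A test day is scored
per appliance and the per-appliance probabilities are merged with the
union rule:

    union = 1 - prod_a (1 - p_a)

The per-appliance probability construction is this package's
reconstruction of the baseline (which the source literature gives only in
outline): when the appliance fired, p_a is the mixture density at the
best-matching event time normalized by the mixture's peak density, so an
event at the habitual time scores 1 and an off-schedule event scores near
0; when it did not fire, p_a = 1 - prevalence, the probability of a
no-use day for that weekday.  Both choices keep p_a in [0, 1].

The union rule is the baseline's known weakness: a single appliance with a
strict routine saturates the score and masks anomalies in every other
appliance.  The evidence-fusion scorer does not share this failure mode,
which is exactly the contrast this module exists to demonstrate.

Time of day is treated linearly on [0, 24); mixtures do not wrap across
midnight (household appliances rarely straddle it — documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .events import EventLog

_PEAK_GRID = np.linspace(0.0, 24.0, 2401)  # 0.01 h resolution


@dataclass
class ApplianceDayModel:
    """Mixture + prevalence for one (appliance, weekday) cell.

    ``weights/means/variances`` are None when fewer than two training
    events were available (prevalence-only fallback).
    """

    prevalence: float
    weights: np.ndarray | None = None
    means: np.ndarray | None = None
    variances: np.ndarray | None = None
    _peak: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError(f"prevalence out of range: {self.prevalence}")
        if self.weights is not None:
            if abs(float(np.sum(self.weights)) - 1.0) > 1e-6:
                raise ValueError("mixture weights must sum to 1")
            if np.any(np.asarray(self.variances) <= 0):
                raise ValueError("mixture variances must be > 0")

    @property
    def has_mixture(self) -> bool:
        return self.weights is not None

    def density(self, hours: np.ndarray) -> np.ndarray:
        h = np.asarray(hours, dtype=float)[:, None]
        w = np.asarray(self.weights, dtype=float)[None, :]
        mu = np.asarray(self.means, dtype=float)[None, :]
        var = np.asarray(self.variances, dtype=float)[None, :]
        comp = np.exp(-0.5 * (h - mu) ** 2 / var) / np.sqrt(2.0 * np.pi * var)
        return (w * comp).sum(axis=1)

    def peak_density(self) -> float:
        if self._peak is None:
            grid = np.concatenate([_PEAK_GRID, np.asarray(self.means, dtype=float)])
            self._peak = float(self.density(grid).max())
        return self._peak


@dataclass
class GmmUsageModel:
    """Per-(appliance, weekday) mixture models for a household."""

    models: dict[tuple[str, int], ApplianceDayModel]
    appliance_ids: list[str]


@dataclass(frozen=True)
class GmmDailyScore:
    date: Date
    per_appliance: dict[str, float]
    union: float


def _event_hours(ts: pd.Series) -> np.ndarray:
    return (ts.dt.hour + ts.dt.minute / 60.0).to_numpy(dtype=float)


def fit_gmm_model(
    train_log: EventLog, max_components: int = 3, seed: int = 0
) -> GmmUsageModel:
    """Fit time-of-day mixtures per (relevant appliance, weekday).

    Component count is selected by BIC over 1..max_components (capped by
    the sample count); ties break toward fewer components.  Cells with
    fewer than two events fall back to prevalence only.
    """
    if not train_log.events:
        raise ValueError("training log contains no events")
    appliances = sorted(a for a, info in train_log.registry.items() if info.relevant)
    weekday_day_counts = {wd: 0 for wd in range(7)}
    for d in train_log.dates():
        weekday_day_counts[d.weekday()] += 1

    df = train_log.to_frame()
    df = df[df["appliance_id"].isin(appliances)]
    df["weekday"] = df["timestamp"].dt.weekday
    df["date"] = df["timestamp"].dt.date

    models: dict[tuple[str, int], ApplianceDayModel] = {}
    for (appliance, weekday), grp in df.groupby(["appliance_id", "weekday"]):
        n_wd = weekday_day_counts[int(weekday)]
        prevalence = grp["date"].nunique() / n_wd if n_wd else 0.0
        hours = _event_hours(grp["timestamp"])
        cell = ApplianceDayModel(prevalence=min(prevalence, 1.0))
        if len(hours) >= 2:
            X = hours[:, None]
            best = None
            best_bic = np.inf
            for k in range(1, min(max_components, len(hours)) + 1):
                # variance floor ~ (6 min)^2: event times have minute
                # resolution, so narrower spikes are artefacts that let
                # BIC overfit duplicate timestamps
                gm = GaussianMixture(
                    n_components=k, random_state=seed, covariance_type="full",
                    reg_covar=0.01,
                ).fit(X)
                bic = gm.bic(X)
                if bic < best_bic - 1e-9:  # strict improvement: ties keep fewer
                    best, best_bic = gm, bic
            cell = ApplianceDayModel(
                prevalence=min(prevalence, 1.0),
                weights=best.weights_.copy(),
                means=best.means_.ravel().copy(),
                variances=best.covariances_.reshape(-1).copy(),
            )
        models[(str(appliance), int(weekday))] = cell
    return GmmUsageModel(models=models, appliance_ids=appliances)


def gmm_score_day(model: GmmUsageModel, test_log: EventLog, date: Date) -> GmmDailyScore:
    """Per-appliance normality probabilities and their union for one day."""
    first, last = test_log.span
    if not (first <= date <= last):
        raise ValueError(f"date {date} outside test span {test_log.span}")
    df = test_log.to_frame()
    df = df[df["timestamp"].dt.date == date]
    weekday = date.weekday()
    per_appliance: dict[str, float] = {}
    for appliance in model.appliance_ids:
        cell = model.models.get((appliance, weekday))
        hours = _event_hours(df.loc[df["appliance_id"] == appliance, "timestamp"])
        if len(hours) == 0:
            # no-use day: its probability under the trained weekday prevalence
            p = 1.0 - (cell.prevalence if cell else 0.0)
        elif cell is None:
            p = 0.0  # never used on this weekday in training
        elif cell.has_mixture:
            p = float(np.max(cell.density(hours)) / cell.peak_density())
        else:
            # events observed but times unmodelled: fall back to prevalence
            p = cell.prevalence
        per_appliance[appliance] = min(max(p, 0.0), 1.0)
    union = 1.0 - float(np.prod([1.0 - p for p in per_appliance.values()]))
    return GmmDailyScore(date=date, per_appliance=per_appliance, union=union)


def gmm_score_period(model: GmmUsageModel, test_log: EventLog) -> list[GmmDailyScore]:
    return [gmm_score_day(model, test_log, d) for d in test_log.dates()]


def gmm_score_week(daily_scores: Sequence[GmmDailyScore]) -> pd.Series:
    """Calendar-week (Mon-Sun) mean of daily union scores; indexed by week start."""
    s = pd.Series(
        [d.union for d in daily_scores],
        index=pd.to_datetime([d.date for d in daily_scores]),
    )
    weekly = s.groupby(s.index.to_period("W-SUN")).mean()
    weekly.index = weekly.index.start_time.date
    return weekly


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_gmm_model(model: GmmUsageModel, path: str | Path) -> None:
    """Structured-text dump: one block per (appliance, weekday) cell."""
    with open(path, "w") as fh:
        fh.write(f"appliances: {';'.join(model.appliance_ids)}\n")
        for (appliance, weekday), cell in sorted(model.models.items()):
            fh.write(f"[{appliance}|{weekday}]\n")
            fh.write(f"prevalence: {float(cell.prevalence)!r}\n")
            if cell.has_mixture:
                for w, mu, var in zip(cell.weights, cell.means, cell.variances):
                    fh.write(f"component: {float(w)!r},{float(mu)!r},{float(var)!r}\n")


def read_gmm_model(path: str | Path) -> GmmUsageModel:
    models: dict[tuple[str, int], ApplianceDayModel] = {}
    appliance_ids: list[str] = []
    key = None
    prevalence = 0.0
    comps: list[tuple[float, float, float]] = []

    def flush() -> None:
        if key is None:
            return
        if comps:
            w, mu, var = (np.array(col) for col in zip(*comps))
            models[key] = ApplianceDayModel(prevalence, w / w.sum(), mu, var)
        else:
            models[key] = ApplianceDayModel(prevalence)

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("appliances:"):
                value = line.split(":", 1)[1].strip()
                appliance_ids = value.split(";") if value else []
            elif line.startswith("["):
                flush()
                appliance, weekday = line[1:-1].rsplit("|", 1)
                key, prevalence, comps = (appliance, int(weekday)), 0.0, []
            elif line.startswith("prevalence:"):
                prevalence = float(line.split(":", 1)[1])
            elif line.startswith("component:"):
                comps.append(tuple(float(x) for x in line.split(":", 1)[1].split(",")))
    flush()
    return GmmUsageModel(models=models, appliance_ids=appliance_ids)
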