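"""Dempster-Shafer evidence machinery on the fixed three-hypothesis frame.

The frame of discernment is Omega = {normal pattern, abnormal pattern}.
Its power set yields three focal elements: h1 (normal), h2 (abnormal) and
h3 = h1 u h2 (either; total ignorance).  The empty set carries mass zero by
construction.  Each appliance observation produces a basic belief
assignment (BBA) over these three elements; Dempster's rule of combination
fuses independent BBAs into an accumulated belief, and belief/plausibility
bound the probability of each hypothesis from below and above.

The frame is deliberately hard-coded: a general power-set engine would add
surface without coverage, since every mass function in this method lives on
exactly these three focal elements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

#: absolute tolerance for the sum-to-one mass invariant
MASS_SUM_TOL = 1e-9
#: conflict K at or above 1 - this is treated as total conflict
TOTAL_CONFLICT_TOL = 1e-12


class Hypothesis(Enum):
    """Focal elements of the power set of {normal, abnormal}."""

    H1_NORMAL = "h1"
    H2_ABNORMAL = "h2"
    H3_EITHER = "h3"  # h1 u h2, i.e. the whole frame Omega


class TotalConflictError(ValueError):
    """Raised when two mass functions are in full contradiction (K ~ 1).

    Only possible when both operands put zero mass on h3 and their
    committed beliefs oppose each other; with any residual ignorance on
    either side the conflict K stays strictly below one.
    """


@dataclass(frozen=True)
class MassFunction:
    """A basic belief assignment over {h1, h2, h3}.

    Masses are non-negative and sum to one; m(empty set) = 0 is implicit.
    """

    h1: float
    h2: float
    h3: float

    def __post_init__(self) -> None:
        for name, v in (("h1", self.h1), ("h2", self.h2), ("h3", self.h3)):
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"mass m({name}) must be a finite number, got {v!r}")
            if v < 0:
                raise ValueError(f"mass m({name}) must be >= 0, got {v}")
        total = self.h1 + self.h2 + self.h3
        if abs(total - 1.0) > MASS_SUM_TOL:
            raise ValueError(f"masses must sum to 1 (got {total!r})")

    @classmethod
    def vacuous(cls) -> "MassFunction":
        """Total ignorance: all mass on h3.  Neutral element of combination."""
        return cls(0.0, 0.0, 1.0)

    def mass(self, a: Hypothesis) -> float:
        return {
            Hypothesis.H1_NORMAL: self.h1,
            Hypothesis.H2_ABNORMAL: self.h2,
            Hypothesis.H3_EITHER: self.h3,
        }[a]


def conflict(m1: MassFunction, m2: MassFunction) -> float:
    """Dempster conflict K: total mass landing on empty intersections.

    On this frame only h1 x h2 and h2 x h1 intersect to the empty set.
    """
    return m1.h1 * m2.h2 + m1.h2 * m2.h1


def combine(m1: MassFunction, m2: MassFunction) -> MassFunction:
    """Dempster's rule of combination for two BBAs on the fixed frame.

    Intersections follow set algebra: h1^h1 = h1, h1^h3 = h1, h2^h3 = h2,
    h3^h3 = h3; h1^h2 is empty and feeds the conflict K.  The surviving
    products are renormalized by 1 - K.

    Raises
    ------
    TotalConflictError
        If K >= 1 - 1e-12 (both operands fully committed and opposed).
    """
    k = conflict(m1, m2)
    denom = 1.0 - k
    if denom <= TOTAL_CONFLICT_TOL:
        raise TotalConflictError(
            f"total conflict between mass functions (K = {k!r}); "
            "combination is undefined"
        )
    # cross terms grouped pairwise so the result is bit-identical under
    # argument swap (IEEE addition of two floats is commutative)
    h1 = (m1.h1 * m2.h1 + (m1.h1 * m2.h3 + m1.h3 * m2.h1)) / denom
    h2 = (m1.h2 * m2.h2 + (m1.h2 * m2.h3 + m1.h3 * m2.h2)) / denom
    h3 = (m1.h3 * m2.h3) / denom
    # renormalize to absorb floating-point rounding
    total = h1 + h2 + h3
    return MassFunction(h1 / total, h2 / total, h3 / total)


def combine_all(masses: Sequence[MassFunction] | Iterable[MassFunction]) -> MassFunction:
    """Left fold of :func:`combine` over a non-empty sequence of BBAs.

    By associativity of Dempster's rule the fold equals the joint
    combination computed in a single pass; the fold is simply cheaper.
    A length-one sequence is returned unchanged.
    """
    masses = list(masses)
    if not masses:
        raise ValueError("combine_all requires at least one mass function")
    acc = masses[0]
    for step, m in enumerate(masses[1:], start=2):
        try:
            acc = combine(acc, m)
        except TotalConflictError as exc:
            raise TotalConflictError(
                f"total conflict at fusion step {step} of {len(masses)}: {exc}"
            ) from exc
    return acc


def belief(m: MassFunction, a: Hypothesis) -> float:
    """bel(A): sum of masses of all focal elements contained in A."""
    if a is Hypothesis.H1_NORMAL:
        return m.h1
    if a is Hypothesis.H2_ABNORMAL:
        return m.h2
    return m.h1 + m.h2 + m.h3  # the whole frame: always 1 up to rounding


def plausibility(m: MassFunction, a: Hypothesis) -> float:
    """pl(A): sum of masses of all focal elements intersecting A."""
    if a is Hypothesis.H1_NORMAL:
        return m.h1 + m.h3
    if a is Hypothesis.H2_ABNORMAL:
        return m.h2 + m.h3
    return m.h1 + m.h2 + m.h3


@dataclass(frozen=True)
class BeliefInterval:
    """[bel, pl] bounds on the probability of a hypothesis.

    The width pl - bel is the residual ignorance about the hypothesis.
    """

    bel: float
    pl: float

    def __post_init__(self) -> None:
        if not (-MASS_SUM_TOL <= self.bel <= self.pl + MASS_SUM_TOL <= 1.0 + 2 * MASS_SUM_TOL):
            raise ValueError(f"invalid belief interval [{self.bel}, {self.pl}]")

    @property
    def width(self) -> float:
        return self.pl - self.bel


def interval(m: MassFunction, a: Hypothesis) -> BeliefInterval:
    """The [bel(A), pl(A)] uncertainty interval for hypothesis ``a``."""
    return BeliefInterval(belief(m, a), plausibility(m, a))


def truncate2(x: float) -> float:
    """Truncate (floor) to two decimal places.

    Display convention used when reproducing printed worked-example values
    (0.8974 -> 0.89, 0.9231 -> 0.92); internal arithmetic stays at full
    precision.
    """
    return math.floor(x * 100.0) / 100.0
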