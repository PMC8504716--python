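"""Core data containers for a parallel-arm trial with a dichotomous endpoint.

A completed two-arm randomized controlled trial with a yes/no outcome (e.g.
all-cause death) is summarised by a 2x2 table: event / no-event counts in the
control arm (a, c) and in the experimental arm (b, d).  Everything downstream
— event rates, the responder decomposition, the chi-square test — is a pure
function of these four integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterator

__all__ = [
    "TrialTable2x2",
    "EventRates",
    "ParticipantBreakdown",
    "ChiSquareResult",
    "TableInvariantError",
    "DecompositionError",
    "ZeroMarginError",
    "InfeasibleGridPointError",
    "round_half_up",
    "ROUNDING_RULES",
]


class TableInvariantError(ValueError):
    """A 2x2 trial table violates one of its structural invariants."""


class DecompositionError(ValueError):
    """A category count in the responder decomposition came out negative."""


class ZeroMarginError(ValueError):
    """A margin of the 2x2 table is zero, so the chi-square statistic is undefined."""


class InfeasibleGridPointError(ValueError):
    """A sweep grid point yields a negative arm or cell count."""


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    This is the everyday "round to the closest unit" rule (0.5 -> 1), as
    opposed to Python's built-in banker's rounding (0.5 -> 0).
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


def _round_bankers(x: float) -> int:
    return int(round(x))


#: Registry of rounding-rule identifiers accepted by configs.
ROUNDING_RULES = {"half-up": round_half_up, "bankers": _round_bankers}


@dataclass(frozen=True)
class TrialTable2x2:
    """Summary counts of a completed two-arm RCT.

    Parameters
    ----------
    a : int
        Events in the control arm.
    b : int
        Events in the experimental arm.
    c : int
        Event-free participants in the control arm.
    d : int
        Event-free participants in the experimental arm.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TableInvariantError(f"cell {f.name!r} must be an integer, got {v!r}")
            if v < 0:
                raise TableInvariantError(f"cell {f.name!r} must be >= 0, got {v}")
        if self.a + self.c == 0:
            raise TableInvariantError("control arm is empty (a + c = 0)")
        if self.b + self.d == 0:
            raise TableInvariantError("experimental arm is empty (b + d = 0)")

    @property
    def Nc(self) -> int:
        """Control arm size (a + c)."""
        return self.a + self.c

    @property
    def NT(self) -> int:
        """Experimental arm size (b + d)."""
        return self.b + self.d

    @property
    def N(self) -> int:
        """Total enrolment."""
        return self.Nc + self.NT

    @classmethod
    def from_margins(cls, a: int, b: int, Nc: int, NT: int) -> "TrialTable2x2":
        """Build a table from event counts and arm totals."""
        if a > Nc or b > NT:
            raise TableInvariantError(
                f"events exceed arm size (a={a}, Nc={Nc}, b={b}, NT={NT})"
            )
        return cls(a=a, b=b, c=Nc - a, d=NT - b)

    def cells(self) -> Iterator[int]:
        yield from (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class EventRates:
    """Observed event rates and effect measures of a 2x2 trial.

    Attributes
    ----------
    Rc, RT : float
        Event rates a/Nc and b/NT in the control and experimental arms.
    AB : float
        Absolute benefit, Rc - RT.
    RR : float or None
        Relative risk RT/Rc; ``None`` when Rc = 0 (undefined).
    """

    Rc: float
    RT: float
    AB: float
    RR: float | None

    def __post_init__(self) -> None:
        if not (0.0 <= self.Rc <= 1.0 and 0.0 <= self.RT <= 1.0):
            raise ValueError("event rates must lie in [0, 1]")

    @property
    def relative_risk(self) -> float:
        """RR, raising instead of silently returning a placeholder when Rc = 0."""
        if self.RR is None:
            raise ZeroDivisionError("relative risk undefined: control event rate is 0")
        return self.RR


@dataclass(frozen=True)
class ParticipantBreakdown:
    """Counts of the five participant categories in a completed trial.

    Responders are participants who present the event untreated and avoid it
    when treated; they carry all the efficacy information.  Non-responders
    present the event in either arm; non-informative participants present it
    in neither.  Unnecessary participants (non-responders + non-informative)
    cannot benefit regarding the primary outcome, and ethical losses are all
    enrolled participants except the experimental-arm responders — the only
    ones who actually benefit.
    """

    responders_T: int
    potential_responders_C: int
    nonresponders_T: int
    nonresponders_C: int
    noninformative: int
    d2: int

    def __post_init__(self) -> None:
        for name in (
            "responders_T",
            "potential_responders_C",
            "nonresponders_T",
            "nonresponders_C",
            "noninformative",
            "d2",
        ):
            if getattr(self, name) < 0:
                raise DecompositionError(
                    f"category {name!r} is negative ({getattr(self, name)}): "
                    "the table is structurally inconsistent with the responder model"
                )

    @property
    def responders_total(self) -> int:
        return self.responders_T + self.potential_responders_C

    @property
    def nonresponders_total(self) -> int:
        return self.nonresponders_T + self.nonresponders_C

    @property
    def unnecessary(self) -> int:
        """Participants who cannot benefit: non-responders + non-informative."""
        return self.noninformative + self.nonresponders_total

    @property
    def ethical_losses(self) -> int:
        """Everyone enrolled except the experimental-arm responders."""
        return self.unnecessary + self.potential_responders_C

    @property
    def total(self) -> int:
        return self.responders_total + self.unnecessary

    def to_dict(self) -> dict[str, int]:
        return {
            "responders_T": self.responders_T,
            "potential_responders_C": self.potential_responders_C,
            "responders_total": self.responders_total,
            "nonresponders_T": self.nonresponders_T,
            "nonresponders_C": self.nonresponders_C,
            "nonresponders_total": self.nonresponders_total,
            "noninformative": self.noninformative,
            "unnecessary": self.unnecessary,
            "ethical_losses": self.ethical_losses,
            "d2": self.d2,
            "total": self.total,
        }


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-square test of the 2x2 table (df = 1)."""

    statistic: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("chi-square statistic must be >= 0")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")
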