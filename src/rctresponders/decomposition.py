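"""Responder decomposition of a 2x2 trial table.

Under exchangeability (both arms drawn from the same population), the
experimental arm would have seen ``a * NT / Nc`` events had nobody been
treated.  The shortfall relative to the observed events ``b`` identifies the
responders in the treated arm; scaling by the arm-size ratio identifies their
counterparts ("potential responders") in the control arm.  The remaining
participants split into non-responders (event in either arm) and
non-informative participants (event in neither arm).

All counts are rounded to whole participants at the final step, never at the
intermediate rates; the default rule rounds halves away from zero.  The
framework assumes the experimental treatment is at least as good as the
control: when the data point the other way the responder count is clamped at
zero and a warning is emitted.
"""

from __future__ import annotations

import warnings
from typing import Callable

from scipy import stats

from .table import (
    ChiSquareResult,
    DecompositionError,
    EventRates,
    ParticipantBreakdown,
    ROUNDING_RULES,
    TrialTable2x2,
    ZeroMarginError,
    round_half_up,
)

__all__ = [
    "event_rates",
    "expected_events_if_untreated",
    "responders_in_T",
    "potential_responders_in_C",
    "decompose",
    "ethical_loss_fraction",
    "chi_square_2x2",
    "HarmfulTreatmentWarning",
]


class HarmfulTreatmentWarning(UserWarning):
    """The experimental arm shows more events than expected untreated."""


def _resolve_rounding(rounding: str | Callable[[float], int]) -> Callable[[float], int]:
    if callable(rounding):
        return rounding
    try:
        return ROUNDING_RULES[rounding]
    except KeyError:
        raise ValueError(
            f"unknown rounding rule {rounding!r}; known rules: {sorted(ROUNDING_RULES)}"
        ) from None


def event_rates(table: TrialTable2x2) -> EventRates:
    """Observed event rates, absolute benefit and relative risk.

    Rc = a/Nc and RT = b/NT; the absolute benefit is AB = Rc - RT and the
    relative risk RR = RT/Rc.  RR is ``None`` when no control events occurred
    (accessing :attr:`EventRates.relative_risk` then raises rather than
    returning a silent zero).
    """
    Rc = table.a / table.Nc
    RT = table.b / table.NT
    RR = RT / Rc if Rc > 0 else None
    return EventRates(Rc=Rc, RT=RT, AB=Rc - RT, RR=RR)


def expected_events_if_untreated(
    table: TrialTable2x2, rounding: str | Callable[[float], int] = "half-up"
) -> int:
    """Events the experimental arm would have shown without treatment.

    Exchangeability puts the untreated event rate at the control rate a/Nc,
    so the expected count is ``a * NT / Nc``, rounded to whole participants.
    """
    rnd = _resolve_rounding(rounding)
    return rnd(table.a * table.NT / table.Nc)


def responders_in_T(
    table: TrialTable2x2, rounding: str | Callable[[float], int] = "half-up"
) -> int:
    """Number of responders in the experimental arm.

    Canonical route: rounded expected untreated events minus observed events,
    ``round(a*NT/Nc) - b`` — algebraically ``(Rc - RT) * NT`` up to the
    rounding route.  Clamped at zero (with :class:`HarmfulTreatmentWarning`)
    when the experimental arm did worse than expected, since the model
    assumes the experimental treatment is at least as good as the control.
    """
    expected = expected_events_if_untreated(table, rounding)
    n = expected - table.b
    if n < 0:
        warnings.warn(
            "experimental arm shows more events than expected untreated "
            f"({table.b} > {expected}); responder count clamped at 0",
            HarmfulTreatmentWarning,
            stacklevel=2,
        )
        return 0
    return n


def potential_responders_in_C(
    table: TrialTable2x2, rounding: str | Callable[[float], int] = "half-up"
) -> int:
    """Responder-profile participants randomized to the control arm.

    The treated-arm responders scaled by the arm-size ratio Nc/NT; these
    participants present the event by definition and sit among the ``a``
    control-arm events.
    """
    rnd = _resolve_rounding(rounding)
    return rnd(responders_in_T(table, rounding) * table.Nc / table.NT)


def decompose(
    table: TrialTable2x2, rounding: str | Callable[[float], int] = "half-up"
) -> ParticipantBreakdown:
    """Split all enrolled participants into the five response categories.

    Returns a :class:`ParticipantBreakdown` with responders per arm,
    non-responders per arm (all treated-arm events, plus control events not
    attributed to potential responders), non-informative participants
    (event-free in both arms: c + d minus the treated-arm responders hidden
    in d), and the derived unnecessary / ethical-loss totals.

    Raises
    ------
    DecompositionError
        If any category count comes out negative, naming the offender.
    """
    r_T = responders_in_T(table, rounding)
    pr_C = potential_responders_in_C(table, rounding)
    if pr_C > table.a:
        raise DecompositionError(
            f"potential responders in C ({pr_C}) exceed control-arm events ({table.a})"
        )
    if r_T > table.d:
        raise DecompositionError(
            f"responders in T ({r_T}) exceed event-free treated participants ({table.d})"
        )
    return ParticipantBreakdown(
        responders_T=r_T,
        potential_responders_C=pr_C,
        nonresponders_T=table.b,
        nonresponders_C=table.a - pr_C,
        noninformative=table.c + table.d - r_T,
        d2=table.d - r_T,
    )


def ethical_loss_fraction(breakdown: ParticipantBreakdown, total: int) -> float:
    """Share of enrolled participants who suffer ethical loss.

    Everyone except the experimental-arm responders: they bore the burden of
    participation without benefiting regarding the primary outcome.
    """
    if total <= 0:
        raise ValueError("total enrolment must be positive")
    return breakdown.ethical_losses / total


def chi_square_2x2(
    table: TrialTable2x2, continuity_correction: bool = False
) -> ChiSquareResult:
    """Pearson chi-square test of arm-by-outcome association (df = 1).

    Expected cell counts are row_total * col_total / N; the statistic is the
    usual sum of squared Pearson residuals, optionally Yates-corrected.  The
    p-value is the upper tail of the chi-square distribution with 1 df.

    Raises
    ------
    ZeroMarginError
        If any row or column margin is zero (statistic undefined).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.N
    row_event, row_free = a + b, c + d
    col_c, col_t = table.Nc, table.NT
    if min(row_event, row_free, col_c, col_t) == 0:
        raise ZeroMarginError("a zero margin makes the chi-square statistic undefined")
    observed = (a, b, c, d)
    expected = (
        row_event * col_c / n,
        row_event * col_t / n,
        row_free * col_c / n,
        row_free * col_t / n,
    )
    stat = 0.0
    for o, e in zip(observed, expected):
        dev = abs(o - e)
        if continuity_correction:
            dev = max(dev - 0.5, 0.0)
        stat += dev * dev / e
    return ChiSquareResult(
        statistic=stat, df=1, p_value=float(stats.chi2.sf(stat, df=1))
    )
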