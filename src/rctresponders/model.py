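"""Model/Results interface over the responder decomposition.

`ResponderTrialModel` wraps a completed 2x2 trial; `fit()` performs the
decomposition and returns a `ResponderTrialResults` carrying the event
rates, the five-category breakdown, the efficacy test and a printable
summary in the style of a demographics table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import decomposition as dec
from .table import (
    ChiSquareResult,
    EventRates,
    ParticipantBreakdown,
    TrialTable2x2,
)

__all__ = ["ResponderTrialModel", "ResponderTrialResults"]


class ResponderTrialModel:
    """Responder decomposition of a parallel-arm RCT with a binary endpoint.

    Parameters
    ----------
    table : TrialTable2x2
        Observed event / no-event counts per arm.
    rounding : str
        Rule used when converting fractional expected counts to whole
        participants: ``"half-up"`` (default, halves away from zero) or
        ``"bankers"``.

    Examples
    --------
    >>> m = ResponderTrialModel.from_counts(a=194, b=269, c=2139, d=4418)
    >>> res = m.fit()
    >>> res.breakdown.responders_total
    181
    """

    def __init__(self, table: TrialTable2x2, rounding: str = "half-up"):
        self.table = table
        self.rounding = rounding

    @classmethod
    def from_counts(cls, a: int, b: int, c: int, d: int, **kwargs) -> "ResponderTrialModel":
        """Build from the four cell counts (events a, b; event-free c, d)."""
        return cls(TrialTable2x2(a=a, b=b, c=c, d=d), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ResponderTrialModel":
        """Build from a two-row frame with columns ``arm``, ``events``, ``no_events``.

        ``arm`` must contain exactly the labels ``"C"`` and ``"T"``.
        """
        required = {"arm", "events", "no_events"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        by_arm = df.set_index("arm")
        if set(by_arm.index) != {"C", "T"}:
            raise ValueError(f"expected arms {{'C', 'T'}}, got {set(by_arm.index)}")
        return cls(
            TrialTable2x2(
                a=int(by_arm.loc["C", "events"]),
                b=int(by_arm.loc["T", "events"]),
                c=int(by_arm.loc["C", "no_events"]),
                d=int(by_arm.loc["T", "no_events"]),
            ),
            **kwargs,
        )

    def fit(self) -> "ResponderTrialResults":
        """Run the decomposition and efficacy test."""
        table = self.table
        return ResponderTrialResults(
            model=self,
            table=table,
            rates=dec.event_rates(table),
            breakdown=dec.decompose(table, self.rounding),
            expected_untreated_events=dec.expected_events_if_untreated(
                table, self.rounding
            ),
            chi2=dec.chi_square_2x2(table),
        )


@dataclass(frozen=True)
class ResponderTrialResults:
    """Fitted responder decomposition of one trial."""

    model: ResponderTrialModel
    table: TrialTable2x2
    rates: EventRates
    breakdown: ParticipantBreakdown
    expected_untreated_events: int
    chi2: ChiSquareResult

    @property
    def ethical_loss_fraction(self) -> float:
        return dec.ethical_loss_fraction(self.breakdown, self.table.N)

    def to_frame(self) -> pd.DataFrame:
        """Breakdown as a tidy one-column frame of participant counts."""
        return pd.DataFrame.from_dict(
            self.breakdown.to_dict(), orient="index", columns=["count"]
        )

    def summary(self) -> str:
        """Human-readable report mirroring a trial demographics table."""
        t, bd, r = self.table, self.breakdown, self.rates
        rr = f"{r.RR:.3f}" if r.RR is not None else "undefined (Rc = 0)"
        lines = [
            "Responder decomposition of a two-arm RCT",
            "=" * 56,
            f"{'Arm':<26}{'Events':>10}{'No event':>10}{'Total':>10}",
            f"{'Control (C)':<26}{t.a:>10}{t.c:>10}{t.Nc:>10}",
            f"{'Experimental (T)':<26}{t.b:>10}{t.d:>10}{t.NT:>10}",
            f"{'Total':<26}{t.a + t.b:>10}{t.c + t.d:>10}{t.N:>10}",
            "-" * 56,
            f"{'Control event rate Rc':<38}{r.Rc:>10.4f}",
            f"{'Experimental event rate RT':<38}{r.RT:>10.4f}",
            f"{'Absolute benefit (Rc - RT)':<38}{r.AB:>10.4f}",
            f"{'Relative risk (RT / Rc)':<38}{rr:>10}",
            f"{'Chi-square (df=1)':<38}{self.chi2.statistic:>10.2f}",
            f"{'p-value':<38}{self.chi2.p_value:>10.2e}",
            "-" * 56,
            f"{'Expected T events if untreated':<38}{self.expected_untreated_events:>10}",
            f"{'Responders (T arm)':<38}{bd.responders_T:>10}",
            f"{'Potential responders (C arm)':<38}{bd.potential_responders_C:>10}",
            f"{'Responders, total':<38}{bd.responders_total:>10}",
            f"{'Non-responders':<38}{bd.nonresponders_total:>10}",
            f"{'Non-informative':<38}{bd.noninformative:>10}",
            f"{'Unnecessary participants':<38}{bd.unnecessary:>10}",
            f"{'Ethical losses':<38}{bd.ethical_losses:>10}",
            f"{'Ethical-loss share':<38}{self.ethical_loss_fraction * 100:>9.1f}%",
            "=" * 56,
        ]
        return "\n".join(lines)
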