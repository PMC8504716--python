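"""Trial-family reconstruction over a grid of responder proportions.

Starting from a seed trial, a family of hypothetical RCTs is built by varying
the proportion ``p`` of responders in the enrolled sample while holding fixed:
the experimental-arm responder subgroup (121 in the seed trial), its
control-arm counterpart (60), the allocation ratio, and the untreated event
probability of unnecessary participants.  Each grid point yields a complete
2x2 table from which sample size, ethical losses, relative risk and the
chi-square efficacy statistic are read off.

Reconstruction at proportion p:

* total responders ``R`` = fixed T-arm responders + their C-arm counterpart,
* total sample size ``N = R / p``,
* arms split by the seed allocation ratio,
* every C-arm potential responder presents the event,
* every unnecessary participant presents the event with the fixed untreated
  probability (the seed control rate) in both arms.

Counts are rounded to whole participants per the configured rule.  Because
the experimental event count shrinks to single digits as p -> 1, this
integerization adds +/-1-count jitter on top of the smooth underlying
curves; each row therefore also carries the pre-rounding (continuous-model)
metrics, and trend verdicts are taken on those (see `trend_check`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import decomposition as dec
from .table import InfeasibleGridPointError, ROUNDING_RULES, TrialTable2x2

__all__ = ["SweepConfig", "SweepRow", "TrendReport", "reconstruct_trial", "run_sweep", "trend_check"]

# Seed trial: 2:1 experimental:control allocation, 194/2333 control mortality,
# 121 experimental-arm responders.
_SEED_NC, _SEED_NT = 2333, 4687
_SEED_A = 194
_SEED_RESPONDERS_T = 121


class SweepConfig(BaseModel):
    """Parameters of the responder-proportion sweep.

    Attributes
    ----------
    responders_T_fixed : int
        Experimental-arm responder subgroup, held constant across the family.
    arm_ratio : float
        Experimental-arm share of total enrolment, NT / (Nc + NT).
    Rc_unnecessary : float
        Untreated event probability of unnecessary participants (the seed
        control event rate), constant across all reconstructed trials.
    p_start, p_stop, p_step : float
        Responder-proportion grid (inclusive ends); the default
        0.025 .. 1.0 by 0.025 gives 40 trials.  p = 0 is excluded since
        sample size diverges there.
    rounding : str
        Rounding rule identifier ("half-up" or "bankers").
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    responders_T_fixed: int = Field(default=_SEED_RESPONDERS_T, gt=0)
    arm_ratio: float = Field(default=_SEED_NT / (_SEED_NC + _SEED_NT), gt=0.0, lt=1.0)
    Rc_unnecessary: float = Field(default=_SEED_A / _SEED_NC, ge=0.0, le=1.0)
    p_start: float = Field(default=0.025, gt=0.0)
    p_stop: float = Field(default=1.0, le=1.0)
    p_step: float = Field(default=0.025, gt=0.0)
    rounding: str = "half-up"

    @model_validator(mode="after")
    def _check_grid(self) -> "SweepConfig":
        if not (self.p_step <= self.p_stop):
            raise ValueError("require 0 < p_step <= p_stop <= 1")
        if self.p_start < self.p_step:
            raise ValueError("p_start must be >= p_step (p = 0 diverges)")
        if self.p_start > self.p_stop:
            raise ValueError("p_start must be <= p_stop")
        if self.rounding not in ROUNDING_RULES:
            raise ValueError(f"unknown rounding rule {self.rounding!r}")
        return self

    @property
    def potential_responders_C(self) -> int:
        """C-arm responder counterpart, fixed across the family."""
        rnd = ROUNDING_RULES[self.rounding]
        return rnd(self.responders_T_fixed * (1.0 - self.arm_ratio) / self.arm_ratio)

    @property
    def responders_total(self) -> int:
        return self.responders_T_fixed + self.potential_responders_C

    def grid(self) -> np.ndarray:
        """Responder-proportion grid points, ascending."""
        n = int(round((self.p_stop - self.p_start) / self.p_step)) + 1
        return self.p_start + self.p_step * np.arange(n)


@dataclass(frozen=True)
class SweepRow:
    """One reconstructed trial of the family.

    Integer counts and the metrics computed from them follow the
    whole-participant rounding rule; the ``*_exact`` fields are the same
    quantities from the continuous (pre-rounding) reconstruction.
    """

    p: float
    N: int
    Nc: int
    NT: int
    a: int
    b: int
    ethical_losses: int
    ethical_loss_pct: float
    RR: float
    chi2: float
    N_exact: float
    ethical_loss_pct_exact: float
    RR_exact: float
    chi2_exact: float


def _pearson_chi2(a: float, b: float, Nc: float, NT: float) -> float:
    """Pearson statistic on possibly fractional cell counts."""
    n = Nc + NT
    r1, r2 = a + b, n - a - b
    stat = 0.0
    for o, e in (
        (a, r1 * Nc / n),
        (b, r1 * NT / n),
        (Nc - a, r2 * Nc / n),
        (NT - b, r2 * NT / n),
    ):
        stat += (o - e) ** 2 / e
    return stat


def _reconstruct_exact(p: float, config: SweepConfig) -> tuple[float, float, float, float]:
    """Continuous-model cell counts (a, b, Nc, NT) at proportion p."""
    r_T = config.responders_T_fixed
    pr_C = config.potential_responders_C
    N = (r_T + pr_C) / p
    NT = N * config.arm_ratio
    Nc = N - NT
    b = config.Rc_unnecessary * (NT - r_T)
    a = pr_C + config.Rc_unnecessary * (Nc - pr_C)
    return a, b, Nc, NT


def reconstruct_trial(p: float, config: SweepConfig | None = None) -> TrialTable2x2:
    """Reconstruct the 2x2 table of the family member at responder proportion p.

    Raises
    ------
    InfeasibleGridPointError
        If p puts an arm below its fixed responder subgroup or any cell
        count below zero.
    """
    config = config or SweepConfig()
    if not (0.0 < p <= 1.0):
        raise InfeasibleGridPointError(f"responder proportion must be in (0, 1], got {p}")
    rnd = ROUNDING_RULES[config.rounding]
    r_T = config.responders_T_fixed
    pr_C = config.potential_responders_C
    N = rnd(config.responders_total / p)
    NT = rnd(N * config.arm_ratio)
    Nc = N - NT
    unnecessary_T = NT - r_T
    unnecessary_C = Nc - pr_C
    if unnecessary_T < 0 or unnecessary_C < 0:
        raise InfeasibleGridPointError(
            f"p={p}: arm smaller than its fixed responder subgroup "
            f"(Nc={Nc} vs {pr_C}, NT={NT} vs {r_T})"
        )
    b = rnd(config.Rc_unnecessary * unnecessary_T)
    a = pr_C + rnd(config.Rc_unnecessary * unnecessary_C)
    return TrialTable2x2.from_margins(a=a, b=b, Nc=Nc, NT=NT)


def run_sweep(config: SweepConfig | None = None) -> list[SweepRow]:
    """Reconstruct the full family over the configured grid (ascending in p).

    Each row's integer metrics come from the decomposition and chi-square
    operations applied to the reconstructed table.
    """
    config = config or SweepConfig()
    rows: list[SweepRow] = []
    for p in config.grid():
        p = float(p)
        table = reconstruct_trial(p, config)
        rates = dec.event_rates(table)
        chi2 = dec.chi_square_2x2(table).statistic
        ethical = table.N - config.responders_T_fixed
        a_x, b_x, nc_x, nt_x = _reconstruct_exact(p, config)
        n_x = nc_x + nt_x
        rr_x = (b_x / nt_x) / (a_x / nc_x)
        rows.append(
            SweepRow(
                p=p,
                N=table.N,
                Nc=table.Nc,
                NT=table.NT,
                a=table.a,
                b=table.b,
                ethical_losses=ethical,
                ethical_loss_pct=100.0 * ethical / table.N,
                RR=rates.relative_risk,
                chi2=chi2,
                N_exact=n_x,
                ethical_loss_pct_exact=100.0 * (n_x - config.responders_T_fixed) / n_x,
                RR_exact=rr_x,
                chi2_exact=_pearson_chi2(a_x, b_x, nc_x, nt_x),
            )
        )
    return rows


@dataclass(frozen=True)
class TrendReport:
    """Monotonicity and linearity verdicts for a sweep.

    Verdicts are evaluated on the continuous-model series (free of
    whole-participant rounding jitter); ``max_rounding_jitter`` records the
    largest adverse step of the rounded series so the size of the
    integerization artifact is visible.  R-squared values are ``None``
    (flagged) for degenerate, constant series.
    """

    n_monotone_nonincreasing: bool
    ethical_loss_pct_monotone_nonincreasing: bool
    rr_monotone_nonincreasing: bool
    chi2_monotone_nondecreasing: bool
    r2_ethical_loss_pct: float | None
    r2_chi2: float | None
    max_rounding_jitter: dict[str, float]

    @property
    def all_monotone(self) -> bool:
        return (
            self.n_monotone_nonincreasing
            and self.ethical_loss_pct_monotone_nonincreasing
            and self.rr_monotone_nonincreasing
            and self.chi2_monotone_nondecreasing
        )

    def to_dict(self) -> dict:
        return {
            "n_monotone_nonincreasing": self.n_monotone_nonincreasing,
            "ethical_loss_pct_monotone_nonincreasing": self.ethical_loss_pct_monotone_nonincreasing,
            "rr_monotone_nonincreasing": self.rr_monotone_nonincreasing,
            "chi2_monotone_nondecreasing": self.chi2_monotone_nondecreasing,
            "r2_ethical_loss_pct": self.r2_ethical_loss_pct,
            "r2_chi2": self.r2_chi2,
            "max_rounding_jitter": self.max_rounding_jitter,
        }


def _linear_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    if np.ptp(y) == 0.0:
        return None
    coef = np.polyfit(x, y, 1)
    resid = y - np.polyval(coef, x)
    return float(1.0 - resid.var() / y.var())


def trend_check(rows: list[SweepRow]) -> TrendReport:
    """Verify the qualitative behaviour of the family as p increases.

    As the responder proportion rises: sample size, ethical-loss share and
    relative risk fall, while the chi-square efficacy statistic rises; the
    ethical-loss share is exactly linear in p before rounding.
    """
    if len(rows) < 3:
        raise ValueError("trend check needs at least 3 sweep rows")
    ordered = sorted(rows, key=lambda r: r.p)
    p = np.array([r.p for r in ordered])
    n_x = np.array([r.N_exact for r in ordered])
    pct_x = np.array([r.ethical_loss_pct_exact for r in ordered])
    rr_x = np.array([r.RR_exact for r in ordered])
    chi_x = np.array([r.chi2_exact for r in ordered])
    rr = np.array([r.RR for r in ordered])
    chi = np.array([r.chi2 for r in ordered])
    n = np.array([r.N for r in ordered], dtype=float)
    pct = np.array([r.ethical_loss_pct for r in ordered])
    return TrendReport(
        n_monotone_nonincreasing=bool(np.all(np.diff(n_x) <= 1e-12)),
        ethical_loss_pct_monotone_nonincreasing=bool(np.all(np.diff(pct_x) <= 1e-12)),
        rr_monotone_nonincreasing=bool(np.all(np.diff(rr_x) <= 1e-12)),
        chi2_monotone_nondecreasing=bool(np.all(np.diff(chi_x) >= -1e-9)),
        r2_ethical_loss_pct=_linear_r2(p, pct_x),
        r2_chi2=_linear_r2(p, chi_x),
        max_rounding_jitter={
            "N": float(np.max(np.diff(n), initial=0.0)),
            "ethical_loss_pct": float(np.max(np.diff(pct), initial=0.0)),
            "RR": float(np.max(np.diff(rr), initial=0.0)),
            "chi2": float(np.max(-np.diff(chi), initial=0.0)),
        },
    )
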