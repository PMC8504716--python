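"""File formats: trial tables, configs, reports.

Trial tables come in as a JSON object with integer cells ``a, b, c, d``
(arm totals are derived) or as a two-row CSV with header
``arm,events,no_events`` and arms labelled C and T.  Sweeps go out as CSV
with a fixed column order so reruns are byte-comparable; breakdown reports
go out as JSON and as an aligned-text demographics table.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from pydantic import ValidationError

from .cohort import CohortConfig
from .sweep import SweepConfig, SweepRow
from .table import TableInvariantError, TrialTable2x2

__all__ = [
    "read_table_json",
    "read_table_csv",
    "read_table",
    "read_sweep_config",
    "read_cohort_config",
    "write_breakdown_json",
    "sweep_to_frame",
    "write_sweep_csv",
]

SWEEP_COLUMNS = [
    "p",
    "N",
    "Nc",
    "NT",
    "events_C",
    "events_T",
    "ethical_losses",
    "ethical_loss_pct",
    "relative_risk",
    "chi_square",
]


def read_table_json(path: str | Path) -> TrialTable2x2:
    """Read a 2x2 table from a JSON object with keys a, b, c, d."""
    path = Path(path)
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise TableInvariantError(f"{path}:{exc.lineno}: invalid JSON: {exc.msg}") from exc
    if not isinstance(payload, dict):
        raise TableInvariantError(f"{path}: expected a JSON object")
    extra = set(payload) - {"a", "b", "c", "d"}
    if extra:
        raise TableInvariantError(f"{path}: unknown keys {sorted(extra)}")
    missing = {"a", "b", "c", "d"} - set(payload)
    if missing:
        raise TableInvariantError(f"{path}: missing keys {sorted(missing)}")
    for k in ("a", "b", "c", "d"):
        if not isinstance(payload[k], int) or isinstance(payload[k], bool):
            raise TableInvariantError(f"{path}: field {k!r} must be an integer")
    return TrialTable2x2(**payload)


def read_table_csv(path: str | Path) -> TrialTable2x2:
    """Read a 2x2 table from a two-row CSV with header arm,events,no_events."""
    path = Path(path)
    df = pd.read_csv(path)
    expected_cols = ["arm", "events", "no_events"]
    if list(df.columns) != expected_cols:
        raise TableInvariantError(
            f"{path}:1: expected header {','.join(expected_cols)}, got {','.join(df.columns)}"
        )
    if sorted(df["arm"]) != ["C", "T"]:
        raise TableInvariantError(f"{path}: arms must be exactly C and T, got {list(df['arm'])}")
    rows = df.set_index("arm")
    for line, arm in ((2, df["arm"].iloc[0]), (3, df["arm"].iloc[1])):
        for col in ("events", "no_events"):
            v = rows.loc[arm, col]
            if pd.isna(v) or int(v) != v or v < 0:
                raise TableInvariantError(
                    f"{path}:{line}: field {col!r} must be a nonnegative integer, got {v!r}"
                )
    return TrialTable2x2(
        a=int(rows.loc["C", "events"]),
        b=int(rows.loc["T", "events"]),
        c=int(rows.loc["C", "no_events"]),
        d=int(rows.loc["T", "no_events"]),
    )


def read_table(path: str | Path) -> TrialTable2x2:
    """Dispatch on extension: .json or .csv."""
    path = Path(path)
    if path.suffix == ".json":
        return read_table_json(path)
    if path.suffix == ".csv":
        return read_table_csv(path)
    raise TableInvariantError(f"{path}: unsupported table format {path.suffix!r}")


def _read_config(path: str | Path, cls):
    path = Path(path)
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}:{exc.lineno}: invalid JSON: {exc.msg}") from exc
    try:
        return cls(**payload)
    except ValidationError as exc:
        raise ValueError(f"{path}: invalid {cls.__name__}: {exc}") from exc


def read_sweep_config(path: str | Path) -> SweepConfig:
    """Load a SweepConfig from strict JSON (unknown keys rejected)."""
    return _read_config(path, SweepConfig)


def read_cohort_config(path: str | Path) -> CohortConfig:
    """Load a CohortConfig from strict JSON (unknown keys rejected)."""
    return _read_config(path, CohortConfig)


def write_breakdown_json(results, path: str | Path) -> None:
    """Dump a fitted decomposition to JSON (counts, rates, test)."""
    rr = results.rates.RR
    payload = {
        "table": {"a": results.table.a, "b": results.table.b, "c": results.table.c, "d": results.table.d},
        "rates": {
            "Rc": results.rates.Rc,
            "RT": results.rates.RT,
            "AB": results.rates.AB,
            "RR": rr,
        },
        "expected_untreated_events": results.expected_untreated_events,
        "breakdown": results.breakdown.to_dict(),
        "ethical_loss_fraction": results.ethical_loss_fraction,
        "chi_square": {
            "statistic": results.chi2.statistic,
            "df": results.chi2.df,
            "p_value": results.chi2.p_value,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def sweep_to_frame(rows: list[SweepRow]) -> pd.DataFrame:
    """Sweep rows as a DataFrame in the canonical column order."""
    return pd.DataFrame(
        {
            "p": [r.p for r in rows],
            "N": [r.N for r in rows],
            "Nc": [r.Nc for r in rows],
            "NT": [r.NT for r in rows],
            "events_C": [r.a for r in rows],
            "events_T": [r.b for r in rows],
            "ethical_losses": [r.ethical_losses for r in rows],
            "ethical_loss_pct": [r.ethical_loss_pct for r in rows],
            "relative_risk": [r.RR for r in rows],
            "chi_square": [r.chi2 for r in rows],
        },
        columns=SWEEP_COLUMNS,
    )


def write_sweep_csv(rows: list[SweepRow], path: str | Path) -> None:
    """Write the sweep as deterministic CSV (fixed columns, repr floats)."""
    sweep_to_frame(rows).to_csv(path, index=False)
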