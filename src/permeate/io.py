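"""Plain-text I/O: Em tables as CSV, traces as CSV + JSON sidecar, fit reports as JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Union

import pandas as pd

from .calibration import CalibrationCurve, FluorescenceTrace, TraceEvent
from .fitting import EmTable, FitResult
from .presets import ConditionSpec

__all__ = [
    "read_em_table",
    "write_em_table",
    "read_em_tables",
    "read_trace",
    "write_trace",
    "write_fit_result",
    "read_fit_result_dict",
    "write_calibration_report",
]

PathLike = Union[str, Path]

_EM_COLUMNS = ["condition", "genotype", "K_out_mM", "Em_mV", "sem_mV", "n"]


def write_em_table(table: EmTable, path: PathLike) -> None:
    """Write one Em table in the canonical CSV schema."""
    df = table.data.copy()
    df.insert(0, "condition", table.label)
    df.insert(1, "genotype", table.condition.genotype if table.condition else "")
    df[_EM_COLUMNS].to_csv(path, index=False)


def read_em_table(path: PathLike, condition: Optional[ConditionSpec] = None) -> EmTable:
    """Read a single-condition Em CSV (columns condition, genotype, K_out_mM, Em_mV, sem_mV, n)."""
    tables = read_em_tables(path, condition=condition)
    if len(tables) != 1:
        raise ValueError(f"{path} holds {len(tables)} conditions; expected exactly 1")
    return tables[0]


def read_em_tables(path: PathLike, condition: Optional[ConditionSpec] = None) -> List[EmTable]:
    """Read an Em CSV, splitting on the ``condition`` column if present."""
    df = pd.read_csv(path)
    missing = [c for c in ("K_out_mM", "Em_mV") if c not in df.columns]
    if missing:
        raise ValueError(f"{path} missing required columns: {missing}")
    groups = df.groupby("condition", sort=False) if "condition" in df.columns else [("", df)]
    tables = []
    for label, sub in groups:
        data = sub[[c for c in ("K_out_mM", "Em_mV", "sem_mV", "n") if c in sub.columns]]
        tables.append(
            EmTable(data.reset_index(drop=True), label=str(label), condition=condition)
        )
    return tables


def write_trace(trace: FluorescenceTrace, csv_path: PathLike, events_path: PathLike) -> None:
    """Write a trace as time/fluorescence CSV plus a JSON event sidecar."""
    pd.DataFrame(
        {"time_s": trace.time_s, "fluorescence_au": trace.fluorescence_au}
    ).to_csv(csv_path, index=False)
    Path(events_path).write_text(
        json.dumps([e.to_dict() for e in trace.events], indent=2)
    )


def read_trace(csv_path: PathLike, events_path: PathLike, label: str = "") -> FluorescenceTrace:
    df = pd.read_csv(csv_path)
    events = [
        TraceEvent(time_s=e["time_s"], label=e["label"], K_out_mM=e.get("K_out_mM"))
        for e in json.loads(Path(events_path).read_text())
    ]
    return FluorescenceTrace(
        time_s=df["time_s"].to_numpy(),
        fluorescence_au=df["fluorescence_au"].to_numpy(),
        events=events,
        label=label,
    )


def write_fit_result(result: FitResult, path: PathLike) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2))


def read_fit_result_dict(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())


def write_calibration_report(curve: CalibrationCurve, path: PathLike, **extra) -> None:
    report = curve.to_dict()
    report.update(extra)
    Path(path).write_text(json.dumps(report, indent=2))
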