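"""Plain-text trace and event-table I/O.

Traces are stored as two-column TSV (time_s, current_pA) with a JSON
sidecar (``<path>.json``) holding sampling rate, voltage protocol,
scenario name and seed.  Event tables (idealized dwells or ground
truth) are plain CSV.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .idealize import DWELL_COLUMNS, IdealizedRecord
from .protocol import VoltageProtocol
from .recording import CurrentTrace

__all__ = ["write_trace", "read_trace", "write_events", "read_events", "write_truth", "read_truth"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trace(trace: CurrentTrace, path: str | Path, float_fmt: str = "%.17g") -> Path:
    path = Path(path)
    data = np.column_stack([trace.times(), trace.samples])
    header = "time_s\tcurrent_pA"
    np.savetxt(path, data, fmt=float_fmt, delimiter="\t", header=header, comments="")
    meta = {
        "sampling_rate_hz": trace.sampling_rate,
        "protocol": trace.protocol.to_dict(),
        "scenario": trace.metadata.get("scenario"),
        "seed": trace.metadata.get("seed"),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_trace(path: str | Path) -> CurrentTrace:
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    meta = json.loads(_sidecar(path).read_text())
    protocol = VoltageProtocol.from_dict(meta["protocol"])
    return CurrentTrace(
        data[:, 1],
        float(meta["sampling_rate_hz"]),
        protocol,
        {"scenario": meta.get("scenario"), "seed": meta.get("seed"), "source": str(path)},
    )


def write_events(record: IdealizedRecord, path: str | Path) -> Path:
    path = Path(path)
    d = record.dwells.copy()
    d.attrs = {}
    d.to_csv(path, index=False)
    _sidecar(path).write_text(
        json.dumps({"total_time_s": record.total_time, "baseline_pA": record.baseline})
    )
    return path


def read_events(path: str | Path) -> IdealizedRecord:
    path = Path(path)
    d = pd.read_csv(path)
    missing = set(DWELL_COLUMNS) - set(d.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        total = float(meta["total_time_s"])
        baseline = float(meta.get("baseline_pA", 0.0))
    else:
        total = float((d["start_s"] + d["duration_s"]).max()) if len(d) else 0.0
        baseline = 0.0
    return IdealizedRecord(d, total_time=total, baseline=baseline)


def write_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    truth.to_csv(path, index=False)
    return path


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
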