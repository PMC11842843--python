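"""Patch-clamp current traces: delimited-text reading and writing.

Time is in ms, current in pA, voltage in mV (a scalar per trace, or one
value per sample for ramp protocols).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class TraceParseError(ValueError):
    pass


@dataclass
class CurrentTrace:
    """A recorded or synthesized current time series."""

    time_ms: np.ndarray
    current_pA: np.ndarray
    voltage_mV: float | np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        if self.time_ms.shape != self.current_pA.shape:
            raise TraceParseError("time and current arrays differ in length")
        if len(self.time_ms) and np.any(np.diff(self.time_ms) <= 0):
            raise TraceParseError("trace time must be strictly increasing")
        if isinstance(self.voltage_mV, (list, np.ndarray)):
            self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
            if self.voltage_mV.shape != self.time_ms.shape:
                raise TraceParseError("per-sample voltage must match trace length")

    def __len__(self) -> int:
        return len(self.time_ms)

    @property
    def voltage_is_scalar(self) -> bool:
        return np.isscalar(self.voltage_mV) or np.ndim(self.voltage_mV) == 0


def read_current_trace(
    path: str | Path,
    voltage_mV: float | None = None,
    delimiter: str | None = None,
    **metadata,
) -> CurrentTrace:
    """Read a (time_ms, current_pA[, voltage_mV]) delimited text file.

    A single non-numeric header line is skipped; any other non-numeric
    cell raises :class:`TraceParseError` with its row index.
    """
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        if delimiter is None:
            try:
                delimiter = csv.Sniffer().sniff(sample, delimiters=",;\t ").delimiter
            except csv.Error:
                delimiter = ","
        reader = csv.reader(fh, delimiter=delimiter)
        for irow, row in enumerate(reader):
            row = [c for c in row if c.strip() != ""]
            if not row:
                continue
            try:
                vals = [float(c) for c in row]
            except ValueError:
                if irow == 0 and not rows:  # header line
                    continue
                raise TraceParseError(f"non-numeric cell at row {irow}") from None
            if len(vals) < 2:
                raise TraceParseError(f"row {irow}: need at least time and current columns")
            rows.append(vals)
    if not rows:
        raise TraceParseError(f"no data rows in {path}")
    arr = np.array([r[:3] if len(r) >= 3 else r[:2] for r in rows], dtype=object)
    time = np.array([r[0] for r in rows])
    curr = np.array([r[1] for r in rows])
    if voltage_mV is None and all(len(r) >= 3 for r in rows):
        voltage = np.array([r[2] for r in rows])
    elif voltage_mV is not None:
        voltage = float(voltage_mV)
    else:
        raise TraceParseError("voltage must be given or present as a third column")
    del arr
    return CurrentTrace(time_ms=time, current_pA=curr, voltage_mV=voltage, metadata=metadata)


def write_current_trace(trace: CurrentTrace, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if trace.voltage_is_scalar:
            writer.writerow(["time_ms", "current_pA"])
            for t, i in zip(trace.time_ms, trace.current_pA):
                writer.writerow([repr(float(t)), repr(float(i))])
        else:
            writer.writerow(["time_ms", "current_pA", "voltage_mV"])
            for t, i, v in zip(trace.time_ms, trace.current_pA, trace.voltage_mV):
                writer.writerow([repr(float(t)), repr(float(i)), repr(float(v))])
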