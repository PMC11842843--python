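"""Permeation event records and their CSV serialization."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

DIRECTIONS = ("influx", "efflux")


@dataclass(frozen=True)
class PermeationEvent:
    """One completed boundary-to-boundary transit.

    ``entry_ns`` is the last crossing of the entry plane before the
    transit, ``exit_ns`` the first crossing of the exit plane.
    """

    particle_id: int
    species: str
    entry_ns: float
    exit_ns: float
    direction: str

    def __post_init__(self) -> None:
        if self.exit_ns <= self.entry_ns:
            raise ValueError(
                f"event exit time {self.exit_ns} not after entry time {self.entry_ns}"
            )
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")

    @property
    def transit_ns(self) -> float:
        return self.exit_ns - self.entry_ns


class EventLog:
    """An exit-time-ordered collection of permeation events."""

    def __init__(self, events: list[PermeationEvent] | None = None):
        self.events = sorted(events or [], key=lambda e: (e.exit_ns, e.particle_id))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def filter(self, species: str | None = None, direction: str | None = None) -> "EventLog":
        out = [
            e
            for e in self.events
            if (species is None or e.species == species)
            and (direction is None or e.direction == direction)
        ]
        return EventLog(out)

    def exit_times(self) -> np.ndarray:
        return np.array([e.exit_ns for e in self.events])

    def transit_times(self) -> np.ndarray:
        return np.array([e.transit_ns for e in self.events])


_HEADER = ["particle_id", "species", "entry_ns", "exit_ns", "transit_ns", "direction"]


def write_events(events: EventLog, path: str | Path) -> None:
    """Write one row per event, ordered by exit time."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for e in events:
            writer.writerow(
                [
                    e.particle_id,
                    e.species,
                    repr(e.entry_ns),
                    repr(e.exit_ns),
                    repr(e.transit_ns),
                    e.direction,
                ]
            )


def read_events(path: str | Path) -> EventLog:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out.append(
                PermeationEvent(
                    particle_id=int(row["particle_id"]),
                    species=row["species"],
                    entry_ns=float(row["entry_ns"]),
                    exit_ns=float(row["exit_ns"]),
                    direction=row["direction"],
                )
            )
    return EventLog(out)
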