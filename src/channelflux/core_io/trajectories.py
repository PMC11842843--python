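"""Trajectory container and the JSON-lines interchange dialect.

Units are nm and ns (MD convention).  The canonical on-disk form is one
JSON object per line::

    {"frame": 0, "time_ns": 0.0, "id": 3, "species": "chloride",
     "x": 0.1, "y": -0.2, "z": 1.4, "box": [4.0, 4.0, 4.4]}

Every particle present in frame 0 must appear in every frame (no ragged
trajectories) and frame times must be strictly increasing.  Adapters for
binary trajectory formats can construct :class:`Trajectory` directly; the
jsonl reader is the only built-in dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

SPECIES = ("chloride", "malate", "protein-atom", "other")

_SPECIES_ALIASES = {
    "chloride": "chloride",
    "cl": "chloride",
    "cl-": "chloride",
    "cla": "chloride",
    "malate": "malate",
    "mal": "malate",
    "mal2-": "malate",
    "protein-atom": "protein-atom",
    "protein": "protein-atom",
    "other": "other",
}


class TrajectoryError(ValueError):
    """Raised for contract violations in trajectory data."""


def normalize_species(tag: str) -> str:
    """Map a free-form species tag onto the closed vocabulary."""
    norm = _SPECIES_ALIASES.get(str(tag).strip().lower())
    if norm is None:
        raise TrajectoryError(f"unknown species tag: {tag!r} (expected one of {SPECIES})")
    return norm


@dataclass
class Trajectory:
    """Time-ordered particle coordinates with box dimensions.

    Attributes
    ----------
    times : (F,) frame time stamps in ns, strictly increasing.
    ids : (P,) particle ids.
    species : (P,) tags from :data:`SPECIES`.
    coords : (F, P, 3) positions in nm.
    box : (F, 3) box dimensions in nm.
    """

    times: np.ndarray
    ids: np.ndarray
    species: np.ndarray
    coords: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ids = np.asarray(self.ids, dtype=int)
        self.species = np.asarray(self.species, dtype="U12")
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.times.ndim != 1 or len(self.times) == 0:
            raise TrajectoryError("trajectory must contain at least one frame")
        if np.any(np.diff(self.times) <= 0):
            raise TrajectoryError("frame times must be strictly increasing")
        if self.coords.shape != (len(self.times), len(self.ids), 3):
            raise TrajectoryError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"{len(self.times)} frames x {len(self.ids)} particles"
            )
        if self.box.shape != (len(self.times), 3):
            raise TrajectoryError("box must be (n_frames, 3)")
        bad = set(self.species.tolist()) - set(SPECIES)
        if bad:
            raise TrajectoryError(f"species tags outside vocabulary: {sorted(bad)}")
        if len(np.unique(self.ids)) != len(self.ids):
            raise TrajectoryError("duplicate particle ids")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def protein_mask(self) -> np.ndarray:
        return self.species == "protein-atom"

    def species_mask(self, species: str | list[str] | None) -> np.ndarray:
        if species is None:
            return np.ones(len(self.ids), dtype=bool)
        if isinstance(species, str):
            species = [species]
        return np.isin(self.species, [normalize_species(s) for s in species])


def read_trajectory(source: str | Path, dialect: str = "jsonl") -> Trajectory:
    """Read a trajectory file in the declared dialect (jsonl only built in)."""
    if dialect != "jsonl":
        raise TrajectoryError(f"unsupported dialect: {dialect!r}")
    frames: dict[int, dict] = {}
    times: dict[int, float] = {}
    boxes: dict[int, list] = {}
    species: dict[int, str] = {}
    with open(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                f = int(rec["frame"])
                pid = int(rec["id"])
                xyz = (float(rec["x"]), float(rec["y"]), float(rec["z"]))
                times[f] = float(rec["time_ns"])
                boxes[f] = [float(v) for v in rec["box"]]
                species[pid] = normalize_species(rec["species"])
            except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
                raise TrajectoryError(f"malformed jsonl record at line {lineno}: {exc}") from exc
            frames.setdefault(f, {})[pid] = xyz

    if not frames:
        raise TrajectoryError(f"empty trajectory file: {source}")
    frame_ids = sorted(frames)
    t = np.array([times[f] for f in frame_ids])
    if np.any(np.diff(t) <= 0):
        raise TrajectoryError("frame times must be strictly increasing")
    pids = sorted(frames[frame_ids[0]])
    pid_set = set(pids)
    coords = np.empty((len(frame_ids), len(pids), 3))
    for i, f in enumerate(frame_ids):
        present = frames[f]
        if set(present) != pid_set:
            missing = sorted(pid_set ^ set(present))
            raise TrajectoryError(f"ragged trajectory: frame {f}, particle ids {missing}")
        for j, pid in enumerate(pids):
            coords[i, j] = present[pid]
    return Trajectory(
        times=t,
        ids=np.array(pids),
        species=np.array([species[p] for p in pids]),
        coords=coords,
        box=np.array([boxes[f] for f in frame_ids]),
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the jsonl dialect (full float precision)."""
    with open(path, "w") as fh:
        for i, t in enumerate(traj.times):
            box = traj.box[i].tolist()
            for j, pid in enumerate(traj.ids):
                x, y, z = traj.coords[i, j]
                rec = {
                    "frame": int(i),
                    "time_ns": float(t),
                    "id": int(pid),
                    "species": str(traj.species[j]),
                    "x": float(x),
                    "y": float(y),
                    "z": float(z),
                    "box": box,
                }
                fh.write(json.dumps(rec) + "\n")
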