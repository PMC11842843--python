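"""Permeation event detection and flux statistics.

Conventions: +z points from cytosol to vacuole; an "influx" is a transit
in +z.  Currents carried by anion influx under cytosolic-negative
potential are reported negative.  Detection uses two planes at +-d from
the protein reference; a completed influx crosses the cytosolic plane
and then the vacuolar plane without returning past the cytosolic plane
in between.  Crossing times are linearly interpolated between frames,
and per-frame z jumps larger than half the box are treated as periodic
wraps (the ion passes through the box boundary, not through the pore).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io.events import EventLog, PermeationEvent
from .core_io.trajectories import Trajectory

ELEMENTARY_CHARGE_C = 1.602176634e-19

__all__ = [
    "DetectorParams",
    "FluxSummary",
    "SiteModel",
    "OccupancyTrace",
    "detect_events",
    "flux_summary",
    "flux_to_current",
    "scale_current_linear",
    "segment_conductive_phases",
    "ConductivePhase",
    "site_occupancy",
    "relative_influx_timing",
    "LagHistogram",
    "axial_density",
]


@dataclass
class DetectorParams:
    """Boundary-plane detector settings (nm)."""

    boundary_offset_nm: float = 1.5
    reference: str = "com"  # "com" (per-frame protein centre of mass) or "fixed"
    fixed_z: float = 0.0
    species: list | None = None

    def __post_init__(self) -> None:
        if self.boundary_offset_nm <= 0:
            raise ValueError("boundary offset must be positive")
        if self.reference not in ("com", "fixed"):
            raise ValueError("reference mode must be 'com' or 'fixed'")


def _reference_z(traj: Trajectory, params: DetectorParams) -> np.ndarray:
    if params.reference == "fixed":
        return np.full(traj.n_frames, params.fixed_z)
    mask = traj.protein_mask
    if not mask.any():
        raise ValueError("no protein-tagged particles; use fixed-z reference mode")
    return traj.coords[:, mask, 2].mean(axis=1)


def _wrap(z: np.ndarray, box: np.ndarray) -> np.ndarray:
    return (z + box / 2.0) % box - box / 2.0


def _plane_crossings(t0, u0, t1, u1, plane, box):
    """(time, direction) for each crossing of a periodic image of ``plane``."""
    out = []
    if u1 == u0:
        return out
    lo, hi = (u0, u1) if u1 > u0 else (u1, u0)
    for k in range(math.ceil((lo - plane) / box), math.floor((hi - plane) / box) + 1):
        p = plane + k * box
        if lo < p <= hi or lo <= p < hi:
            frac = (p - u0) / (u1 - u0)
            out.append((t0 + frac * (t1 - t0), 1 if u1 > u0 else -1))
    return out


def detect_events(traj: Trajectory, params: DetectorParams | None = None) -> EventLog:
    """Detect completed boundary-to-boundary transits in a trajectory."""
    params = params or DetectorParams()
    if traj.n_frames < 2:
        raise ValueError("trajectory needs at least 2 frames for event detection")
    box_z = traj.box[:, 2]
    d = params.boundary_offset_nm
    if np.any(d > box_z / 2.0):
        raise ValueError("boundary offset exceeds half the box height")

    ref = _reference_z(traj, params)
    sel = traj.species_mask(params.species) & ~traj.protein_mask
    times = traj.times
    events: list[PermeationEvent] = []

    for j in np.flatnonzero(sel):
        zw = _wrap(traj.coords[:, j, 2] - ref, box_z)
        # unwrap: jumps beyond half a box are periodic wraps
        dz = np.diff(zw)
        shift = np.where(dz > box_z[1:] / 2, -box_z[1:], np.where(dz < -box_z[1:] / 2, box_z[1:], 0.0))
        u = zw.copy()
        u[1:] += np.cumsum(shift)

        origin: str | None = None
        entry_t = 0.0
        for f in range(len(times) - 1):
            xs = [
                (tc, dirn, "cyt")
                for tc, dirn in _plane_crossings(times[f], u[f], times[f + 1], u[f + 1], -d, box_z[f])
            ] + [
                (tc, dirn, "vac")
                for tc, dirn in _plane_crossings(times[f], u[f], times[f + 1], u[f + 1], d, box_z[f])
            ]
            for tc, dirn, plane in sorted(xs):
                if plane == "cyt" and dirn > 0:
                    origin, entry_t = "cyt", tc
                elif plane == "cyt" and dirn < 0:
                    if origin == "vac":
                        events.append(
                            PermeationEvent(int(traj.ids[j]), str(traj.species[j]), entry_t, tc, "efflux")
                        )
                    origin = None
                elif plane == "vac" and dirn < 0:
                    origin, entry_t = "vac", tc
                elif plane == "vac" and dirn > 0:
                    if origin == "cyt":
                        events.append(
                            PermeationEvent(int(traj.ids[j]), str(traj.species[j]), entry_t, tc, "influx")
                        )
                    origin = None
    return EventLog(events)


@dataclass
class FluxSummary:
    """Per-species flux statistics and derived current."""

    species: str
    n_events: int
    duration_ns: float
    flow_rate_per_us: float
    transit_mean_ns: float | None
    transit_sd_ns: float | None
    current_pA: float
    voltage_mV: float
    direction: str = "influx"


def flux_to_current(
    rate_per_us: float, valence: int = 1, direction: str = "influx"
) -> float:
    """Convert an ion flow rate (ions/us) to a signed current in pA.

    Anion influx under cytosolic-negative potential is reported negative.
    """
    if rate_per_us < 0:
        raise ValueError("rate must be non-negative")
    if valence == 0 or int(valence) != valence:
        raise ValueError("valence must be a non-zero integer")
    magnitude = rate_per_us * 1e6 * abs(valence) * ELEMENTARY_CHARGE_C * 1e12  # pA
    sign = -1.0 if direction == "influx" else 1.0
    return sign * magnitude


def scale_current_linear(current_pA: float, v_from_mV: float, v_to_mV: float) -> float:
    """Ohmic rescaling of a current between holding potentials."""
    if v_from_mV == 0:
        raise ValueError("cannot scale from 0 mV")
    return current_pA * (v_to_mV / v_from_mV)


def flux_summary(
    events: EventLog,
    duration_ns: float,
    voltage_mV: float = 0.0,
    species: str | None = None,
    valence: int = 1,
    direction: str = "influx",
) -> FluxSummary:
    """Summarize one species' completed transits in a given direction."""
    if duration_ns <= 0:
        raise ValueError("duration must be positive")
    sub = events.filter(species=species, direction=direction)
    n = len(sub)
    rate = n / (duration_ns / 1000.0)
    if n:
        transits = sub.transit_times()
        mean = float(np.mean(transits))
        sd = float(np.std(transits, ddof=1)) if n > 1 else 0.0
    else:
        mean = sd = None
    return FluxSummary(
        species=species or "all",
        n_events=n,
        duration_ns=duration_ns,
        flow_rate_per_us=rate,
        transit_mean_ns=mean,
        transit_sd_ns=sd,
        current_pA=flux_to_current(rate, valence, direction) if n else 0.0,
        voltage_mV=voltage_mV,
        direction=direction,
    )


@dataclass
class ConductivePhase:
    start_ns: float
    end_ns: float
    n_events: int

    @property
    def duration_ns(self) -> float:
        return self.end_ns - self.start_ns

    @property
    def flow_rate_per_us(self) -> float:
        if self.duration_ns <= 0:
            return float("nan")
        return self.n_events / (self.duration_ns / 1000.0)


def segment_conductive_phases(events: EventLog, max_gap_ns: float = 50.0) -> list[ConductivePhase]:
    """Maximal runs of events whose inter-event gaps are <= max_gap."""
    if max_gap_ns <= 0:
        raise ValueError("max_gap must be positive")
    if len(events) == 0:
        return []
    t = np.sort(events.exit_times())
    phases = []
    start = prev = t[0]
    count = 1
    for x in t[1:]:
        if x - prev <= max_gap_ns:
            count += 1
        else:
            phases.append(ConductivePhase(start, prev, count))
            start, count = x, 1
        prev = x
    phases.append(ConductivePhase(start, prev, count))
    return phases


@dataclass
class SiteModel:
    """Named axial site intervals [z_lo, z_hi] in nm, reference frame of the pore."""

    sites: dict  # name -> (z_lo, z_hi)

    def __post_init__(self) -> None:
        iv = sorted(self.sites.values())
        for (a1, b1), (a2, b2) in zip(iv, iv[1:]):
            if b1 > a2:
                raise ValueError("site intervals must not overlap")
        for a, b in iv:
            if b <= a:
                raise ValueError("site interval must have positive width")

    @classmethod
    def around(cls, centers: dict, half_width: float = 0.25) -> "SiteModel":
        return cls({k: (z - half_width, z + half_width) for k, z in centers.items()})


@dataclass
class OccupancyTrace:
    """Per-frame per-site occupant counts."""

    frame_times: np.ndarray
    counts: dict  # site name -> (n_frames,) int array

    def mean_occupancy(self) -> dict:
        return {k: float(np.mean(v)) for k, v in self.counts.items()}

    def total_mean(self) -> float:
        return float(sum(self.mean_occupancy().values()))


def site_occupancy(
    traj: Trajectory,
    sites: SiteModel,
    species: str | list | None = None,
    params: DetectorParams | None = None,
) -> OccupancyTrace:
    """Count ions inside each axial site interval, frame by frame."""
    params = params or DetectorParams()
    ref = _reference_z(traj, params)
    sel = traj.species_mask(species) & ~traj.protein_mask
    zw = _wrap(traj.coords[:, sel, 2] - ref[:, None], traj.box[:, 2][:, None])
    counts = {}
    for name, (lo, hi) in sites.sites.items():
        counts[name] = np.sum((zw >= lo) & (zw <= hi), axis=1).astype(int)
    return OccupancyTrace(frame_times=traj.times.copy(), counts=counts)


@dataclass
class LagHistogram:
    """Lags from each primary event back to its latest conditioning event."""

    lags_ns: np.ndarray
    bin_edges_ns: np.ndarray
    counts: np.ndarray
    n_no_antecedent: int
    window_ns: float

    def mass_within(self, lag_ns: float) -> int:
        return int(np.sum(self.lags_ns <= lag_ns))


def relative_influx_timing(
    primary: EventLog,
    conditioning: EventLog,
    window_ns: float,
    bin_width_ns: float = 2.0,
) -> LagHistogram:
    """Lag of each primary (e.g. chloride) influx behind the most recent
    conditioning (e.g. malate) influx, measured between event exit times."""
    if window_ns <= 0:
        raise ValueError("window must be positive")
    cond = np.sort(conditioning.exit_times()) if len(conditioning) else np.array([])
    lags = []
    n_none = 0
    for e in primary:
        if len(cond) == 0:
            n_none += 1
            continue
        i = np.searchsorted(cond, e.exit_ns, side="right") - 1
        if i < 0:
            n_none += 1
            continue
        lag = e.exit_ns - cond[i]
        if lag <= window_ns:
            lags.append(lag)
    lags = np.array(lags)
    edges = np.arange(0.0, window_ns + bin_width_ns, bin_width_ns)
    counts, edges = np.histogram(lags, bins=edges)
    return LagHistogram(
        lags_ns=lags,
        bin_edges_ns=edges,
        counts=counts,
        n_no_antecedent=n_none,
        window_ns=window_ns,
    )


def axial_density(
    traj: Trajectory,
    species: str | list | None = None,
    bins: int = 50,
    params: DetectorParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged axial count density; integrates to the mean particle count.

    Returns (bin_edges_nm, density_per_nm).
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    params = params or DetectorParams()
    ref = _reference_z(traj, params)
    sel = traj.species_mask(species) & ~traj.protein_mask
    zw = _wrap(traj.coords[:, sel, 2] - ref[:, None], traj.box[:, 2][:, None])
    half = float(np.max(traj.box[:, 2])) / 2.0
    counts, edges = np.histogram(zw.ravel(), bins=bins, range=(-half, half))
    width = np.diff(edges)
    density = counts / (traj.n_frames * width)
    return edges, density
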