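"""Ground-truth generators for every analysis stage.

``simulate_knockon`` runs a continuous-time, event-driven simulation of
voltage-biased single-file anion hopping over an ordered chain of axial
binding sites (S1..S3 by default) flanked by periodic reservoirs.  A
move into an occupied site succeeds only by displacing the occupant
chain onward in the direction of motion (the knock-on rule); if the
chain is full the end ion is pushed out of the pore.  The rule is
mirror-symmetric so that unbiased rates give zero net flux; the voltage
bias rectifies it toward vacuolar exits.  Chloride conduction can be
gated by a two-state trap (bursty release), and trapped-chloride release
is accelerated while a malate occupies the middle site (facilitation).

The emitted trajectory is piecewise linear: ions dwell at sites and move
during a short transition window before each jump, plus per-frame
Gaussian jitter.  Ground truth (events, occupancies, fluxes) is computed
from the exact un-jittered path, so detector output can be compared
one-for-one.

Rate semantics (all in 1/ns, ``bias`` multiplies forward moves and
divides backward moves):

==============================  ===========================
move                            rate
==============================  ===========================
cytosolic entry -> first site   entry_rate[sp] * bias
forward hop site i -> i+1       hop_rate[sp] * bias
vacuolar exit from last site    exit_rate[sp] * bias
backward hop site i -> i-1      hop_rate[sp] / bias
back-exit first site -> cyt     exit_rate[sp] / bias
vacuolar entry -> last site     entry_rate[sp] / bias
trap gate closed -> open        cl_escape_rate (* facilitation
                                if malate at middle site)
trap gate open -> closed        cl_trap_rate
==============================  ===========================

While the gate is closed, chloride ions cannot initiate moves (they are
retained at their sites); chloride entry into an empty first site
remains possible (the ion becomes trapped), and an advancing malate can
still displace trapped chloride via the knock-on rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io.events import EventLog, PermeationEvent
from .core_io.structures import Structure
from .core_io.traces import CurrentTrace
from .core_io.trajectories import Trajectory

__all__ = [
    "KnockOnParams",
    "SyntheticTruth",
    "simulate_knockon",
    "make_toy_pore",
    "synth_activation_trace",
    "preset_params",
    "PRESETS",
]


@dataclass
class KnockOnParams:
    """Parameters of the knock-on hopping simulation (nm / ns units)."""

    site_z: tuple = (-1.0, 0.0, 1.0)
    entry_rate: dict = field(default_factory=lambda: {"chloride": 0.5, "malate": 0.0})
    exit_rate: dict = field(default_factory=lambda: {"chloride": 1.0, "malate": 1.0})
    hop_rate: dict = field(default_factory=lambda: {"chloride": 1.0, "malate": 1.0})
    bias: float = 1.0
    n_chloride: int = 8
    n_malate: int = 0
    cl_escape_rate: float | None = None  # None disables the trap gate
    cl_trap_rate: float = 0.0
    facilitation: float = 1.0
    boundary_nm: float = 1.5
    reservoir_offset_nm: float = 0.9
    recycle_ns: float = 2.0
    # half the box must exceed any single-frame displacement (a full
    # cascade-driven transit spans ~2*(boundary+reservoir_offset)), or the
    # detector would misread it as a periodic wrap
    box_z: float = 9.0
    box_xy: float = 4.0
    frame_interval_ns: float = 0.1
    duration_ns: float = 2000.0
    jitter_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        sites = np.asarray(self.site_z, dtype=float)
        if len(sites) < 2 or np.any(np.diff(sites) <= 0):
            raise ValueError("site positions must be strictly increasing along z")
        if self.frame_interval_ns <= 0 or self.duration_ns <= 0:
            raise ValueError("frame interval and duration must be positive")
        if self.n_chloride + self.n_malate < 1:
            raise ValueError("at least one ion required")
        for d in (self.entry_rate, self.exit_rate, self.hop_rate):
            if any(v < 0 for v in d.values()):
                raise ValueError("rates must be non-negative")
        total = sum(self.entry_rate.values()) + sum(self.exit_rate.values()) + sum(
            self.hop_rate.values()
        )
        if total == 0:
            raise ValueError("no dynamics: all rate constants are zero")
        min_gap = float(np.min(np.diff(sites)))
        if min_gap < 4.0 * self.jitter_sd:
            raise ValueError(
                f"site spacing {min_gap} nm smaller than jitter scale "
                f"({4 * self.jitter_sd} nm); crossing truth would be ambiguous"
            )
        if sites[0] <= -self.boundary_nm or sites[-1] >= self.boundary_nm:
            raise ValueError("all sites must lie strictly between the boundary planes")
        outer = self.boundary_nm + self.reservoir_offset_nm
        if outer >= self.box_z / 2:
            raise ValueError("reservoirs must fit inside the periodic box")


@dataclass
class SyntheticTruth:
    """Exact ground truth for one simulate_knockon run."""

    events: EventLog
    frame_times: np.ndarray
    occupancy: dict  # site name -> (n_frames,) array of species tags ('' = empty)
    duration_ns: float

    def mean_flux(self, species: str, direction: str = "influx") -> float:
        """True mean flux in ions/us."""
        n = len(self.events.filter(species=species, direction=direction))
        return n / (self.duration_ns / 1000.0)

    def total_site_occupancy(self) -> np.ndarray:
        """Per-frame total number of occupied sites."""
        occ = np.zeros(len(self.frame_times))
        for tags in self.occupancy.values():
            occ += tags != ""
        return occ


class _Ion:
    __slots__ = ("idx", "species", "u", "break_t", "break_u", "last_t")

    def __init__(self, idx: int, species: str, u0: float):
        self.idx = idx
        self.species = species
        self.u = u0  # unwrapped z
        self.break_t = [0.0]
        self.break_u = [u0]
        self.last_t = 0.0

    def move_to(self, t: float, du: float, frame_dt: float) -> None:
        """Dwell until just before t, then jump by du over a short window."""
        tau = min(0.5 * frame_dt, 0.5 * (t - self.last_t))
        if tau > 0:
            self.break_t.append(t - tau)
            self.break_u.append(self.u)
        self.break_t.append(t)
        self.u += du
        self.break_u.append(self.u)
        self.last_t = t

    def drift_to(self, t_end: float, du: float) -> None:
        """Slow linear drift (reservoir recycling through the box boundary)."""
        self.break_t.append(t_end)
        self.u += du
        self.break_u.append(self.u)
        self.last_t = t_end


def _wrap(z, box):
    return (z + box / 2.0) % box - box / 2.0


def _segment_crossings(t0, u0, t1, u1, plane, box):
    """Times at which the linear segment crosses any periodic image of ``plane``."""
    out = []
    if u1 == u0:
        return out
    lo, hi = (u0, u1) if u1 > u0 else (u1, u0)
    k_lo = math.ceil((lo - plane) / box)
    k_hi = math.floor((hi - plane) / box)
    for k in range(k_lo, k_hi + 1):
        p = plane + k * box
        if lo < p <= hi or lo <= p < hi:
            frac = (p - u0) / (u1 - u0)
            if 0.0 <= frac <= 1.0:
                out.append((t0 + frac * (t1 - t0), 1 if u1 > u0 else -1))
    return out


def _exact_events(ion: _Ion, boundary: float, box: float) -> list[PermeationEvent]:
    """Run the transit state machine on the exact piecewise-linear path."""
    events = []
    origin = None
    entry_t = 0.0
    t_arr, u_arr = ion.break_t, ion.break_u
    for s in range(len(t_arr) - 1):
        xs = [(tc, d, "cyt") for tc, d in _segment_crossings(t_arr[s], u_arr[s], t_arr[s + 1], u_arr[s + 1], -boundary, box)]
        xs += [(tc, d, "vac") for tc, d in _segment_crossings(t_arr[s], u_arr[s], t_arr[s + 1], u_arr[s + 1], boundary, box)]
        for tc, d, plane in sorted(xs):
            if plane == "cyt" and d > 0:  # entered pore from cytosolic side
                origin, entry_t = "cyt", tc
            elif plane == "cyt" and d < 0:
                if origin == "vac":
                    events.append(
                        PermeationEvent(ion.idx, ion.species, entry_t, tc, "efflux")
                    )
                origin = None
            elif plane == "vac" and d < 0:  # entered pore from vacuolar side
                origin, entry_t = "vac", tc
            elif plane == "vac" and d > 0:
                if origin == "cyt":
                    events.append(
                        PermeationEvent(ion.idx, ion.species, entry_t, tc, "influx")
                    )
                origin = None
    return events


def simulate_knockon(params: KnockOnParams) -> tuple[Trajectory, SyntheticTruth]:
    """Run the knock-on simulation; same seed gives bit-identical output."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    sites = np.asarray(params.site_z, dtype=float)
    n_sites = len(sites)
    mid = n_sites // 2
    box = params.box_z
    res_cyt = sites[0] - params.reservoir_offset_nm
    res_vac = sites[-1] + params.reservoir_offset_nm
    frame_dt = params.frame_interval_ns

    species_list = ["chloride"] * params.n_chloride + ["malate"] * params.n_malate
    ions = []
    cyt_pool: list[int] = []
    vac_pool: list[int] = []
    for i, sp in enumerate(species_list):
        if i % 2 == 0:
            ions.append(_Ion(i, sp, res_cyt))
            cyt_pool.append(i)
        else:
            ions.append(_Ion(i, sp, res_vac))
            vac_pool.append(i)
    occupants: list[int | None] = [None] * n_sites
    recycling: list[tuple[float, int, str]] = []  # (ready time, ion, destination pool)

    gated = params.cl_escape_rate is not None
    gate_open = not gated
    occ_changes: list[list[tuple[float, str]]] = [[(0.0, "")] for _ in range(n_sites)]

    def fwd_du(a: float, b: float) -> float:
        return (b - a) % box

    def bwd_du(a: float, b: float) -> float:
        return -((a - b) % box)

    def chain_end(k: int) -> int | None:
        """First empty site >= k, or None if occupied through the last site."""
        for j in range(k, n_sites):
            if occupants[j] is None:
                return j
        return None

    def chain_start(k: int) -> int | None:
        """First empty site <= k, or None if occupied down to the first site."""
        for j in range(k, -1, -1):
            if occupants[j] is None:
                return j
        return None

    def record_occ(t: float, site: int) -> None:
        occ = occupants[site]
        occ_changes[site].append((t, "" if occ is None else ions[occ].species))

    # --- move enumeration -------------------------------------------------
    def enabled_moves() -> list[tuple[float, tuple]]:
        moves = []
        cyt_species = {ions[i].species for i in cyt_pool}
        vac_species = {ions[i].species for i in vac_pool}
        for sp in ("chloride", "malate"):
            er = params.entry_rate.get(sp, 0.0)
            if er > 0:
                # cytosolic entry (with knock-on cascade); while the gate is
                # closed a chloride may only enter an empty first site,
                # whereas malate pushes through regardless (it disrupts
                # chloride retention)
                ok = sp in cyt_species
                if ok and not gate_open and sp == "chloride" and occupants[0] is not None:
                    ok = False
                if ok:
                    moves.append((er * params.bias, ("enter_cyt", sp)))
                # vacuolar entry (with mirror-image knock-on cascade)
                ok = sp in vac_species
                if ok and not gate_open and sp == "chloride" and occupants[-1] is not None:
                    ok = False
                if ok:
                    moves.append((er / params.bias, ("enter_vac", sp)))
        for k in range(n_sites):
            i = occupants[k]
            if i is None:
                continue
            sp = ions[i].species
            # a closed gate freezes chloride-initiated moves only; trapped
            # chloride can still be displaced by an advancing malate
            frozen = (not gate_open) and sp == "chloride"
            hr = params.hop_rate.get(sp, 0.0)
            xr = params.exit_rate.get(sp, 0.0)
            if not frozen:
                if k + 1 < n_sites and hr > 0:
                    moves.append((hr * params.bias, ("hop_fwd", k)))
                if k == n_sites - 1 and xr > 0:
                    moves.append((xr * params.bias, ("exit_vac", k)))
                if k > 0 and hr > 0:
                    moves.append((hr / params.bias, ("hop_bwd", k)))
                if k == 0 and xr > 0:
                    moves.append((xr / params.bias, ("exit_cyt", k)))
        if gated:
            if gate_open:
                if params.cl_trap_rate > 0:
                    moves.append((params.cl_trap_rate, ("close_gate",)))
            else:
                rate = params.cl_escape_rate
                m = occupants[mid]
                if m is not None and ions[m].species == "malate":
                    rate = rate * params.facilitation
                if rate > 0:
                    moves.append((rate, ("open_gate",)))
        return moves

    # --- move application -------------------------------------------------
    drift_fwd = fwd_du(res_vac, res_cyt)  # vac res -> cyt res through the boundary
    drift_bwd = bwd_du(res_cyt, res_vac)

    def exit_to_vac(t: float, i: int) -> None:
        """Leave via the vacuolar side, then drift back to the cytosolic
        reservoir through the periodic boundary."""
        ions[i].move_to(t, fwd_du(sites[-1], res_vac), frame_dt)
        ions[i].drift_to(t + params.recycle_ns, drift_fwd)
        recycling.append((t + params.recycle_ns, i, "cyt"))

    def exit_to_cyt(t: float, i: int) -> None:
        ions[i].move_to(t, bwd_du(sites[0], res_cyt), frame_dt)
        ions[i].drift_to(t + params.recycle_ns, drift_bwd)
        recycling.append((t + params.recycle_ns, i, "vac"))

    def push_chain(t: float, k: int) -> None:
        """Shift occupants from site k forward by one; last may exit."""
        j = chain_end(k)
        if j is None:
            i = occupants[-1]
            exit_to_vac(t, i)
            occupants[-1] = None
            record_occ(t, n_sites - 1)
            j = n_sites - 1
        for s in range(j, k, -1):
            i = occupants[s - 1]
            ions[i].move_to(t, fwd_du(sites[s - 1], sites[s]), frame_dt)
            occupants[s] = i
            occupants[s - 1] = None
            record_occ(t, s)
            record_occ(t, s - 1)

    def push_chain_bwd(t: float, k: int) -> None:
        """Shift occupants from site k backward by one; first may exit."""
        j = chain_start(k)
        if j is None:
            i = occupants[0]
            exit_to_cyt(t, i)
            occupants[0] = None
            record_occ(t, 0)
            j = 0
        for s in range(j, k):
            i = occupants[s + 1]
            ions[i].move_to(t, bwd_du(sites[s + 1], sites[s]), frame_dt)
            occupants[s] = i
            occupants[s + 1] = None
            record_occ(t, s)
            record_occ(t, s + 1)

    def take_from_pool(pool: list, sp: str) -> int:
        for idx, i in enumerate(pool):
            if ions[i].species == sp:
                return pool.pop(idx)
        raise RuntimeError("pool exhausted")  # guarded by enabled_moves

    def apply(t: float, move: tuple) -> None:
        nonlocal gate_open
        kind = move[0]
        if kind == "enter_cyt":
            sp = move[1]
            if occupants[0] is not None:
                push_chain(t, 0)
            i = take_from_pool(cyt_pool, sp)
            ions[i].move_to(t, fwd_du(res_cyt, sites[0]), frame_dt)
            occupants[0] = i
            record_occ(t, 0)
        elif kind == "enter_vac":
            sp = move[1]
            if occupants[-1] is not None:
                push_chain_bwd(t, n_sites - 1)
            i = take_from_pool(vac_pool, sp)
            ions[i].move_to(t, bwd_du(res_vac, sites[-1]), frame_dt)
            occupants[-1] = i
            record_occ(t, n_sites - 1)
        elif kind == "hop_fwd":
            k = move[1]
            if occupants[k + 1] is not None:
                push_chain(t, k + 1)
            i = occupants[k]
            ions[i].move_to(t, fwd_du(sites[k], sites[k + 1]), frame_dt)
            occupants[k + 1] = i
            occupants[k] = None
            record_occ(t, k)
            record_occ(t, k + 1)
        elif kind == "hop_bwd":
            k = move[1]
            if occupants[k - 1] is not None:
                push_chain_bwd(t, k - 1)
            i = occupants[k]
            ions[i].move_to(t, bwd_du(sites[k], sites[k - 1]), frame_dt)
            occupants[k - 1] = i
            occupants[k] = None
            record_occ(t, k)
            record_occ(t, k - 1)
        elif kind == "exit_vac":
            i = occupants[-1]
            exit_to_vac(t, i)
            occupants[-1] = None
            record_occ(t, n_sites - 1)
        elif kind == "exit_cyt":
            i = occupants[0]
            exit_to_cyt(t, i)
            occupants[0] = None
            record_occ(t, 0)
        elif kind == "open_gate":
            gate_open = True
        elif kind == "close_gate":
            gate_open = False

    # --- main loop --------------------------------------------------------
    t = 0.0
    while t < params.duration_ns:
        moves = enabled_moves()
        total = sum(r for r, _ in moves)
        t_ready = min((r[0] for r in recycling), default=math.inf)
        t_next = t + rng.exponential(1.0 / total) if total > 0 else math.inf
        if t_ready <= min(t_next, params.duration_ns):
            # a recycled ion becomes available; rates change, so resample
            recycling.sort()
            t, i, dest = recycling.pop(0)
            (cyt_pool if dest == "cyt" else vac_pool).append(i)
            continue
        if not math.isfinite(t_next) or t_next >= params.duration_ns:
            break
        t = t_next
        u = rng.random() * total
        acc = 0.0
        chosen = moves[-1][1]
        for r, mv in moves:
            acc += r
            if u < acc:
                chosen = mv
                break
        apply(t, chosen)

    # --- frame emission ---------------------------------------------------
    frame_times = np.arange(0.0, params.duration_ns + 0.5 * frame_dt, frame_dt)
    frame_times = frame_times[frame_times <= params.duration_ns]
    n_frames = len(frame_times)
    n_ions = len(ions)

    n_protein = 8
    prot_z = np.tile([-0.5, 0.5], 4)
    prot_xy = np.array(
        [[0.8, 0.0], [0.8, 0.0], [-0.8, 0.0], [-0.8, 0.0], [0.0, 0.8], [0.0, 0.8], [0.0, -0.8], [0.0, -0.8]]
    )

    coords = np.zeros((n_frames, n_ions + n_protein, 3))
    min_gap = float(np.min(np.diff(sites)))
    clip = 0.5 * min_gap
    for j, ion in enumerate(ions):
        bt = np.asarray(ion.break_t)
        bu = np.asarray(ion.break_u)
        z_u = np.interp(frame_times, bt, bu)
        jitter = np.clip(
            rng.normal(0.0, params.jitter_sd, size=(n_frames, 3)), -clip, clip
        )
        coords[:, j, 0] = jitter[:, 0]
        coords[:, j, 1] = jitter[:, 1]
        coords[:, j, 2] = _wrap(z_u, box) + jitter[:, 2]
    for p in range(n_protein):
        coords[:, n_ions + p, 0] = prot_xy[p, 0]
        coords[:, n_ions + p, 1] = prot_xy[p, 1]
        coords[:, n_ions + p, 2] = prot_z[p]

    traj = Trajectory(
        times=frame_times,
        ids=np.concatenate([np.arange(n_ions), 1000 + np.arange(n_protein)]),
        species=np.array(
            [ion.species for ion in ions] + ["protein-atom"] * n_protein
        ),
        coords=coords,
        box=np.tile([params.box_xy, params.box_xy, box], (n_frames, 1)),
    )

    # --- ground truth -----------------------------------------------------
    all_events: list[PermeationEvent] = []
    for ion in ions:
        all_events.extend(_exact_events(ion, params.boundary_nm, box))
    all_events = [e for e in all_events if e.exit_ns <= params.duration_ns]

    occupancy = {}
    for k in range(n_sites):
        changes = occ_changes[k]
        ch_t = np.array([c[0] for c in changes])
        ch_s = np.array([c[1] for c in changes], dtype="U12")
        idx = np.searchsorted(ch_t, frame_times, side="right") - 1
        occupancy[f"S{k + 1}"] = ch_s[idx]

    truth = SyntheticTruth(
        events=EventLog(all_events),
        frame_times=frame_times,
        occupancy=occupancy,
        duration_ns=params.duration_ns,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# presets


def preset_params(name: str, seed: int = 0, duration_ns: float = 2000.0) -> KnockOnParams:
    """Qualitative concentration regimes (rates are not calibrated fits)."""
    if name == "malate-high":
        return KnockOnParams(
            entry_rate={"chloride": 0.0, "malate": 2.0},
            exit_rate={"chloride": 0.0, "malate": 0.08},
            hop_rate={"chloride": 0.0, "malate": 0.08},
            bias=4.0,
            n_chloride=0,
            n_malate=8,
            duration_ns=duration_ns,
            seed=seed,
        )
    if name == "chloride-high":
        return KnockOnParams(
            entry_rate={"chloride": 0.15, "malate": 0.0},
            exit_rate={"chloride": 0.4, "malate": 0.0},
            hop_rate={"chloride": 0.4, "malate": 0.0},
            bias=4.0,
            n_chloride=12,
            n_malate=0,
            cl_escape_rate=0.02,
            cl_trap_rate=0.3,
            duration_ns=duration_ns,
            seed=seed,
        )
    if name == "mixed":
        return KnockOnParams(
            entry_rate={"chloride": 0.15, "malate": 0.015},
            exit_rate={"chloride": 0.4, "malate": 0.15},
            hop_rate={"chloride": 0.4, "malate": 0.15},
            bias=4.0,
            n_chloride=12,
            n_malate=3,
            cl_escape_rate=0.01,
            cl_trap_rate=0.3,
            facilitation=60.0,
            duration_ns=duration_ns,
            seed=seed,
        )
    raise ValueError(f"unknown preset: {name!r}")


PRESETS = ("malate-high", "chloride-high", "mixed")


# ---------------------------------------------------------------------------
# toy pore geometries


def make_toy_pore(
    kind: str,
    *,
    wall_radius: float = 5.0,
    waist_radius: float = 3.0,
    end_radius: float = 8.0,
    length: float = 20.0,
    n_per_ring: int = 24,
    ring_spacing: float = 1.0,
    vdw: float = 1.7,
):
    """Build a pseudo-atom pore wall with a closed-form radius profile.

    Returns ``(structure, analytic_radius)`` where ``analytic_radius`` is
    a vectorized callable giving the exact probe radius at axial position
    z (Angstrom) for this wall.
    """
    if kind == "ring":
        ring_z = np.array([0.0])
        ring_r = np.array([float(wall_radius)])
    elif kind == "cylinder":
        ring_z = np.arange(-length / 2, length / 2 + 1e-9, ring_spacing)
        ring_r = np.full(len(ring_z), float(wall_radius))
    elif kind == "hourglass":
        ring_z = np.arange(-length / 2, length / 2 + 1e-9, ring_spacing)
        ring_r = waist_radius + (end_radius - waist_radius) * (2 * ring_z / length) ** 2
    else:
        raise ValueError(f"unknown toy pore kind: {kind!r}")
    if np.any(ring_r <= vdw):
        raise ValueError("wall radius must exceed the vdW radius")

    # neighbouring pseudo-atom spheres must overlap or the probe leaks out
    for r in ring_r:
        chord = 2.0 * r * math.sin(math.pi / n_per_ring)
        if chord >= 2.0 * vdw:
            raise ValueError(
                f"ring of {n_per_ring} atoms at radius {r:.2f} A is too sparse "
                f"(chord {chord:.2f} >= sphere diameter {2 * vdw:.2f}); "
                "the probe would leak between atoms"
            )
    if len(ring_z) > 1 and ring_spacing >= 2.0 * vdw:
        raise ValueError("ring spacing too coarse; the probe would leak between rings")

    angles = np.arange(n_per_ring) * (2 * math.pi / n_per_ring)
    coords = []
    res_ids = []
    for i, (z, r) in enumerate(zip(ring_z, ring_r)):
        for a in angles:
            coords.append((r * math.cos(a), r * math.sin(a), z))
            res_ids.append(i + 1)
    coords = np.array(coords)
    n = len(coords)
    structure = Structure(
        chain_id=np.full(n, "P", dtype="U4"),
        res_id=np.array(res_ids),
        res_name=np.full(n, "TOY", dtype="U5"),
        atom_name=np.full(n, "PS", dtype="U6"),
        element=np.full(n, "C", dtype="U2"),
        coords=coords,
        occupancy=np.ones(n),
        altloc=np.full(n, "", dtype="U1"),
        hetero=np.zeros(n, dtype=bool),
    )

    rz = ring_z.copy()
    rr = ring_r.copy()

    def analytic_radius(z):
        z = np.asarray(z, dtype=float)
        d = np.sqrt(rr[None, :] ** 2 + (z[..., None] - rz[None, :]) ** 2)
        return d.min(axis=-1) - vdw

    return structure, analytic_radius


# ---------------------------------------------------------------------------
# activation traces


def synth_activation_trace(
    amp0: float,
    amp1: float,
    amp2: float,
    tau1: float,
    tau2: float,
    duration_ms: float,
    dt_ms: float = 1.0,
    noise_sd: float = 0.0,
    capacitive_amp: float = 0.0,
    capacitive_decay_ms: float = 1.0,
    voltage_mV: float = -120.0,
    seed: int = 0,
) -> CurrentTrace:
    """Double-exponential activation trace with optional transient and noise.

    y(x) = amp0 + amp1*(1 - exp(-x/tau1)) + amp2*(1 - exp(-x/tau2))
    plus an optional capacitive spike ``capacitive_amp * exp(-x/decay)``
    and i.i.d. Gaussian noise.
    """
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("time constants must be positive")
    if dt_ms <= 0:
        raise ValueError("sampling interval must be positive")
    x = np.arange(0.0, duration_ms + 0.5 * dt_ms, dt_ms)
    x = x[x <= duration_ms]
    y = amp0 + amp1 * (1.0 - np.exp(-x / tau1)) + amp2 * (1.0 - np.exp(-x / tau2))
    if capacitive_amp:
        y = y + capacitive_amp * np.exp(-x / capacitive_decay_ms)
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(x))
    return CurrentTrace(
        time_ms=x,
        current_pA=y,
        voltage_mV=voltage_mV,
        metadata={
            "pulse_start_ms": 0.0,
            "truth": {"amp0": amp0, "amp1": amp1, "amp2": amp2, "tau1": tau1, "tau2": tau2},
        },
    )
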