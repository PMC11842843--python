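"""Conformational metrics: superposition, RMSD matrices, distances, rotamers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io.structures import Structure
from .core_io.trajectories import Trajectory

__all__ = [
    "Selection",
    "RigidTransform",
    "superpose",
    "pairwise_rmsd_matrix",
    "RMSDMatrix",
    "residue_pair_distance",
    "track_rotamer",
    "RotamerTrack",
]


@dataclass
class Selection:
    """Atom selection by chain, residue range(s), and atom name."""

    chains: list | None = None
    res_ranges: list = field(default_factory=list)  # [(lo, hi), ...]; empty = all
    atom_names: tuple = ("CA",)

    def resolve(self, structure: Structure, chain_map: dict | None = None) -> dict:
        """Map (chain, res_id, atom_name) -> coordinate for matched atoms.

        ``chain_map`` relabels structure chains before matching (used for
        swapped protomer pairing).
        """
        out = {}
        for i in range(len(structure)):
            c = str(structure.chain_id[i])
            if chain_map:
                c = chain_map.get(c, c)
            if self.chains is not None and c not in self.chains:
                continue
            r = int(structure.res_id[i])
            if self.res_ranges and not any(lo <= r <= hi for lo, hi in self.res_ranges):
                continue
            if structure.atom_name[i] not in self.atom_names:
                continue
            out[(c, r, str(structure.atom_name[i]))] = structure.coords[i]
        return out


@dataclass
class RigidTransform:
    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _matched_coords(
    mobile: Structure,
    reference: Structure,
    sel: Selection,
    mobile_chain_map: dict | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    a = sel.resolve(mobile, chain_map=mobile_chain_map)
    b = sel.resolve(reference)
    common = sorted(set(a) & set(b))
    dropped = len(set(a) ^ set(b))
    if len(common) < 3:
        missing = sorted(set(a) ^ set(b))[:10]
        raise ValueError(
            f"selection resolves to only {len(common)} matched atoms "
            f"(unmatched examples: {missing})"
        )
    P = np.array([a[k] for k in common])
    Q = np.array([b[k] for k in common])
    return P, Q, dropped


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of P onto Q (proper rotation)."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = (P @ R.T) + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return RigidTransform(rotation=R, translation=t), rmsd


def superpose(
    mobile: Structure,
    reference: Structure,
    sel: Selection | None = None,
    mobile_chain_map: dict | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of matched selected atoms; returns
    (transform, RMSD in A)."""
    sel = sel or Selection()
    P, Q, _ = _matched_coords(mobile, reference, sel, mobile_chain_map)
    return _kabsch(P, Q)


@dataclass
class RMSDMatrix:
    labels: list
    values: np.ndarray
    pairing: str

    def max_offdiagonal(self) -> float:
        v = self.values.copy()
        np.fill_diagonal(v, -np.inf)
        return float(np.max(v))


def pairwise_rmsd_matrix(
    structures: list,
    sel: Selection | None = None,
    pairing: str = "best-of-swapped",
    labels: list | None = None,
    swap_chains: tuple = ("A", "B"),
) -> RMSDMatrix:
    """Symmetric matrix of superposition RMSDs.

    With ``best-of-swapped`` each pair is evaluated under both protomer
    correspondences (identity and the two chains exchanged) and the
    minimum is kept; with ``direct`` only the identity labelling is used.
    """
    if pairing not in ("direct", "best-of-swapped"):
        raise ValueError("pairing must be 'direct' or 'best-of-swapped'")
    sel = sel or Selection()
    n = len(structures)
    labels = labels or [f"s{i}" for i in range(n)]
    a, b = swap_chains
    swap_map = {a: b, b: a}
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, r = superpose(structures[i], structures[j], sel)
            if pairing == "best-of-swapped":
                _, r_swapped = superpose(structures[i], structures[j], sel, mobile_chain_map=swap_map)
                r = min(r, r_swapped)
            M[i, j] = M[j, i] = r
    return RMSDMatrix(labels=labels, values=M, pairing=pairing)


def residue_pair_distance(
    structure: Structure,
    a: tuple[str, int, str],
    b: tuple[str, int, str],
) -> float:
    """Euclidean distance in A between two named atoms (chain, residue, atom)."""
    try:
        ca = structure.atom_coord(*a)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    try:
        cb = structure.atom_coord(*b)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    return float(np.linalg.norm(ca - cb))


@dataclass
class RotamerTrack:
    """Axial displacement of one atom relative to frame 0, with a two-state
    (up/down) labelling under threshold + hysteresis."""

    particle_id: int
    times: np.ndarray
    displacement_nm: np.ndarray  # along the chosen axis
    displacement_3d_nm: np.ndarray
    states: np.ndarray  # "up" / "down"
    threshold_nm: float
    hysteresis_nm: float

    def n_transitions(self) -> int:
        return int(np.sum(self.states[1:] != self.states[:-1]))


def track_rotamer(
    traj: Trajectory,
    particle_id: int,
    axis: int = 2,
    threshold_nm: float = 0.3,
    hysteresis_nm: float = 0.1,
) -> RotamerTrack:
    """Track one atom's axial displacement and classify up/down states.

    The state flips up->down when the displacement drops below
    -(threshold + hysteresis) and back when it rises above
    -(threshold - hysteresis).
    """
    if threshold_nm <= hysteresis_nm or hysteresis_nm < 0:
        raise ValueError("need threshold > hysteresis >= 0")
    where = np.flatnonzero(traj.ids == particle_id)
    if len(where) != 1:
        raise ValueError(f"atom id {particle_id} not present in the trajectory")
    j = where[0]
    pos = traj.coords[:, j, :]
    disp = pos[:, axis] - pos[0, axis]
    disp3d = np.linalg.norm(pos - pos[0], axis=1)
    lo = -(threshold_nm + hysteresis_nm)
    hi = -(threshold_nm - hysteresis_nm)
    states = np.empty(len(disp), dtype="U4")
    state = "up"
    for i, d in enumerate(disp):
        if state == "up" and d <= lo:
            state = "down"
        elif state == "down" and d >= hi:
            state = "up"
        states[i] = state
    return RotamerTrack(
        particle_id=particle_id,
        times=traj.times.copy(),
        displacement_nm=disp,
        displacement_3d_nm=disp3d,
        states=states,
        threshold_nm=threshold_nm,
        hysteresis_nm=hysteresis_nm,
    )
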