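"""Probe-sphere pore radius profiling.

At each axial sample z the pore radius is

    r(z) = max over probe centres (x, y) of  min over atoms i of
           (||probe - atom_i|| - vdw_i)

with the probe constrained to the plane at z within a lateral search
radius of the pore axis.  Slices are processed outward from the centre
of the z range; each slice seeds a 0.25 A local grid search at the
previous slice's optimum and refines it with Nelder-Mead, so the probe
tracks the pore instead of leaking into open space outside the wall.
The procedure is deterministic and auditable.

The axis defaults to the dominant principal axis of the selected
C-alpha atoms (pore-helix selection when present), with the sign fixed
by the third moment of the axial coordinates so that re-deriving the
axis after a rigid motion reproduces the same profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .core_io.structures import Structure

__all__ = [
    "BONDI_RADII",
    "PoreProfile",
    "Constriction",
    "principal_axis_frame",
    "compute_radius_profile",
    "find_constrictions",
    "lining_residues",
]

# Bondi vdW radii (A); united-atom fallback for anything absent.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "Se": 1.90,
    "Zn": 1.39,
    "Mg": 1.73,
    "Na": 2.27,
    "K": 2.75,
    "Ca": 2.31,
    "Fe": 1.63,
}
FALLBACK_VDW = 1.70

# default pore-helix C-alpha selection used to derive the channel axis
PORE_HELIX_RANGES = ((113, 128), (196, 212))


@dataclass
class PoreProfile:
    """Radius-vs-axial-position curve in the axis-aligned frame (A)."""

    z: np.ndarray
    centers: np.ndarray  # (n, 2) optimal probe (x, y) per sample
    radius: np.ndarray
    converged: np.ndarray  # False where no atoms bound the probe ("unbounded")
    rotation: np.ndarray  # world -> axis frame
    origin: np.ndarray

    def min_radius(self) -> float:
        ok = self.converged
        return float(np.min(self.radius[ok])) if ok.any() else float("inf")

    def probe_center_world(self, i: int) -> np.ndarray:
        local = np.array([self.centers[i, 0], self.centers[i, 1], self.z[i]])
        return self.rotation.T @ local + self.origin


@dataclass
class Constriction:
    z: float
    radius: float
    profile_index: int
    lining: list | None = None


def _vdw_radii(elements: np.ndarray, table: dict) -> np.ndarray:
    radii = np.empty(len(elements))
    missing = set()
    for i, el in enumerate(elements):
        r = table.get(str(el))
        if r is None:
            missing.add(str(el))
            r = FALLBACK_VDW
        radii[i] = r
    if missing:
        warnings.warn(
            f"no vdW radius for elements {sorted(missing)}; using fallback {FALLBACK_VDW} A"
        )
    return radii


def principal_axis_frame(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    """(rotation, origin) mapping world coordinates into the axis frame.

    Uses C-alpha atoms of the pore-helix ranges when present, otherwise
    all C-alpha atoms, otherwise all atoms.  The axis is the largest-
    variance principal direction; its sign is set so the axial third
    moment is non-negative (rigid-motion invariant).
    """
    ca = structure.select(atom_names="CA")
    sel_coords = []
    if len(ca):
        for lo, hi in PORE_HELIX_RANGES:
            sub = ca.select(res_range=(lo, hi))
            if len(sub):
                sel_coords.append(sub.coords)
    if sel_coords:
        pts = np.vstack(sel_coords)
    elif len(ca):
        pts = ca.coords
    else:
        pts = structure.coords
    origin = pts.mean(axis=0)
    cov = np.cov((pts - origin).T)
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    zc = (pts - origin) @ axis
    if np.sum(zc**3) < 0:
        axis = -axis
    # complete a right-handed orthonormal frame deterministically
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    x = ref - (ref @ axis) * axis
    x /= np.linalg.norm(x)
    y = np.cross(axis, x)
    rot = np.vstack([x, y, axis])
    return rot, origin


def _axis_frame(structure: Structure, axis) -> tuple[np.ndarray, np.ndarray]:
    if axis is None or (isinstance(axis, str) and axis == "principal"):
        return principal_axis_frame(structure)
    if isinstance(axis, str) and axis == "z":
        return np.eye(3), structure.coords.mean(axis=0)
    vec = np.asarray(axis, dtype=float)
    vec /= np.linalg.norm(vec)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(vec @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    x = ref - (ref @ vec) * vec
    x /= np.linalg.norm(x)
    rot = np.vstack([x, np.cross(vec, x), vec])
    return rot, structure.coords.mean(axis=0)


def _clearance(point_xy, z, coords, radii):
    d = np.sqrt(
        (coords[:, 0] - point_xy[0]) ** 2
        + (coords[:, 1] - point_xy[1]) ** 2
        + (coords[:, 2] - z) ** 2
    )
    return float(np.min(d - radii))


def _grid(pitch: float, radius: float, center=(0.0, 0.0)) -> np.ndarray:
    n = int(np.floor(radius / pitch))
    ax = np.arange(-n, n + 1) * pitch
    gx, gy = np.meshgrid(ax, ax)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts = pts[(pts[:, 0] ** 2 + pts[:, 1] ** 2) <= radius**2]
    return pts + np.asarray(center)


def compute_radius_profile(
    structure: Structure,
    axis=None,
    z_range: tuple[float, float] | None = None,
    step: float = 0.2,
    vdw_table: dict | None = None,
    lateral_max: float = 15.0,
    grid_pitch: float = 0.25,
    include_hetero: bool = False,
) -> PoreProfile:
    """Compute the pore radius profile of a structure along its axis.

    ``step`` is the axial sampling interval in A.  Samples where no atom
    constrains the probe are flagged unconverged with infinite radius.
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    if step <= 0:
        raise ValueError("step must be positive")
    work = structure if include_hetero else structure.select(include_hetero=False)
    if len(work) == 0:
        work = structure
    rot, origin = _axis_frame(work, axis)
    coords = (work.coords - origin) @ rot.T
    radii = _vdw_radii(work.element, vdw_table or BONDI_RADII)
    max_vdw = float(np.max(radii))

    if z_range is None:
        z_range = (float(coords[:, 2].min()), float(coords[:, 2].max()))
    zs = np.arange(z_range[0], z_range[1] + 0.5 * step, step)
    zs = zs[zs <= z_range[1] + 1e-9]

    n = len(zs)
    out_r = np.empty(n)
    out_c = np.empty((n, 2))
    out_ok = np.ones(n, dtype=bool)

    order = np.argsort(coords[:, 2])
    z_sorted = coords[order, 2]

    def optimize_slice(i: int, start: np.ndarray) -> np.ndarray:
        """Track the pore locally: fine grid around ``start``, then refine."""
        z = zs[i]
        win = lateral_max + max_vdw + 1.0
        lo = np.searchsorted(z_sorted, z - win)
        hi = np.searchsorted(z_sorted, z + win)
        sub = coords[order[lo:hi]]
        sub_r = radii[order[lo:hi]]
        if len(sub) == 0:
            out_r[i] = np.inf
            out_c[i] = start
            out_ok[i] = False
            return start
        local = _grid(grid_pitch, 2.0, center=start)
        local = local[(local[:, 0] ** 2 + local[:, 1] ** 2) <= lateral_max**2]
        if len(local) == 0:
            local = start[None, :]
        d = np.sqrt(
            (local[:, 0, None] - sub[None, :, 0]) ** 2
            + (local[:, 1, None] - sub[None, :, 1]) ** 2
            + (z - sub[None, :, 2]) ** 2
        )
        clear = (d - sub_r[None, :]).min(axis=1)
        best = int(np.argmax(clear))
        res = minimize(
            lambda p: -_clearance(p, z, sub, sub_r),
            local[best],
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 200},
        )
        cand = res.x if -res.fun >= clear[best] else local[best]
        if cand[0] ** 2 + cand[1] ** 2 > lateral_max**2:
            cand = local[best]
        out_c[i] = cand
        out_r[i] = max(_clearance(cand, z, sub, sub_r), 0.0)
        return np.asarray(cand)

    # walk outward from the centre sample so each slice starts from its
    # inner neighbour's optimum and the probe cannot jump out of the pore
    mid = n // 2
    center = optimize_slice(mid, np.zeros(2))
    prev = center
    for i in range(mid + 1, n):
        prev = optimize_slice(i, prev)
    prev = center
    for i in range(mid - 1, -1, -1):
        prev = optimize_slice(i, prev)
    return PoreProfile(z=zs, centers=out_c, radius=out_r, converged=out_ok, rotation=rot, origin=origin)


def find_constrictions(profile: PoreProfile, prominence: float = 0.2) -> list[Constriction]:
    """Local minima of r(z) with at least the given prominence, narrowest first."""
    from scipy.signal import find_peaks

    if len(profile.z) < 3:
        raise ValueError("profile needs at least 3 samples")
    r = np.where(profile.converged, profile.radius, np.inf)
    finite = np.isfinite(r)
    if finite.sum() < 3:
        return []
    rr = r[finite]
    zz = profile.z[finite]
    idx_map = np.flatnonzero(finite)
    peaks, _ = find_peaks(-rr, prominence=prominence)
    out = [
        Constriction(z=float(zz[p]), radius=float(rr[p]), profile_index=int(idx_map[p]))
        for p in peaks
    ]
    return sorted(out, key=lambda c: c.radius)


def lining_residues(
    structure: Structure,
    profile: PoreProfile,
    constriction: Constriction,
    contact_cutoff: float = 1.0,
    vdw_table: dict | None = None,
    include_hetero: bool = False,
) -> list[tuple[str, str, int]]:
    """Residues with an atom within (radius + vdW + cutoff) of the probe centre."""
    work = structure if include_hetero else structure.select(include_hetero=False)
    if len(work) == 0:
        work = structure
    center = profile.probe_center_world(constriction.profile_index)
    radii = _vdw_radii(work.element, vdw_table or BONDI_RADII)
    d = np.linalg.norm(work.coords - center, axis=1)
    mask = d <= constriction.radius + radii + contact_cutoff
    found = {
        (str(c), str(rn), int(ri))
        for c, rn, ri in zip(work.chain_id[mask], work.res_name[mask], work.res_id[mask])
    }
    return sorted(found, key=lambda t: (t[0], t[2]))
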