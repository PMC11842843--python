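"""PDB structure reading with deterministic altloc resolution.

Coordinates are kept in Angstrom (the format's native unit).  Altloc
duplicates are resolved to a single atom per (chain, residue, atom name):
the highest-occupancy location wins, ties broken by altloc label order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from biotite.structure.io.pdb import PDBFile


class StructureParseError(ValueError):
    """Raised for malformed or empty coordinate files."""


@dataclass
class Structure:
    """A set of atoms from one model of a coordinate file.

    All per-atom annotations are parallel numpy arrays; ``coords`` is
    (n_atoms, 3) in Angstrom.
    """

    chain_id: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    occupancy: np.ndarray
    altloc: np.ndarray
    hetero: np.ndarray
    model: int | None = None
    _chain_index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.coords) and not np.all(np.isfinite(self.coords)):
            raise StructureParseError("non-finite coordinates in structure")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    def chain_residue_index(self) -> dict[str, np.ndarray]:
        """Sorted unique residue numbers per chain."""
        if not self._chain_index:
            for c in self.chains:
                mask = self.chain_id == c
                self._chain_index[c] = np.unique(self.res_id[mask])
        return self._chain_index

    def select(
        self,
        chain: str | list[str] | None = None,
        res_range: tuple[int, int] | None = None,
        atom_names: str | list[str] | None = None,
        include_hetero: bool = True,
    ) -> "Structure":
        mask = np.ones(len(self), dtype=bool)
        if chain is not None:
            chains = [chain] if isinstance(chain, str) else list(chain)
            mask &= np.isin(self.chain_id, chains)
        if res_range is not None:
            lo, hi = res_range
            mask &= (self.res_id >= lo) & (self.res_id <= hi)
        if atom_names is not None:
            names = [atom_names] if isinstance(atom_names, str) else list(atom_names)
            mask &= np.isin(self.atom_name, names)
        if not include_hetero:
            mask &= ~self.hetero
        return self._subset(mask)

    def _subset(self, mask: np.ndarray) -> "Structure":
        return Structure(
            chain_id=self.chain_id[mask],
            res_id=self.res_id[mask],
            res_name=self.res_name[mask],
            atom_name=self.atom_name[mask],
            element=self.element[mask],
            coords=self.coords[mask],
            occupancy=self.occupancy[mask],
            altloc=self.altloc[mask],
            hetero=self.hetero[mask],
            model=self.model,
        )

    def atom_coord(self, chain: str, res: int, atom: str) -> np.ndarray:
        """Coordinate of a single named atom; KeyError if absent."""
        mask = (self.chain_id == chain) & (self.res_id == res) & (self.atom_name == atom)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise KeyError(f"atom not found: chain {chain!r} residue {res} atom {atom!r}")
        return self.coords[idx[0]].copy()

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        out = self._subset(np.ones(len(self), dtype=bool))
        out.coords = self.coords @ rotation.T + translation
        return out


def _prevalidate_pdb(path: Path) -> int:
    """Check ATOM/HETATM coordinate fields line by line; return record count."""
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                n += 1
                if len(line) < 54:
                    raise StructureParseError(f"truncated record at line {lineno}")
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise StructureParseError(
                            f"malformed coordinate field at line {lineno}"
                        ) from None
    return n


def _resolve_altlocs(
    order_keys: list[tuple], occupancy: np.ndarray, altloc: np.ndarray
) -> np.ndarray:
    """Indices to keep: one atom per key, highest occupancy, ties by label."""
    best: dict[tuple, int] = {}
    for i, key in enumerate(order_keys):
        j = best.get(key)
        if j is None:
            best[key] = i
        else:
            # higher occupancy wins; on a tie the smaller altloc label wins
            if (occupancy[i], -ord(altloc[i] or " ")) > (occupancy[j], -ord(altloc[j] or " ")):
                best[key] = i
    return np.array(sorted(best.values()), dtype=int)


def read_structure(path: str | Path, model: int = 1) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Parameters
    ----------
    path : path to a PDB-format file with at least one ATOM/HETATM record.
    model : 1-based model number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    n_records = _prevalidate_pdb(path)
    if n_records == 0:
        raise StructureParseError(f"no atoms: {path} contains no ATOM/HETATM records")

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=model, altloc="all", extra_fields=["occupancy"])
    altloc_id = (
        atoms.altloc_id
        if "altloc_id" in atoms.get_annotation_categories()
        else np.full(atoms.array_length(), "", dtype="U1")
    )
    altloc_id = np.char.strip(altloc_id.astype("U1"))

    keys = list(
        zip(
            atoms.chain_id.tolist(),
            atoms.res_id.tolist(),
            atoms.ins_code.tolist(),
            atoms.atom_name.tolist(),
        )
    )
    keep = _resolve_altlocs(keys, atoms.occupancy, altloc_id)

    return Structure(
        chain_id=atoms.chain_id[keep].astype("U4"),
        res_id=atoms.res_id[keep].astype(int),
        res_name=atoms.res_name[keep].astype("U5"),
        atom_name=atoms.atom_name[keep].astype("U6"),
        element=np.char.capitalize(atoms.element[keep].astype("U2")),
        coords=np.asarray(atoms.coord[keep], dtype=float),
        occupancy=np.asarray(atoms.occupancy[keep], dtype=float),
        altloc=altloc_id[keep],
        hetero=atoms.hetero[keep].astype(bool),
        model=model,
    )
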