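import numpy as np
import pytest

from channelflux.core_io.trajectories import Trajectory


def format_pdb_line(
    serial,
    name,
    resname,
    chain,
    resseq,
    x,
    y,
    z,
    occupancy=1.0,
    altloc=" ",
    element="C",
    record="ATOM",
):
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:>5d} {name_field}{altloc}{resname:<3s} {chain}"
        f"{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def write_pdb(tmp_path):
    """Write ATOM records to a temporary PDB file; returns the path."""

    def _write(lines, name="test.pdb"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\nEND\n")
        return path

    return _write


@pytest.fixture
def simple_trajectory():
    """Build a Trajectory from per-ion z waypoints with a fixed reference.

    z_per_ion: dict id -> array of z values (nm), one per frame.
    """

    def _build(z_per_ion, times=None, box_z=9.0, species="chloride", with_protein=True):
        ids = sorted(z_per_ion)
        n_frames = len(next(iter(z_per_ion.values())))
        times = np.asarray(times) if times is not None else np.arange(n_frames, dtype=float)
        n_extra = 2 if with_protein else 0
        coords = np.zeros((n_frames, len(ids) + n_extra, 3))
        for j, pid in enumerate(ids):
            coords[:, j, 2] = z_per_ion[pid]
        all_species = [species] * len(ids)
        all_ids = list(ids)
        if with_protein:
            coords[:, len(ids), 2] = -0.5
            coords[:, len(ids) + 1, 2] = 0.5
            all_species += ["protein-atom", "protein-atom"]
            all_ids += [9001, 9002]
        return Trajectory(
            times=times,
            ids=np.array(all_ids),
            species=np.array(all_species),
            coords=coords,
            box=np.tile([4.0, 4.0, box_z], (n_frames, 1)),
        )

    return _build
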