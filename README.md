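# channelflux

Analytics for anion-channel permeation studies: event counting and
single-channel current estimation from ion trajectories, knock-on /
trapping / facilitation regime statistics, probe-sphere pore radius
profiling of channel structures, conformational-class metrics (RMSD
matrices, residue-pair distances, rotamer tracking), and
double-exponential activation-kinetics fitting of patch-clamp traces.
A synthetic-data module generates all required inputs with exact ground
truth, so the full pipeline is testable offline at desk scale.

## Layout

| module | contents |
| --- | --- |
| `channelflux.core_io` | PDB structures (altloc-resolved), JSON-lines trajectories, current traces, event CSVs |
| `channelflux.synthetic_data` | knock-on hopping simulator with ground truth, toy pore walls with analytic radius profiles, Eq.-style activation traces |
| `channelflux.permeation` | boundary-plane transit detection, flux summaries, flux→current conversion, conductive phases, site occupancy, influx-lag histograms, axial densities |
| `channelflux.pore_geometry` | pore radius profiles (max–min probe clearance per axial slice), constrictions, lining residues |
| `channelflux.conformation` | rigid superposition (Kabsch), pairwise RMSD with protomer-swap pairing, residue-pair distances, up/down rotamer tracking |
| `channelflux.kinetics` | double-exponential activation fits, IV curves, exact two-sided Mann–Whitney test |
| `channelflux.pipeline` | YAML-driven end-to-end runs with manifest |

## CLI

```bash
# synthesize a trajectory with ground truth
channelflux simulate --preset mixed --seed 1 --out out/

# detect permeation events and summarize fluxes
channelflux permeate --traj out/trajectory.jsonl --offset-nm 1.5 \
    --voltage-mv -500 --out out/

# pore radius profile of a structure
channelflux pore --pdb data/pdb/8ZTH.pdb --step 0.2 --out profile.csv

# conformational metrics
channelflux conf rmsd --pdbs a.pdb b.pdb --range 86-243 --out matrix.csv
channelflux conf dist --pdb x.pdb --pair A:148:CA,A:227:CA

# activation kinetics fit
channelflux fit --trace trace.csv --voltage-mv -120 --window-end 2500 --out fit.json

# full pipeline from a config
channelflux run config.yaml
```

Presets `malate-high`, `chloride-high`, and `mixed` reproduce the three
qualitative conduction regimes: continuous knock-on malate flow, bursty
trapped-chloride flux, and malate-facilitated chloride release.

## Units and conventions

Structures are in Å (PDB convention); trajectories in nm/ns (MD
convention); currents in pA, potentials in mV. +z points cytosol →
vacuole, an influx is a +z transit, and anion influx under
cytosolic-negative potential is reported as negative current
(1 pA ≡ 6.24 × 10⁶ monovalent ions/s).
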