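"""GRO coordinate import/export (nm units), via MDAnalysis.

Atom names carry the bead type; the residue index carries the molecule
index.  Velocities are written when present and read when the file has
them (zeros otherwise).
"""

from __future__ import annotations

import os

import numpy as np

from .model import DEFAULT_BEAD_MASS, ParticleState, SimulationBox

__all__ = ["read_gro", "write_gro"]


def write_gro(path, state: ParticleState, box: SimulationBox, with_velocities=True):
    """Write a GRO snapshot (fixed-column format, 3-decimal nm precision)."""
    import MDAnalysis as mda

    n = state.n
    if n == 0:
        with open(path, "w") as fh:
            fh.write("pfmd system\n    0\n")
            fh.write("".join(f"{L:10.5f}" for L in box.lengths) + "\n")
        return
    n_res = int(state.molecule.max()) + 1
    u = mda.Universe.empty(
        n, n_residues=n_res, atom_resindex=state.molecule,
        trajectory=True, velocities=with_velocities,
    )
    u.add_TopologyAttr("names", [state.type_names[t] for t in state.types])
    u.add_TopologyAttr("resnames", ["MOL"] * n_res)
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    u.atoms.positions = state.positions * 10.0  # nm -> Angstrom
    if with_velocities:
        u.atoms.velocities = state.velocities * 10.0
    u.dimensions = [*(box.lengths * 10.0), 90.0, 90.0, 90.0]
    u.atoms.write(str(path))


def read_gro(path, type_names=None, mass=DEFAULT_BEAD_MASS):
    """Read a GRO file into (ParticleState, SimulationBox).

    ``type_names`` fixes the type ordering; by default types are assigned
    in order of first appearance of each atom name.  Files without
    velocities yield zero velocities.
    """
    import MDAnalysis as mda

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        u = mda.Universe(str(path))
    except Exception as exc:
        raise ValueError(f"could not parse GRO file {path}: {exc}") from exc
    names = list(u.atoms.names)
    if type_names is None:
        type_names = list(dict.fromkeys(names))
    t_idx = {name: i for i, name in enumerate(type_names)}
    try:
        types = np.array([t_idx[nm] for nm in names], dtype=int)
    except KeyError as exc:
        raise ValueError(f"atom name {exc} not in type_names {type_names}") from exc
    box = SimulationBox(np.asarray(u.dimensions[:3], dtype=float) / 10.0)
    pos = box.wrap(u.atoms.positions.astype(float) / 10.0)
    if getattr(u.trajectory.ts, "has_velocities", False):
        vel = u.atoms.velocities.astype(float) / 10.0
    else:
        vel = np.zeros_like(pos)
    molecule = u.atoms.resindices.astype(int)
    state = ParticleState(pos, vel, types, np.full(len(pos), mass), molecule, type_names)
    return state, box
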