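"""Synthetic system builders: homogeneous fluid, binary mixture, bilayer.

Builders produce wrapped, Maxwell-Boltzmann-initialized particle states
(and, for the bilayer, a matching bonded topology).  They are first-class
parts of the package: tests and the calibration/optimization machinery run
on systems produced here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    DEFAULT_BEAD_MASS,
    KB,
    AngleRecord,
    BondRecord,
    ParticleState,
    SimulationBox,
    Topology,
)

__all__ = [
    "BuilderSpec",
    "maxwell_boltzmann_velocities",
    "build_homogeneous",
    "build_binary",
    "build_bilayer",
    "LIPID_BEAD_NAMES",
    "DEFAULT_BOND",
    "DEFAULT_ANGLE",
]

#: 12-bead Martini-like DPPC layout: 3-bead head + glycerol + two 4-bead tails.
LIPID_BEAD_NAMES = ["N", "P", "G", "G", "C", "C", "C", "C", "C", "C", "C", "C"]

#: Default bonded parameters (builder defaults, overridable in topologies).
DEFAULT_BOND = {"r0": 0.47, "k": 1250.0}  # nm, kJ mol^-1 nm^-2
DEFAULT_ANGLE = {"theta0": np.pi, "ka": 25.0}  # rad, kJ/mol

# intra-lipid bonds / angles on the 12-bead layout (indices into one lipid)
_LIPID_BONDS = [(0, 1), (1, 2), (2, 3), (2, 4), (4, 5), (5, 6), (6, 7),
                (3, 8), (8, 9), (9, 10), (10, 11)]
_LIPID_ANGLES = [(0, 1, 2), (1, 2, 4), (2, 4, 5), (4, 5, 6), (5, 6, 7),
                 (3, 8, 9), (8, 9, 10), (9, 10, 11)]

# 10-bead triglyceride: central glycerol + three 3-bead tails
_TG_BEAD_NAMES = ["G"] + ["C"] * 9
_TG_BONDS = [(0, 1), (1, 2), (2, 3), (0, 4), (4, 5), (5, 6), (0, 7), (7, 8), (8, 9)]
_TG_ANGLES = [(0, 1, 2), (1, 2, 3), (0, 4, 5), (4, 5, 6), (0, 7, 8), (7, 8, 9)]


@dataclass
class BuilderSpec:
    """Declarative description of a synthetic system."""

    kind: str  # "homogeneous" | "binary" | "bilayer"
    counts: dict
    box: tuple = (5.2, 5.2, 5.2)
    temperature: float = 300.0
    area_per_lipid: float | None = None
    n_tg: int = 0
    premixed: bool = False
    seed: int = 0

    def build(self):
        if self.kind == "homogeneous":
            return build_homogeneous(
                n=self.counts.get("W", 1171),
                box_lengths=self.box,
                temperature=self.temperature,
                seed=self.seed,
            )
        if self.kind == "binary":
            return build_binary(
                n_a=self.counts.get("A", 5083),
                n_b=self.counts.get("B", 5472),
                box_lengths=self.box,
                temperature=self.temperature,
                premixed=self.premixed,
                seed=self.seed,
            )
        if self.kind == "bilayer":
            return build_bilayer(
                n_lipids=self.counts.get("lipid", 528),
                n_solvent=self.counts.get("W", 14000),
                box_lengths=self.box,
                temperature=self.temperature,
                area_per_lipid=self.area_per_lipid,
                n_tg=self.n_tg,
                seed=self.seed,
            )
        raise ValueError(f"unknown system kind {self.kind!r}")


def maxwell_boltzmann_velocities(masses, temperature, rng, remove_com=True):
    """Sample velocities at T (nm/ps) and optionally zero total momentum."""
    masses = np.asarray(masses, dtype=float)
    v = rng.standard_normal((len(masses), 3)) * np.sqrt(KB * temperature / masses)[:, None]
    if remove_com and len(masses):
        v -= np.average(v, axis=0, weights=masses)
    return v


def build_homogeneous(n=1171, box_lengths=(5.2, 5.2, 5.2), temperature=300.0,
                      mass=DEFAULT_BEAD_MASS, seed=0):
    """Single-type fluid with uniform random positions."""
    rng = np.random.default_rng(seed)
    box = SimulationBox(np.asarray(box_lengths, dtype=float))
    pos = rng.uniform(0.0, 1.0, (n, 3)) * box.lengths
    masses = np.full(n, mass)
    state = ParticleState(
        pos,
        maxwell_boltzmann_velocities(masses, temperature, rng),
        np.zeros(n, dtype=int),
        masses,
        np.arange(n),
        ["W"],
    )
    return state, box


def build_binary(n_a=5083, n_b=5472, box_lengths=(10.6, 10.6, 10.6), temperature=300.0,
                 mass=DEFAULT_BEAD_MASS, premixed=False, seed=0):
    """Two-species monatomic mixture, pre-separated into slabs by default.

    With slab initialization species A occupies the lower part of the box
    along z and B the upper part, so the interface normal is z.
    """
    rng = np.random.default_rng(seed)
    box = SimulationBox(np.asarray(box_lengths, dtype=float))
    n = n_a + n_b
    pos = rng.uniform(0.0, 1.0, (n, 3)) * box.lengths
    if not premixed:
        z_split = box.lengths[2] * n_a / n
        pos[:n_a, 2] = rng.uniform(0.0, z_split, n_a)
        pos[n_a:, 2] = rng.uniform(z_split, box.lengths[2], n_b)
    types = np.concatenate([np.zeros(n_a, dtype=int), np.ones(n_b, dtype=int)])
    masses = np.full(n, mass)
    state = ParticleState(
        pos,
        maxwell_boltzmann_velocities(masses, temperature, rng),
        types,
        masses,
        np.arange(n),
        ["A", "B"],
    )
    return state, box


#: canonical type order for lipid systems
LIPID_TYPE_NAMES = ["N", "P", "G", "C", "W"]

#: Placeholder mixing matrix for the lipid system (kJ/mol), ordered as
#: LIPID_TYPE_NAMES.  These are builder defaults of Flory-Huggins-like
#: magnitude that hold a lamellar bilayer together (hydrophobic C repels
#: water strongly, heads are water-miscible); production parametrizations
#: should be obtained with the optimize module and supplied via config.
DEFAULT_LIPID_CHI = np.array(
    [
        #  N     P     G     C     W
        [0.0, -2.0, 4.0, 27.0, -4.0],  # N
        [-2.0, 0.0, 4.0, 27.0, -4.0],  # P
        [4.0, 4.0, 0.0, 9.0, 6.0],  # G
        [27.0, 27.0, 9.0, 0.0, 42.0],  # C
        [-4.0, -4.0, 6.0, 42.0, 0.0],  # W
    ]
)


def default_field_params(kind: str, kappa: float = 0.05, a: float = 9.21,
                         sigma: float = 0.238):
    """Field parameters a builder-emitted config wires in by default.

    binary systems get the immiscible chi_AB = 36 kJ/mol; bilayer systems
    get the documented placeholder lipid matrix; homogeneous systems a
    single-type zero matrix.
    """
    from .model import FieldParams

    if kind == "homogeneous":
        chi = np.zeros((1, 1))
    elif kind == "binary":
        chi = np.array([[0.0, 36.0], [36.0, 0.0]])
    elif kind == "bilayer":
        chi = DEFAULT_LIPID_CHI.copy()
    else:
        raise ValueError(f"unknown system kind {kind!r}")
    return FieldParams(chi=chi, kappa=kappa, a=a, sigma=sigma)


def _add_molecule(topology, bead_names, bonds, angles, offset,
                  bond_params=None, angle_params=None):
    bp = {**DEFAULT_BOND, **(bond_params or {})}
    ap = {**DEFAULT_ANGLE, **(angle_params or {})}
    for i, j in bonds:
        topology.bonds.append(BondRecord(offset + i, offset + j, bp["r0"], bp["k"]))
    for i, j, k in angles:
        topology.angles.append(AngleRecord(offset + i, offset + j, offset + k,
                                           ap["theta0"], ap["ka"]))


def build_bilayer(n_lipids=528, n_solvent=14000, box_lengths=(13.0, 13.0, 14.0),
                  temperature=323.0, mass=DEFAULT_BEAD_MASS, area_per_lipid=None,
                  n_tg=0, seed=0, bond_params=None, angle_params=None):
    """Lamellar two-leaflet bilayer of 12-bead lipids plus solvent.

    Lipids are placed on a square lattice per leaflet with tails pointing
    toward the midplane; optional triglycerides go between the leaflets and
    solvent beads fill the two water slabs.  Returns (state, topology, box).
    """
    if n_lipids % 2:
        raise ValueError("lipid count must be even (two leaflets)")
    rng = np.random.default_rng(seed)
    box = SimulationBox(np.asarray(box_lengths, dtype=float))
    lateral_area = box.lengths[0] * box.lengths[1]
    n_leaflet = n_lipids // 2
    if area_per_lipid is not None and area_per_lipid * n_leaflet > lateral_area * (1 + 1e-9):
        raise ValueError("requested area per lipid exceeds the lateral box area")
    zmid = 0.5 * box.lengths[2]
    # z offsets of the 12 beads above the midplane for the upper leaflet
    dz = np.array([1.95, 1.65, 1.35, 1.35, 1.05, 0.75, 0.45, 0.15, 1.05, 0.75, 0.45, 0.15])
    dxy = np.array([[0.0, 0.0], [0.0, 0.0], [0.0, 0.0], [0.3, 0.0],
                    [0.0, 0.0], [0.0, 0.0], [0.0, 0.0], [0.0, 0.0],
                    [0.3, 0.0], [0.3, 0.0], [0.3, 0.0], [0.3, 0.0]])
    n_side = int(np.ceil(np.sqrt(n_leaflet)))
    sx = box.lengths[0] / n_side
    sy = box.lengths[1] / n_side
    t_idx = {name: i for i, name in enumerate(LIPID_TYPE_NAMES)}

    positions, types, molecule = [], [], []
    topology = Topology(molecules={"DPPC": LIPID_BEAD_NAMES, "TG": _TG_BEAD_NAMES,
                                   "W": ["W"]})
    mol = 0
    for leaflet, sign in ((0, 1.0), (1, -1.0)):
        for li in range(n_leaflet):
            gx = (li % n_side + 0.5) * sx
            gy = (li // n_side + 0.5) * sy
            offset = len(positions)
            for b, name in enumerate(LIPID_BEAD_NAMES):
                jitter = rng.uniform(-0.05, 0.05, 3)
                positions.append([
                    gx + dxy[b, 0] + jitter[0],
                    gy + dxy[b, 1] + jitter[1],
                    zmid + sign * dz[b] + jitter[2],
                ])
                types.append(t_idx[name])
                molecule.append(mol)
            _add_molecule(topology, LIPID_BEAD_NAMES, _LIPID_BONDS, _LIPID_ANGLES,
                          offset, bond_params, angle_params)
            mol += 1
    for _ in range(n_tg):
        cx, cy = rng.uniform(0, box.lengths[0]), rng.uniform(0, box.lengths[1])
        offset = len(positions)
        tg_dz = np.array([0.0, 0.3, 0.6, 0.9, 0.3, 0.6, 0.9, 0.3, 0.6, 0.9])
        tg_dx = np.array([0.0, 0.25, 0.25, 0.25, -0.25, -0.25, -0.25, 0.0, 0.0, 0.0])
        sgn = rng.choice([-1.0, 1.0])
        for b, name in enumerate(_TG_BEAD_NAMES):
            jitter = rng.uniform(-0.05, 0.05, 3)
            positions.append([cx + tg_dx[b] + jitter[0], cy + jitter[1],
                              zmid + sgn * 0.3 * (tg_dz[b] > 0) * tg_dz[b] + jitter[2]])
            types.append(t_idx[name])
            molecule.append(mol)
        _add_molecule(topology, _TG_BEAD_NAMES, _TG_BONDS, _TG_ANGLES,
                      offset, bond_params, angle_params)
        mol += 1
    # solvent in the two slabs outside the membrane
    z_top = zmid + dz.max() + 0.25
    z_bot = zmid - dz.max() - 0.25
    for _ in range(n_solvent):
        x = rng.uniform(0, box.lengths[0])
        y = rng.uniform(0, box.lengths[1])
        w_top = box.lengths[2] - z_top
        w_bot = z_bot
        if rng.uniform(0, w_top + w_bot) < w_bot:
            z = rng.uniform(0, z_bot)
        else:
            z = rng.uniform(z_top, box.lengths[2])
        positions.append([x, y, z])
        types.append(t_idx["W"])
        molecule.append(mol)
        mol += 1

    positions = box.wrap(np.asarray(positions))
    types = np.asarray(types)
    masses = np.full(len(positions), mass)
    state = ParticleState(
        positions,
        maxwell_boltzmann_velocities(masses, temperature, rng),
        types,
        masses,
        np.asarray(molecule),
        LIPID_TYPE_NAMES,
    )
    return state, topology, box
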