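"""Domain types, units and shared invariants.

The internal unit system is the GROMACS-style one: length nm, time ps,
mass g/mol, energy kJ/mol, temperature K.  Pressure is carried internally
in kJ mol^-1 nm^-3 and converted to bar only at reporting boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "KB",
    "BAR_PER_KJ_NM3",
    "DEFAULT_BEAD_MASS",
    "DEFAULT_RHO0",
    "to_bar",
    "from_bar",
    "SimulationBox",
    "ParticleState",
    "Topology",
    "BondRecord",
    "AngleRecord",
    "FieldParams",
    "ThermoBaroParams",
    "IntegratorParams",
]

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 0.00831446

#: 1 kJ mol^-1 nm^-3 expressed in bar (10^3 / (N_A * 10^-27 m^3 * 10^5 Pa)).
BAR_PER_KJ_NM3 = 16.6054

#: Default coarse-grained bead mass, g/mol (four waters per bead).
DEFAULT_BEAD_MASS = 72.0

#: Number density of 4:1-mapped water at 1 g/cm^3, nm^-3.
DEFAULT_RHO0 = 8.364


def to_bar(value):
    """Convert a pressure from kJ mol^-1 nm^-3 to bar."""
    return np.asarray(value) * BAR_PER_KJ_NM3 if np.ndim(value) else value * BAR_PER_KJ_NM3


def from_bar(value):
    """Convert a pressure from bar to kJ mol^-1 nm^-3."""
    return np.asarray(value) / BAR_PER_KJ_NM3 if np.ndim(value) else value / BAR_PER_KJ_NM3


@dataclass
class SimulationBox:
    """Orthorhombic periodic box with per-axis edge lengths in nm."""

    lengths: np.ndarray
    periodic: bool = True

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=float).copy()
        if self.lengths.shape != (3,):
            raise ValueError("box lengths must be a 3-vector")
        if not np.all(self.lengths > 0):
            raise ValueError("box lengths must be positive")

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Wrap positions into [0, L_a) per axis.  Idempotent."""
        wrapped = np.mod(positions, self.lengths)
        # mod can return L_a exactly for tiny negative inputs; fold those back
        wrapped[wrapped == self.lengths] = 0.0
        return wrapped

    def minimum_image(self, dr: np.ndarray) -> np.ndarray:
        """Minimum-image displacement vectors."""
        return dr - self.lengths * np.round(dr / self.lengths)

    def scale(self, mu: np.ndarray) -> "SimulationBox":
        return SimulationBox(self.lengths * np.asarray(mu, dtype=float))

    def copy(self) -> "SimulationBox":
        return SimulationBox(self.lengths.copy())


@dataclass
class ParticleState:
    """Positions, velocities and identities of all coarse-grained beads.

    ``types`` are small integers indexing into ``type_names``; ``molecule``
    holds a molecule index per bead so bonded terms and builders can address
    whole molecules.
    """

    positions: np.ndarray
    velocities: np.ndarray
    types: np.ndarray
    masses: np.ndarray
    molecule: np.ndarray
    type_names: Sequence[str]

    def __post_init__(self):
        n = len(self.positions)
        self.positions = np.asarray(self.positions, dtype=float).reshape(n, 3)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(n, 3)
        self.types = np.asarray(self.types, dtype=np.int64).reshape(n)
        self.masses = np.asarray(self.masses, dtype=float).reshape(n)
        self.molecule = np.asarray(self.molecule, dtype=np.int64).reshape(n)
        self.type_names = list(self.type_names)
        if self.types.size and self.types.max() >= len(self.type_names):
            raise ValueError("type index out of range of type_names")

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    def type_counts(self) -> np.ndarray:
        return np.bincount(self.types, minlength=self.n_types)

    def kinetic_energy(self) -> float:
        return 0.5 * float(np.sum(self.masses[:, None] * self.velocities**2))

    def copy(self) -> "ParticleState":
        return ParticleState(
            self.positions.copy(),
            self.velocities.copy(),
            self.types.copy(),
            self.masses.copy(),
            self.molecule.copy(),
            list(self.type_names),
        )


@dataclass(frozen=True)
class BondRecord:
    i: int
    j: int
    r0: float  # nm
    k: float  # kJ mol^-1 nm^-2

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("bond indices must be distinct")
        if self.r0 <= 0:
            raise ValueError("equilibrium bond length must be positive")


@dataclass(frozen=True)
class AngleRecord:
    i: int
    j: int
    k: int
    theta0: float  # rad
    ka: float  # kJ/mol

    def __post_init__(self):
        if len({self.i, self.j, self.k}) != 3:
            raise ValueError("angle indices must be distinct")


@dataclass
class Topology:
    """Bonded interaction records (harmonic bonds, harmonic-cosine angles)."""

    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    molecules: dict = field(default_factory=dict)  # name -> bead-type sequence

    def bond_arrays(self):
        if not self.bonds:
            return (np.empty((0, 2), dtype=int), np.empty(0), np.empty(0))
        idx = np.array([[b.i, b.j] for b in self.bonds], dtype=int)
        r0 = np.array([b.r0 for b in self.bonds])
        kb = np.array([b.k for b in self.bonds])
        return idx, r0, kb

    def angle_arrays(self):
        if not self.angles:
            return (np.empty((0, 3), dtype=int), np.empty(0), np.empty(0))
        idx = np.array([[a.i, a.j, a.k] for a in self.angles], dtype=int)
        th0 = np.array([a.theta0 for a in self.angles])
        ka = np.array([a.ka for a in self.angles])
        return idx, th0, ka


@dataclass
class FieldParams:
    """Parameters of the density-functional interaction energy.

    chi is the symmetric type-mixing matrix (kJ/mol, zero diagonal), kappa
    the incompressibility (mol/kJ), a the equation-of-state density offset
    (nm^-3), rho0 the reference bead density (nm^-3) and sigma the Gaussian
    filter spread per type (nm).
    """

    chi: np.ndarray
    kappa: float
    a: float
    rho0: float = DEFAULT_RHO0
    sigma: np.ndarray | float = 0.238
    mesh_shape: Optional[tuple] = None

    def __post_init__(self):
        self.chi = np.atleast_2d(np.asarray(self.chi, dtype=float))
        if self.chi.shape[0] != self.chi.shape[1]:
            raise ValueError("chi must be square")
        if not np.allclose(self.chi, self.chi.T):
            raise ValueError("chi must be symmetric")
        if np.any(np.abs(np.diag(self.chi)) > 0):
            raise ValueError("chi diagonal must be zero (self-mixing handled by kappa)")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.rho0 <= 0:
            raise ValueError("rho0 must be positive")
        sig = np.asarray(self.sigma, dtype=float)
        if sig.ndim == 0:
            sig = np.full(self.n_types, float(sig))
        if sig.shape != (self.n_types,):
            raise ValueError("sigma must be scalar or one value per type")
        if np.any(sig <= 0):
            raise ValueError("sigma must be positive")
        self.sigma = sig
        if self.mesh_shape is not None:
            self.mesh_shape = tuple(int(m) for m in self.mesh_shape)
            if len(self.mesh_shape) != 3 or min(self.mesh_shape) < 4:
                raise ValueError("mesh_shape needs >= 4 points per axis")

    @property
    def n_types(self) -> int:
        return self.chi.shape[0]


# FFT-friendly mesh sizes (products of 2, 3, 5).
_SMOOTH = [4, 5, 6, 8, 9, 10, 12, 15, 16, 18, 20, 24, 25, 27, 30, 32, 36, 40,
           45, 48, 50, 54, 60, 64, 72, 75, 80, 81, 90, 96, 100, 108, 120, 128,
           135, 144, 150, 160, 162, 180, 192, 200, 216, 240, 256, 270, 288, 300]


def default_mesh_shape(box: SimulationBox, sigma: float) -> tuple:
    """Smallest FFT-friendly mesh with cell spacing <= sigma along each axis."""
    shape = []
    for L in box.lengths:
        need = int(np.ceil(L / sigma))
        shape.append(next((m for m in _SMOOTH if m >= need), need))
    return tuple(shape)


@dataclass
class ThermoBaroParams:
    """Thermostat/barostat settings (CSVR + Berendsen or SCR)."""

    temperature: float = 300.0  # K
    tau_t: float = 0.1  # ps
    pressure: float = 1.0  # bar
    beta: float = 4.6e-5  # bar^-1, isothermal compressibility of water
    tau_p: float = 1.0  # ps
    barostat: str = "berendsen"  # "berendsen" | "scr" | "none"
    mode: str = "isotropic"  # "isotropic" | "semi-isotropic" | "constant-area"
    seed: int = 0

    def __post_init__(self):
        if self.tau_t <= 0:
            raise ValueError("tau_t must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.barostat not in ("berendsen", "scr", "none"):
            raise ValueError(f"unknown barostat {self.barostat!r}")
        if self.mode not in ("isotropic", "semi-isotropic", "constant-area"):
            raise ValueError(f"unknown coupling mode {self.mode!r}")
        if self.barostat != "none" and self.tau_p < self.tau_t:
            warnings.warn(
                "tau_p < tau_t: pressure coupling should remain weaker (slower) "
                "than the thermostat coupling",
                stacklevel=2,
            )


@dataclass
class IntegratorParams:
    """rRESPA time steps: outer dt1 for field forces, inner dt2 for bonded."""

    dt_outer: float = 0.3  # ps
    dt_inner: float = 0.03  # ps

    def __post_init__(self):
        if self.dt_inner <= 0 or self.dt_outer <= 0:
            raise ValueError("time steps must be positive")
        ratio = self.dt_outer / self.dt_inner
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError("dt_outer must be an integer multiple of dt_inner")

    @property
    def n_inner(self) -> int:
        return int(round(self.dt_outer / self.dt_inner))
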