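"""Intramolecular energies, forces and per-axis virials.

Harmonic bonds U = 1/2 k_b (r - r0)^2 and harmonic-cosine angles
U = 1/2 k_a (cos theta - cos theta0)^2, with minimum-image displacements.
The per-axis virial r_a F_a is what enters the diagonal pressure tensor;
it equals -L_a dU/dL_a under affine scaling of intramolecular distances.
"""

from __future__ import annotations

import numpy as np

from .model import SimulationBox

__all__ = ["bond_energy_forces", "angle_energy_forces"]


def bond_energy_forces(
    positions: np.ndarray,
    box: SimulationBox,
    idx: np.ndarray,
    r0: np.ndarray,
    kb: np.ndarray,
    per_interaction: bool = False,
):
    """Energy (kJ/mol), per-particle forces and per-axis virial of all bonds."""
    n = len(positions)
    forces = np.zeros((n, 3))
    if len(idx) == 0:
        out = (0.0, forces, np.zeros(3))
        return out + (np.zeros((0, 3)),) if per_interaction else out
    rij = box.minimum_image(positions[idx[:, 0]] - positions[idx[:, 1]])
    r = np.linalg.norm(rij, axis=1)
    if np.any(r > 0.5 * np.min(box.lengths)):
        raise ValueError("bond length exceeds half the box: minimum image is ambiguous")
    energy = 0.5 * float(np.sum(kb * (r - r0) ** 2))
    # force on i along -dU/dr_i
    fmag = -kb * (r - r0) / np.where(r > 0, r, 1.0)
    fij = fmag[:, None] * rij
    np.add.at(forces, idx[:, 0], fij)
    np.add.at(forces, idx[:, 1], -fij)
    per = rij * fij  # r_a F_a per bond per axis
    virial = per.sum(axis=0)
    if per_interaction:
        return energy, forces, virial, per
    return energy, forces, virial


def angle_energy_forces(
    positions: np.ndarray,
    box: SimulationBox,
    idx: np.ndarray,
    theta0: np.ndarray,
    ka: np.ndarray,
    per_interaction: bool = False,
):
    """Energy, forces and per-axis virial of all harmonic-cosine angles.

    Angle records are (i, j, k) with j the vertex.  Degenerate collinear
    geometries are handled by clamping cos theta into [-1, 1].
    """
    n = len(positions)
    forces = np.zeros((n, 3))
    if len(idx) == 0:
        out = (0.0, forces, np.zeros(3))
        return out + (np.zeros((0, 3)),) if per_interaction else out
    ri, rj, rk = positions[idx[:, 0]], positions[idx[:, 1]], positions[idx[:, 2]]
    rij = box.minimum_image(ri - rj)
    rkj = box.minimum_image(rk - rj)
    nij = np.linalg.norm(rij, axis=1)
    nkj = np.linalg.norm(rkj, axis=1)
    cth = np.clip(np.sum(rij * rkj, axis=1) / (nij * nkj), -1.0, 1.0)
    dcos = cth - np.cos(theta0)
    energy = 0.5 * float(np.sum(ka * dcos**2))
    dU = (ka * dcos)[:, None]  # dU/dcos
    # grad_i cos = rkj/(nij nkj) - cos * rij/nij^2 ; grad_k symmetric
    gi = rkj / (nij * nkj)[:, None] - cth[:, None] * rij / (nij**2)[:, None]
    gk = rij / (nij * nkj)[:, None] - cth[:, None] * rkj / (nkj**2)[:, None]
    fi = -dU * gi
    fk = -dU * gk
    fj = -(fi + fk)
    np.add.at(forces, idx[:, 0], fi)
    np.add.at(forces, idx[:, 1], fj)
    np.add.at(forces, idx[:, 2], fk)
    per = rij * fi + rkj * fk
    virial = per.sum(axis=0)
    if per_interaction:
        return energy, forces, virial, per
    return energy, forces, virial
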