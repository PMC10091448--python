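"""Per-axis internal pressure: kinetic, bonded and field contributions.

The field part of the diagonal pressure tensor follows from differentiating
the interaction energy W with respect to one box length at fixed fractional
coordinates.  Because the Gaussian filter acts in Fourier space, its
transfer function depends on the box lengths through the wave vectors, and
the derivative picks up a per-axis term proportional to sigma^2 times the
axis-resolved second derivative of the filtered density:

    P_a V = -W + sum_cells dV sum_t (dw/dphi_t) (phi_t + sigma_t^2 d2phi_t/da2)

The first two pieces are isotropic; the last is the anisotropic (Laplacian)
term that vanishes in homogeneous systems but generates normal/lateral
pressure imbalance at interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bonded as _bonded
from .field import DensityField, _k_vectors, build_density_field, dw_dphi, gaussian_filter_grid
from .model import BAR_PER_KJ_NM3, FieldParams, ParticleState, SimulationBox, Topology

__all__ = [
    "PressureDecomposition",
    "kinetic_pressure",
    "filtered_potential",
    "field_pressure",
    "total_pressure",
    "lateral_pressure_profile",
]


@dataclass
class PressureDecomposition:
    """Diagonal pressure components per Cartesian axis, in bar."""

    kinetic: np.ndarray
    bond: np.ndarray
    angle: np.ndarray
    field_iso: np.ndarray
    field_aniso: np.ndarray

    @property
    def per_axis(self) -> np.ndarray:
        return self.kinetic + self.bond + self.angle + self.field_iso + self.field_aniso

    @property
    def scalar(self) -> float:
        return float(self.per_axis.mean())

    def lateral_normal(self, normal_axis: int = 2):
        lat = [a for a in range(3) if a != normal_axis]
        p = self.per_axis
        return 0.5 * (p[lat[0]] + p[lat[1]]), p[normal_axis]


def kinetic_pressure(state: ParticleState, box: SimulationBox) -> np.ndarray:
    """2 T_a / V per axis, in bar."""
    twice_t = np.sum(state.masses[:, None] * state.velocities**2, axis=0)
    return twice_t / box.volume * BAR_PER_KJ_NM3


def filtered_potential(
    density: DensityField, params: FieldParams, box: SimulationBox
) -> np.ndarray:
    """Filtered potential grids: the Gaussian-filtered dw/dphi_t (kJ/mol)."""
    dwd = dw_dphi(density, params)
    return np.stack(
        [gaussian_filter_grid(dwd[t], params.sigma[t], box) for t in range(dwd.shape[0])]
    )


def _second_derivative(density: DensityField, box: SimulationBox, axis: int) -> np.ndarray:
    """Spectral d^2 phi_t / d a^2 for every type, from cached transforms."""
    kx, ky, kz = _k_vectors(box, density.mesh_shape)
    ka2 = (kx, ky, kz)[axis] ** 2
    return np.stack(
        [
            np.fft.irfftn(-ka2 * density.grids_k[t], s=density.mesh_shape, axes=(0, 1, 2))
            for t in range(density.grids.shape[0])
        ]
    )


def field_pressure(
    density: DensityField,
    params: FieldParams,
    box: SimulationBox,
    W: float | None = None,
):
    """Per-axis field pressure in bar, split into isotropic and anisotropic parts."""
    from .field import interaction_energy

    if density.grids.shape[1:] != tuple(density.mesh_shape):
        raise RuntimeError("density grids inconsistent with mesh shape")
    if W is None:
        W = interaction_energy(density, params)
    dwd = dw_dphi(density, params)
    V = box.volume
    dV = density.cell_volume
    iso_val = (-W + dV * float(np.sum(dwd * density.grids))) / V
    iso = np.full(3, iso_val * BAR_PER_KJ_NM3)
    aniso = np.empty(3)
    sig2 = params.sigma[:, None, None, None] ** 2
    for axis in range(3):
        d2 = _second_derivative(density, box, axis)
        aniso[axis] = dV * float(np.sum(dwd * sig2 * d2)) / V * BAR_PER_KJ_NM3
    return iso, aniso


def total_pressure(
    state: ParticleState,
    box: SimulationBox,
    topology: Topology | None = None,
    params: FieldParams | None = None,
    density: DensityField | None = None,
) -> PressureDecomposition:
    """Assemble the full per-axis pressure decomposition for one configuration."""
    kin = kinetic_pressure(state, box)
    zero = np.zeros(3)
    bond = zero.copy()
    angle = zero.copy()
    if topology is not None:
        idx, r0, kb = topology.bond_arrays()
        if len(idx):
            _, _, vir = _bonded.bond_energy_forces(state.positions, box, idx, r0, kb)
            bond = vir / box.volume * BAR_PER_KJ_NM3
        aidx, th0, ka = topology.angle_arrays()
        if len(aidx):
            _, _, avir = _bonded.angle_energy_forces(state.positions, box, aidx, th0, ka)
            angle = avir / box.volume * BAR_PER_KJ_NM3
    if params is not None:
        if density is None:
            density = build_density_field(state, box, params)
        iso, aniso = field_pressure(density, params, box)
    else:
        iso, aniso = zero.copy(), zero.copy()
    return PressureDecomposition(kin, bond, angle, iso, aniso)


def lateral_pressure_profile(
    frames,
    topology: Topology | None,
    params: FieldParams | None,
    axis: int = 2,
    n_slabs: int = 50,
):
    """Slab-resolved normal-minus-lateral pressure profile, frame averaged.

    ``frames`` iterates over (ParticleState, SimulationBox) pairs.  Field
    contributions come from the local integrand of the field pressure
    restricted to each slab; kinetic terms from the particles in the slab;
    bonded virials are attributed to the slab containing the interaction
    midpoint (Harasima-like convention), which keeps the profile integral
    consistent with the global tensor.

    Returns a dict with slab centers ``z`` (nm) and per-slab Delta P = P_N -
    P_L (bar) for field, kinetic, bond, angle and total contributions.
    """
    if n_slabs < 4:
        raise ValueError("n_slabs must be at least 4")
    lat = [a for a in range(3) if a != axis]
    acc = {k: np.zeros(n_slabs) for k in ("field", "kinetic", "bond", "angle")}
    n_frames = 0
    L_axis = None
    for state, box in frames:
        n_frames += 1
        L = box.lengths[axis]
        L_axis = L
        slab_vol = box.volume / n_slabs

        # kinetic: m v_a^2 per particle into its slab
        sl = np.clip((state.positions[:, axis] / L * n_slabs).astype(int), 0, n_slabs - 1)
        mv2 = state.masses[:, None] * state.velocities**2
        dmv2 = mv2[:, axis] - 0.5 * (mv2[:, lat[0]] + mv2[:, lat[1]])
        acc["kinetic"] += np.bincount(sl, weights=dmv2, minlength=n_slabs) / slab_vol * BAR_PER_KJ_NM3

        if topology is not None:
            for kind in ("bond", "angle"):
                if kind == "bond":
                    idx, r0, kb = topology.bond_arrays()
                    if not len(idx):
                        continue
                    _, _, _, per = _bonded.bond_energy_forces(
                        state.positions, box, idx, r0, kb, per_interaction=True
                    )
                    mid = state.positions[idx[:, 0]] + 0.5 * box.minimum_image(
                        state.positions[idx[:, 1]] - state.positions[idx[:, 0]]
                    )
                else:
                    aidx, th0, ka = topology.angle_arrays()
                    if not len(aidx):
                        continue
                    _, _, _, per = _bonded.angle_energy_forces(
                        state.positions, box, aidx, th0, ka, per_interaction=True
                    )
                    mid = state.positions[aidx[:, 1]]
                zmid = np.mod(mid[:, axis], L)
                slb = np.clip((zmid / L * n_slabs).astype(int), 0, n_slabs - 1)
                dvir = per[:, axis] - 0.5 * (per[:, lat[0]] + per[:, lat[1]])
                acc[kind] += (
                    np.bincount(slb, weights=dvir, minlength=n_slabs) / slab_vol * BAR_PER_KJ_NM3
                )

        if params is not None:
            density = build_density_field(state, box, params)
            dwd = dw_dphi(density, params)
            from .field import interaction_energy

            phi = density.grids
            total = phi.sum(axis=0)
            w_local = (
                0.5 * np.einsum("lxyz,lm,mxyz->xyz", phi, params.chi, phi)
                + 0.5 * (total - params.a) ** 2 / params.kappa
            ) / params.rho0
            sig2 = params.sigma[:, None, None, None] ** 2
            p_ax = {}
            for a in range(3):
                d2 = _second_derivative(density, box, a)
                p_ax[a] = -w_local + np.sum(dwd * (phi + sig2 * d2), axis=0)
            dp_cell = p_ax[axis] - 0.5 * (p_ax[lat[0]] + p_ax[lat[1]])
            # collapse mesh cells onto slabs along the profile axis
            n_mesh = density.mesh_shape[axis]
            plane = dp_cell.sum(axis=tuple(a for a in range(3) if a != axis))
            zc = (np.arange(n_mesh) + 0.5) * L / n_mesh
            slb = np.clip((zc / L * n_slabs).astype(int), 0, n_slabs - 1)
            acc["field"] += (
                np.bincount(slb, weights=plane, minlength=n_slabs)
                * density.cell_volume
                / slab_vol
                * BAR_PER_KJ_NM3
            )

    if n_frames == 0:
        raise ValueError("no frames supplied")
    for k in acc:
        acc[k] /= n_frames
    z = (np.arange(n_slabs) + 0.5) * L_axis / n_slabs
    total = acc["field"] + acc["kinetic"] + acc["bond"] + acc["angle"]
    return {
        "z": z,
        "dP_field": acc["field"],
        "dP_kinetic": acc["kinetic"],
        "dP_bond": acc["bond"],
        "dP_angle": acc["angle"],
        "dP_total": total,
        "dz": L_axis / n_slabs,
    }
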