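import numpy as np
import pytest

from conftest import make_random_system
from pfmd.field import (
    DensityField,
    assign_densities,
    build_density_field,
    external_potential,
    field_forces,
    gaussian_filter_grid,
    interaction_energy,
)
from pfmd.model import FieldParams, ParticleState, SimulationBox


def _single_particle_state(pos, box, type_names=("W",)):
    return ParticleState(
        np.asarray([pos]), np.zeros((1, 3)), [0], [72.0], [0], list(type_names)
    )


def _uniform_density(value_per_type, mesh_shape, box):
    """Hand-built DensityField with spatially uniform per-type grids."""
    vals = np.atleast_1d(np.asarray(value_per_type, dtype=float))
    grids = np.broadcast_to(
        vals[:, None, None, None], (len(vals),) + tuple(mesh_shape)
    ).copy()
    gk = np.stack([np.fft.rfftn(g) for g in grids])
    cellvol = box.volume / np.prod(mesh_shape)
    return DensityField(grids, grids.copy(), gk, cellvol, tuple(mesh_shape))


class TestCloudInCell:
    def test_particle_on_node_gets_full_weight(self):
        box = SimulationBox([4.0, 4.0, 4.0])
        mesh = (8, 8, 8)
        h = 0.5
        state = _single_particle_state([2 * h, 3 * h, 5 * h], box)
        grid = assign_densities(state, box, mesh)
        cellvol = h**3
        assert grid[0, 2, 3, 5] * cellvol == pytest.approx(1.0)
        assert grid.sum() * cellvol == pytest.approx(1.0)
        assert np.count_nonzero(grid) == 1

    def test_cell_center_spreads_eighth_weight(self):
        box = SimulationBox([4.0, 4.0, 4.0])
        state = _single_particle_state([0.75, 0.75, 0.75], box)  # center of a cell
        grid = assign_densities(state, box, (8, 8, 8))
        nz = grid[grid > 0]
        assert len(nz) == 8
        assert np.allclose(nz * 0.5**3, 0.125)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_deposition_conserves_type_counts(self, seed):
        state, box, params = make_random_system(seed=seed, n=60, n_types=3,
                                                mesh_shape=(12, 16, 20))
        grid = assign_densities(state, box, params.mesh_shape)
        cellvol = box.volume / np.prod(params.mesh_shape)
        assert np.allclose(
            grid.sum(axis=(1, 2, 3)) * cellvol, state.type_counts(), rtol=1e-12
        )

    def test_unwrapped_positions_rejected(self):
        box = SimulationBox([4.0, 4.0, 4.0])
        state = _single_particle_state([5.0, 1.0, 1.0], box)
        with pytest.raises(RuntimeError):
            assign_densities(state, box, (8, 8, 8))


class TestGaussianFilter:
    def test_uniform_grid_unchanged(self):
        box = SimulationBox([3.0, 3.0, 3.0])
        g = np.full((8, 8, 8), 2.7)
        assert np.allclose(gaussian_filter_grid(g, 0.5, box), g, rtol=1e-13)

    def test_vanishing_sigma_is_identity(self, rng):
        box = SimulationBox([3.0, 3.0, 3.0])
        g = rng.standard_normal((12, 12, 12))
        assert np.allclose(gaussian_filter_grid(g, 1e-6, box), g, atol=1e-10)

    def test_impulse_matches_direct_periodic_convolution(self):
        # oracle: real-space periodic sum of the continuum Gaussian kernel
        box = SimulationBox([6.4, 6.4, 6.4])
        n = 32
        sigma = 0.4
        g = np.zeros((n, n, n))
        g[5, 7, 9] = 1.0
        filt = gaussian_filter_grid(g, sigma, box)
        h = box.lengths[0] / n
        coords = np.arange(n) * h
        images = np.arange(-2, 3) * box.lengths[0]

        def axis_kernel(x0):
            d = coords[:, None] - x0 + images[None, :]
            return np.exp(-(d**2) / (2 * sigma**2)).sum(axis=1)

        kx, ky, kz = axis_kernel(5 * h), axis_kernel(7 * h), axis_kernel(9 * h)
        direct = (
            kx[:, None, None] * ky[None, :, None] * kz[None, None, :]
            / (2 * np.pi * sigma**2) ** 1.5
            * h**3  # discrete convolution quadrature
        )
        assert np.allclose(filt, direct, atol=1e-8 * direct.max())

    def test_filter_conserves_mass(self, rng):
        box = SimulationBox([5.0, 4.0, 3.0])
        g = rng.uniform(0, 1, (16, 12, 8))
        f = gaussian_filter_grid(g, 0.7, box)
        assert f.sum() == pytest.approx(g.sum(), rel=1e-12)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            gaussian_filter_grid(np.zeros((4, 4, 4)), -0.1, SimulationBox([1, 1, 1]))


class TestInteractionEnergy:
    def test_zero_at_reference_density(self):
        box = SimulationBox([2.0, 2.0, 2.0])
        params = FieldParams(chi=[[0.0]], kappa=0.05, a=9.21)
        d = _uniform_density([9.21], (8, 8, 8), box)
        assert interaction_energy(d, params) == pytest.approx(0.0, abs=1e-10)

    def test_incompressibility_term_closed_form(self):
        # single type, uniform phi = a + delta: W = V * delta^2 / (2 kappa rho0)
        box = SimulationBox([2.0, 3.0, 4.0])
        params = FieldParams(chi=[[0.0]], kappa=0.05, a=9.21, rho0=8.364)
        delta = 0.37
        d = _uniform_density([9.21 + delta], (8, 8, 8), box)
        expected = box.volume * delta**2 / (2 * params.kappa * params.rho0)
        assert interaction_energy(d, params) == pytest.approx(expected, rel=1e-12)

    def test_mixing_term_closed_form(self):
        # two types at uniform densities with chi_AB = 36 kJ/mol
        box = SimulationBox([2.0, 2.0, 2.0])
        params = FieldParams(chi=[[0.0, 36.0], [36.0, 0.0]], kappa=0.05, a=9.21,
                             rho0=8.364)
        pa, pb = 3.1, 6.11  # sums to a: incompressibility term vanishes
        d = _uniform_density([pa, pb], (8, 8, 8), box)
        expected = box.volume * 36.0 * pa * pb / params.rho0
        assert interaction_energy(d, params) == pytest.approx(expected, rel=1e-12)

    def test_type_count_mismatch_raises(self):
        box = SimulationBox([2.0, 2.0, 2.0])
        params = FieldParams(chi=[[0.0]], kappa=0.05, a=9.21)
        d = _uniform_density([1.0, 2.0], (8, 8, 8), box)
        with pytest.raises(ValueError):
            interaction_energy(d, params)


class TestExternalPotential:
    def test_uniform_density_gives_uniform_potential_zero_gradient(self):
        box = SimulationBox([3.0, 3.0, 3.0])
        params = FieldParams(chi=[[0.0]], kappa=0.05, a=9.21, rho0=8.364)
        delta = 0.5
        d = _uniform_density([9.21 + delta], (8, 8, 8), box)
        pot = external_potential(d, params, box)
        expected = delta / (params.kappa * params.rho0)
        assert np.allclose(pot.v[0], expected, rtol=1e-12)
        assert np.abs(pot.gradients).max() < 1e-12

    def test_zero_at_reference_density(self):
        box = SimulationBox([3.0, 3.0, 3.0])
        params = FieldParams(chi=[[0.0]], kappa=0.05, a=9.21)
        d = _uniform_density([9.21], (8, 8, 8), box)
        pot = external_potential(d, params, box)
        assert np.abs(pot.v).max() < 1e-12

    def test_gradient_grids_are_mean_free(self):
        state, box, params = make_random_system(seed=3)
        d = build_density_field(state, box, params)
        pot = external_potential(d, params, box)
        assert np.abs(pot.gradients.mean(axis=(2, 3, 4))).max() < 1e-12

    def test_functional_derivative_matches_energy_perturbation(self):
        # perturb one node of phi_t by delta and compare dW with dw/dphi * dV
        state, box, params = make_random_system(seed=4, n=30)
        d = build_density_field(state, box, params)
        from pfmd.field import dw_dphi

        dwd = dw_dphi(d, params)
        delta = 1e-6
        w0 = interaction_energy(d, params)
        pert = d.grids.copy()
        pert[1, 3, 4, 5] += delta
        d2 = DensityField(pert, d.raw, d.grids_k, d.cell_volume, d.mesh_shape)
        w1 = interaction_energy(d2, params)
        assert (w1 - w0) / (delta * d.cell_volume) == pytest.approx(
            dwd[1, 3, 4, 5], rel=1e-4
        )


class TestFieldForces:
    def test_uniform_lattice_has_no_forces(self):
        # one particle per mesh node: the filtered density is exactly uniform
        box = SimulationBox([4.0, 4.0, 4.0])
        m = 8
        g = np.arange(m) * (4.0 / m)
        lat = np.array(np.meshgrid(g, g, g, indexing="ij")).reshape(3, -1).T
        state = ParticleState(lat, np.zeros_like(lat), np.zeros(len(lat), int),
                              np.full(len(lat), 72.0), np.arange(len(lat)), ["W"])
        params = FieldParams(chi=[[0.0]], kappa=0.05, a=9.21, sigma=0.4,
                             mesh_shape=(m, m, m))
        d = build_density_field(state, box, params)
        pot = external_potential(d, params, box)
        for method in ("cic-grad", "spectral"):
            f = field_forces(pot, state, box, method=method)
            assert np.abs(f).max() < 1e-6

    def test_spectral_forces_conserve_momentum_exactly(self):
        state, box, params = make_random_system(seed=5, n=50)
        d = build_density_field(state, box, params)
        pot = external_potential(d, params, box)
        f = field_forces(pot, state, box, method="spectral")
        assert np.abs(f.sum(axis=0)).max() < 1e-9 * np.abs(f).max() * len(f)

    def test_forces_match_central_difference_of_energy(self):
        state, box, params = make_random_system(seed=6, n=25)
        d = build_density_field(state, box, params)
        pot = external_potential(d, params, box)
        f = field_forces(pot, state, box)
        eps = 1e-6
        for i in (0, 7, 19):
            for a in range(3):
                w = []
                for s in (+eps, -eps):
                    p = state.positions.copy()
                    p[i, a] += s
                    st2 = ParticleState(box.wrap(p), state.velocities, state.types,
                                        state.masses, state.molecule, state.type_names)
                    w.append(interaction_energy(build_density_field(st2, box, params), params))
                fd = -(w[0] - w[1]) / (2 * eps)
                assert f[i, a] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    @pytest.mark.parametrize("dist", [0.3, 0.5, 0.8])
    def test_two_particle_force_matches_gaussian_pair_potential(self, dist):
        # the filtered-density model is equivalent to particles interacting
        # through a Gaussian pair kernel; on the mesh the kernel variance is
        # 2 sigma^2 plus the assignment windows' h^2/3 per axis (vanishing
        # under mesh refinement).  Averaging over sub-cell offsets removes
        # the positional aliasing ripple.
        box = SimulationBox([5.0, 5.0, 5.0])
        sigma = 0.238
        chi_ab = 36.0
        mesh = 64
        params = FieldParams(chi=[[0.0, chi_ab], [chi_ab, 0.0]], kappa=0.05,
                             a=9.21, rho0=8.364, sigma=sigma,
                             mesh_shape=(mesh, mesh, mesh))
        c = (chi_ab + 1.0 / params.kappa) / params.rho0
        h = box.lengths[0] / mesh
        veff = 2 * sigma**2 + h**2 / 3
        rng = np.random.default_rng(0)
        measured = []
        for _ in range(48):
            origin = rng.uniform(1.5, 3.5, 3)
            pos = box.wrap(np.array([origin, origin + [dist, 0.0, 0.0]]))
            state = ParticleState(pos, np.zeros((2, 3)), [0, 1], [72.0, 72.0],
                                  [0, 1], ["A", "B"])
            d = build_density_field(state, box, params)
            pot = external_potential(d, params, box)
            f = field_forces(pot, state, box)
            measured.append(-f[0, 0])  # repulsion pushes A away from B
        analytic = (
            c * (2 * np.pi * veff) ** -1.5
            * dist / veff * np.exp(-(dist**2) / (2 * veff))
        )
        continuum = (
            c * (4 * np.pi * sigma**2) ** -1.5
            * dist / (2 * sigma**2) * np.exp(-(dist**2) / (4 * sigma**2))
        )
        assert np.mean(measured) == pytest.approx(analytic, rel=1.5e-2)
        assert np.mean(measured) == pytest.approx(continuum, rel=7e-2)


class TestFieldInvariants:
    @pytest.mark.parametrize("seed", [0, 3, 8])
    def test_filtering_conserves_mass(self, seed):
        state, box, params = make_random_system(seed=seed, n=45, n_types=3)
        d = build_density_field(state, box, params)
        assert np.allclose(d.type_masses(), state.type_counts(), rtol=1e-10)
        assert d.grids.min() > -1e-8 * d.grids.max()

    def test_translation_by_one_cell_preserves_energy(self):
        state, box, params = make_random_system(seed=9, n=30, mesh_shape=(16, 16, 16))
        d = build_density_field(state, box, params)
        w0 = interaction_energy(d, params)
        cell = box.lengths / np.array(params.mesh_shape)
        shifted = ParticleState(
            box.wrap(state.positions + cell), state.velocities, state.types,
            state.masses, state.molecule, state.type_names,
        )
        w1 = interaction_energy(build_density_field(shifted, box, params), params)
        assert w1 == pytest.approx(w0, rel=1e-10)
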