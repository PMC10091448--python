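"""Time integration and temperature/pressure control.

Integration uses the reversible multiple-time-step (rRESPA) scheme: slowly
varying field forces are applied at the outer step dt1, bonded forces at
the inner step dt2.  Temperature is controlled by the canonical sampling
through velocity rescaling (CSVR) thermostat; pressure by a Berendsen or a
stochastic cell rescaling (SCR) barostat with isotropic, semi-isotropic or
constant-area coupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as _field

import numpy as np

from . import bonded as _bonded
from .field import build_density_field, external_potential, field_forces, interaction_energy
from .model import (
    BAR_PER_KJ_NM3,
    KB,
    FieldParams,
    IntegratorParams,
    ParticleState,
    SimulationBox,
    ThermoBaroParams,
    Topology,
)
from .pressure import PressureDecomposition, total_pressure

__all__ = [
    "csvr_rescale",
    "berendsen_scale",
    "scr_scale",
    "Simulation",
    "run_simulation",
]


def csvr_rescale(K, n_dof, T_target, tau, dt, rng, noise: bool = True) -> float:
    """CSVR velocity scale factor for one step of length dt.

    Deterministic relaxation of the kinetic energy toward its canonical
    mean plus a stochastic term reproducing the canonical kinetic-energy
    (Gamma) distribution.  With ``noise=False`` the update reduces to a
    Berendsen-style deterministic rescaling.
    """
    if K <= 0:
        raise ValueError("kinetic energy must be positive")
    if n_dof < 1:
        raise ValueError("n_dof must be >= 1")
    Kbar = 0.5 * n_dof * KB * T_target
    c = np.exp(-dt / tau)
    if not noise:
        alpha2 = c + (1.0 - c) * Kbar / K
        return float(np.sqrt(alpha2))
    r1 = rng.standard_normal()
    sum_r2 = rng.chisquare(n_dof - 1) if n_dof > 1 else 0.0
    ratio = Kbar / (n_dof * K)
    alpha2 = (
        c
        + (1.0 - c) * ratio * (r1**2 + sum_r2)
        + 2.0 * r1 * np.sqrt(c * (1.0 - c) * ratio)
    )
    return float(np.sqrt(max(alpha2, 1e-12)))


def _pressure_groups(P_axis: np.ndarray, mode: str):
    """Coupling groups: (axes, group pressure) per barostat mode."""
    if mode == "isotropic":
        return [((0, 1, 2), float(np.mean(P_axis)))]
    if mode == "semi-isotropic":
        return [((0, 1), 0.5 * (P_axis[0] + P_axis[1])), ((2,), float(P_axis[2]))]
    if mode == "constant-area":
        return [((2,), float(P_axis[2]))]
    raise ValueError(f"unknown coupling mode {mode!r}")


def _clamp(mu: float) -> float:
    if mu < 0.95 or mu > 1.05:
        warnings.warn(f"barostat scale factor {mu:.4f} clamped to [0.95, 1.05]", stacklevel=3)
        return float(np.clip(mu, 0.95, 1.05))
    return mu


def berendsen_scale(P_axis, params: ThermoBaroParams, dt: float) -> np.ndarray:
    """Per-axis Berendsen box scale factors mu_a (dimensionless).

    mu = [1 - (dt/tau_P) beta (P_target - P)]^(1/3) per coupling group,
    with P in bar.  Factors outside [0.95, 1.05] are clamped with a warning.
    """
    mu = np.ones(3)
    for axes, P in _pressure_groups(np.asarray(P_axis, dtype=float), params.mode):
        m = _clamp((1.0 - dt / params.tau_p * params.beta * (params.pressure - P)) ** (1.0 / 3.0))
        for a in axes:
            mu[a] = m
    return mu


def scr_scale(
    P_axis,
    params: ThermoBaroParams,
    dt: float,
    volume: float,
    rng,
    noise: bool = True,
) -> np.ndarray:
    """Per-axis stochastic cell rescaling factors.

    The log-volume of each coupling group relaxes deterministically toward
    the target pressure (Berendsen-like, first order in dt) and receives a
    Wiener increment with variance 2 k_B T beta dt / (V tau_P), which makes
    the sampled volume distribution canonical in the NPT ensemble.
    """
    beta_int = params.beta * BAR_PER_KJ_NM3  # (kJ/mol/nm^3)^-1
    kt = KB * params.temperature
    mu = np.ones(3)
    for axes, P in _pressure_groups(np.asarray(P_axis, dtype=float), params.mode):
        w = len(axes) / 3.0
        deps = -w * (params.beta / params.tau_p) * (params.pressure - P) * dt
        if noise:
            var = 2.0 * kt * beta_int * w * dt / (volume * params.tau_p)
            deps += np.sqrt(var) * rng.standard_normal()
        m = _clamp(float(np.exp(deps / len(axes))))
        for a in axes:
            mu[a] = m
    return mu


@dataclass
class Simulation:
    """One MD system with its integrator and (optional) thermo-/barostat.

    ``step()`` advances one outer rRESPA step: field half-kick, nested
    bonded velocity-Verlet loop, field half-kick, then CSVR rescaling and
    the barostat update.  Diagnostics are accumulated per outer step.
    """

    state: ParticleState
    box: SimulationBox
    topology: Topology | None = None
    field_params: FieldParams | None = None
    integrator: IntegratorParams = _field(default_factory=IntegratorParams)
    thermo: ThermoBaroParams | None = None
    seed: int = 0
    force_method: str = "cic-grad"
    remove_net_force: bool = True
    thermostat_on: bool = True
    #: evaluate the pressure decomposition at every outer step
    compute_pressure: bool = True

    def __post_init__(self):
        self.rng = np.random.default_rng(self.seed)
        self.step_count = 0
        self.time = 0.0
        # COM momentum is removed at initialization and never re-zeroed
        self.n_dof = 3 * self.state.n - 3 if self.state.n > 1 else 3
        self.diagnostics = {
            k: []
            for k in (
                "time",
                "temperature",
                "kinetic",
                "field_energy",
                "bond_energy",
                "angle_energy",
                "volume",
                "box",
                "pressure",
                "pressure_axis",
            )
        }
        self._type_counts0 = self.state.type_counts().copy()
        self._bond_cache = self.topology.bond_arrays() if self.topology else None
        self._angle_cache = self.topology.angle_arrays() if self.topology else None
        self._field_eval()

    # -- force evaluations -------------------------------------------------
    def _field_eval(self):
        if self.field_params is None:
            self._density = None
            self._W = 0.0
            self._f_field = np.zeros((self.state.n, 3))
            return
        self._density = build_density_field(self.state, self.box, self.field_params)
        pot = external_potential(self._density, self.field_params, self.box, with_gradients=False)
        self._W = interaction_energy(self._density, self.field_params)
        f = field_forces(pot, self.state, self.box, method=self.force_method)
        if self.remove_net_force:
            f -= f.mean(axis=0)
        self._f_field = f

    def _bonded_eval(self):
        n = self.state.n
        f = np.zeros((n, 3))
        eb = ea = 0.0
        if self._bond_cache is not None and len(self._bond_cache[0]):
            idx, r0, kb = self._bond_cache
            eb, fb, _ = _bonded.bond_energy_forces(self.state.positions, self.box, idx, r0, kb)
            f += fb
        if self._angle_cache is not None and len(self._angle_cache[0]):
            aidx, th0, ka = self._angle_cache
            ea, fa, _ = _bonded.angle_energy_forces(self.state.positions, self.box, aidx, th0, ka)
            f += fa
        self._e_bond, self._e_angle = eb, ea
        return f

    # -- observables -------------------------------------------------------
    def temperature(self) -> float:
        return 2.0 * self.state.kinetic_energy() / (self.n_dof * KB)

    def pressure(self) -> PressureDecomposition:
        return total_pressure(
            self.state, self.box, self.topology, self.field_params, density=self._density
        )

    def potential_energy(self) -> float:
        self._bonded_eval()
        return self._W + self._e_bond + self._e_angle

    # -- integration -------------------------------------------------------
    def step(self):
        st = self.state
        dt1 = self.integrator.dt_outer
        dt2 = self.integrator.dt_inner
        inv_m = 1.0 / st.masses[:, None]

        st.velocities += 0.5 * dt1 * self._f_field * inv_m
        has_bonded = (self._bond_cache is not None and len(self._bond_cache[0])) or (
            self._angle_cache is not None and len(self._angle_cache[0])
        )
        if has_bonded:
            f_b = self._bonded_eval()
            for _ in range(self.integrator.n_inner):
                st.velocities += 0.5 * dt2 * f_b * inv_m
                st.positions[:] = self.box.wrap(st.positions + dt2 * st.velocities)
                f_b = self._bonded_eval()
                st.velocities += 0.5 * dt2 * f_b * inv_m
        else:
            st.positions[:] = self.box.wrap(st.positions + dt1 * st.velocities)
            self._e_bond = self._e_angle = 0.0
        self._field_eval()
        st.velocities += 0.5 * dt1 * self._f_field * inv_m

        pres = self.pressure() if self.compute_pressure else None
        if self.thermo is not None:
            if self.thermostat_on:
                alpha = csvr_rescale(
                    st.kinetic_energy(),
                    self.n_dof,
                    self.thermo.temperature,
                    self.thermo.tau_t,
                    dt1,
                    self.rng,
                )
                st.velocities *= alpha
            if self.thermo.barostat != "none":
                if pres is None:
                    pres = self.pressure()
                if self.thermo.barostat == "berendsen":
                    mu = berendsen_scale(pres.per_axis, self.thermo, dt1)
                else:
                    mu = scr_scale(pres.per_axis, self.thermo, dt1, self.box.volume, self.rng)
                if not np.all(mu == 1.0):
                    self.box = self.box.scale(mu)
                    st.positions[:] = self.box.wrap(st.positions * mu)
                    self._field_eval()

        self.step_count += 1
        self.time += dt1
        assert np.array_equal(st.type_counts(), self._type_counts0), "type counts changed"
        self._record(pres)

    def _record(self, pres):
        d = self.diagnostics
        d["time"].append(self.time)
        d["temperature"].append(self.temperature())
        d["kinetic"].append(self.state.kinetic_energy())
        d["field_energy"].append(self._W)
        d["bond_energy"].append(getattr(self, "_e_bond", 0.0))
        d["angle_energy"].append(getattr(self, "_e_angle", 0.0))
        d["volume"].append(self.box.volume)
        d["box"].append(self.box.lengths.copy())
        if pres is None:
            d["pressure"].append(np.nan)
            d["pressure_axis"].append(np.full(3, np.nan))
        else:
            d["pressure"].append(pres.scalar)
            d["pressure_axis"].append(pres.per_axis.copy())

    def run(self, n_outer: int, callback=None, callback_every: int = 1):
        for _ in range(n_outer):
            self.step()
            if callback is not None and self.step_count % callback_every == 0:
                callback(self)
        return self

    def diagnostics_arrays(self) -> dict:
        return {k: np.asarray(v) for k, v in self.diagnostics.items()}


def run_simulation(config, out_dir=None):
    """Run a config-driven simulation (see :mod:`pfmd.config`).

    Builds the system, integrates for the configured number of outer steps,
    and optionally writes an HDF5 trajectory plus a final GRO snapshot.
    Returns the :class:`Simulation` after the run.
    """
    from .config import simulation_from_config, writers_from_config

    sim = simulation_from_config(config)
    writer, finalize = writers_from_config(config, sim, out_dir)
    if writer is not None:
        writer(sim)  # initial frame
    n = int(config.n_steps)
    every = max(int(config.output_every), 1)
    if n > 0:
        sim.run(n, callback=writer, callback_every=every)
    finalize(sim)
    return sim
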