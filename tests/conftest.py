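import numpy as np
import pytest

from pfmd.builders import build_bilayer, default_field_params
from pfmd.dynamics import Simulation
from pfmd.model import FieldParams, ParticleState, SimulationBox, ThermoBaroParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_random_system(seed=0, n=40, n_types=2, box_lengths=(4.0, 5.0, 6.0),
                       sigma=0.5, chi=20.0, mesh_shape=(24, 30, 32)):
    """Small random multi-type system plus field parameters, for oracles."""
    rng = np.random.default_rng(seed)
    box = SimulationBox(box_lengths)
    pos = rng.uniform(0, 1, (n, 3)) * box.lengths
    types = rng.integers(0, n_types, n)
    state = ParticleState(
        pos,
        rng.standard_normal((n, 3)) * 0.1,
        types,
        np.full(n, 72.0),
        np.arange(n),
        [chr(ord("A") + i) for i in range(n_types)],
    )
    mat = np.full((n_types, n_types), float(chi))
    np.fill_diagonal(mat, 0.0)
    params = FieldParams(chi=mat, kappa=0.05, a=9.21, sigma=sigma, mesh_shape=mesh_shape)
    return state, box, params


@pytest.fixture(scope="session")
def mini_bilayer_frames():
    """Short NVT run of a miniature solvated bilayer; last frames kept.

    Session-scoped because several observables (profiles, tension,
    pressure-profile consistency) analyze the same trajectory.
    """
    state, top, box = build_bilayer(
        n_lipids=64, n_solvent=900, box_lengths=(5.8, 5.8, 10.0),
        temperature=323.0, seed=7,
    )
    params = default_field_params("bilayer")
    thermo = ThermoBaroParams(temperature=323.0, tau_t=0.1, barostat="none")
    sim = Simulation(state, box, topology=top, field_params=params,
                     thermo=thermo, seed=11)
    frames = []

    def keep(s):
        frames.append((s.state.copy(), s.box.copy()))

    sim.run(300)  # relax the constructed lattice
    sim.run(500, callback=keep, callback_every=10)
    return {"frames": frames, "topology": top, "params": params,
            "n_leaflet": 32, "sim": sim}
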