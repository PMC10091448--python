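"""HDF5 trajectory storage (H5MD-style groups) and frame iteration."""

from __future__ import annotations

import numpy as np

from .model import ParticleState, SimulationBox

__all__ = ["TrajectoryWriter", "read_trajectory", "iter_frames"]


class TrajectoryWriter:
    """Appends simulation frames to an HDF5 file.

    Layout: /particles/{positions,velocities}, /box/lengths, /step, /time,
    plus static /particles/{types,masses,molecule} and type names.
    """

    def __init__(self, path, state: ParticleState):
        import h5py

        self._h5 = h5py.File(path, "w")
        n = state.n
        p = self._h5.create_group("particles")
        p.create_dataset("positions", shape=(0, n, 3), maxshape=(None, n, 3), dtype="f8")
        p.create_dataset("velocities", shape=(0, n, 3), maxshape=(None, n, 3), dtype="f8")
        p.create_dataset("types", data=state.types)
        p.create_dataset("masses", data=state.masses)
        p.create_dataset("molecule", data=state.molecule)
        p.attrs["type_names"] = [str(t) for t in state.type_names]
        self._h5.create_dataset("box/lengths", shape=(0, 3), maxshape=(None, 3), dtype="f8")
        self._h5.create_dataset("step", shape=(0,), maxshape=(None,), dtype="i8")
        self._h5.create_dataset("time", shape=(0,), maxshape=(None,), dtype="f8")

    def append(self, sim):
        """Append the current frame of a Simulation (or (state, box, step, time))."""
        state, box = sim.state, sim.box
        step, time = sim.step_count, sim.time
        for name, value in (
            ("particles/positions", state.positions),
            ("particles/velocities", state.velocities),
            ("box/lengths", box.lengths),
            ("step", step),
            ("time", time),
        ):
            ds = self._h5[name]
            ds.resize(ds.shape[0] + 1, axis=0)
            ds[-1] = value
        self._h5.flush()

    __call__ = append

    def close(self):
        self._h5.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def read_trajectory(path) -> dict:
    import h5py

    with h5py.File(path, "r") as fh:
        return {
            "positions": fh["particles/positions"][...],
            "velocities": fh["particles/velocities"][...],
            "types": fh["particles/types"][...],
            "masses": fh["particles/masses"][...],
            "molecule": fh["particles/molecule"][...],
            "type_names": [
                t.decode() if isinstance(t, bytes) else str(t)
                for t in fh["particles"].attrs["type_names"]
            ],
            "box": fh["box/lengths"][...],
            "step": fh["step"][...],
            "time": fh["time"][...],
        }


def iter_frames(data):
    """Yield (ParticleState, SimulationBox) frames from a file or dict."""
    if not isinstance(data, dict):
        data = read_trajectory(data)
    for i in range(len(data["time"])):
        state = ParticleState(
            data["positions"][i],
            data["velocities"][i],
            data["types"],
            data["masses"],
            data["molecule"],
            data["type_names"],
        )
        yield state, SimulationBox(data["box"][i])
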