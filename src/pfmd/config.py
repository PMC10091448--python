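"""TOML run configuration, topology serialization and run orchestration."""

from __future__ import annotations

import os
import tomllib
from dataclasses import dataclass, field as _field

import numpy as np

from .builders import BuilderSpec
from .model import (
    AngleRecord,
    BondRecord,
    FieldParams,
    IntegratorParams,
    ThermoBaroParams,
    Topology,
)

__all__ = [
    "RunConfig",
    "load_config",
    "simulation_from_config",
    "writers_from_config",
    "read_topology",
    "write_topology",
]


@dataclass
class RunConfig:
    system: dict
    field: dict | None
    integrator: dict = _field(default_factory=dict)
    thermostat: dict | None = None
    barostat: dict | None = None
    output: dict = _field(default_factory=dict)
    n_steps: int = 0
    output_every: int = 1
    seed: int = 0


def load_config(path) -> RunConfig:
    """Parse a TOML run configuration with actionable error messages."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    if "system" not in raw:
        raise ValueError("config needs a [system] table (kind = homogeneous|binary|bilayer|gro)")
    return RunConfig(
        system=raw["system"],
        field=raw.get("field"),
        integrator=raw.get("integrator", {}),
        thermostat=raw.get("thermostat"),
        barostat=raw.get("barostat"),
        output=raw.get("output", {}),
        n_steps=int(raw.get("n_steps", 0)),
        output_every=int(raw.get("output_every", 1)),
        seed=int(raw.get("seed", 0)),
    )


def _field_params(cfg: RunConfig, n_types: int) -> FieldParams | None:
    f = cfg.field
    if f is None:
        return None
    chi = f.get("chi", 0.0)
    if np.isscalar(chi):
        mat = np.full((n_types, n_types), float(chi))
        np.fill_diagonal(mat, 0.0)
    else:
        mat = np.asarray(chi, dtype=float)
    kwargs = {}
    if "rho0" in f:
        kwargs["rho0"] = float(f["rho0"])
    if "mesh" in f:
        kwargs["mesh_shape"] = tuple(f["mesh"])
    return FieldParams(chi=mat, kappa=float(f.get("kappa", 0.05)),
                       a=float(f.get("a", 9.21)), sigma=f.get("sigma", 0.238), **kwargs)


def simulation_from_config(cfg: RunConfig):
    """Build a Simulation from a parsed RunConfig."""
    from .dynamics import Simulation

    sys_tbl = dict(cfg.system)
    kind = sys_tbl.pop("kind", "homogeneous")
    topology = None
    if kind == "gro":
        from .gro import read_gro

        state, box = read_gro(sys_tbl["path"], type_names=sys_tbl.get("type_names"))
        if "topology" in sys_tbl:
            topology = read_topology(sys_tbl["topology"])
    else:
        spec = BuilderSpec(
            kind=kind,
            counts=sys_tbl.get("counts", sys_tbl),
            box=tuple(sys_tbl.get("box", (5.2, 5.2, 5.2))),
            temperature=float(sys_tbl.get("temperature", 300.0)),
            area_per_lipid=sys_tbl.get("area_per_lipid"),
            n_tg=int(sys_tbl.get("n_tg", 0)),
            premixed=bool(sys_tbl.get("premixed", False)),
            seed=cfg.seed,
        )
        built = spec.build()
        if kind == "bilayer":
            state, topology, box = built
        else:
            state, box = built
    params = _field_params(cfg, state.n_types)
    thermo = None
    if cfg.thermostat is not None or cfg.barostat is not None:
        th = cfg.thermostat or {}
        ba = cfg.barostat or {}
        thermo = ThermoBaroParams(
            temperature=float(th.get("temperature", sys_tbl.get("temperature", 300.0))),
            tau_t=float(th.get("tau", 0.1)),
            pressure=float(ba.get("pressure", 1.0)),
            beta=float(ba.get("beta", 4.6e-5)),
            tau_p=float(ba.get("tau", 1.0)),
            barostat=ba.get("kind", "none"),
            mode=ba.get("mode", "isotropic"),
            seed=cfg.seed,
        )
    integ = IntegratorParams(
        dt_outer=float(cfg.integrator.get("dt_outer", 0.3)),
        dt_inner=float(cfg.integrator.get("dt_inner", 0.03)),
    )
    return Simulation(state, box, topology=topology, field_params=params,
                      integrator=integ, thermo=thermo, seed=cfg.seed)


def writers_from_config(cfg: RunConfig, sim, out_dir=None):
    """Trajectory/GRO writers per the [output] table; returns (writer, finalize)."""
    out = cfg.output
    base = out_dir or "."
    writer = None
    traj = None
    if out.get("trajectory"):
        from .trajectory import TrajectoryWriter

        traj = TrajectoryWriter(os.path.join(base, out["trajectory"]), sim.state)
        writer = traj.append

    def finalize(sim):
        if traj is not None:
            traj.close()
        if out.get("gro"):
            from .gro import write_gro

            write_gro(os.path.join(base, out["gro"]), sim.state, sim.box)

    return writer, finalize


def write_topology(path, topology: Topology):
    """Serialize a Topology to a plain-text TOML file (compact array form)."""
    idx, r0, kb = topology.bond_arrays()
    aidx, th0, ka = topology.angle_arrays()

    def arr(x, fmt="{}"):
        return "[" + ", ".join(fmt.format(v) for v in x) + "]"

    lines = []
    if topology.molecules:
        lines.append("[molecules]")
        for name, beads in topology.molecules.items():
            lines.append(f'{name} = [' + ", ".join(f'"{b}"' for b in beads) + "]")
        lines.append("")
    lines += [
        "[bonds]",
        f"i = {arr(idx[:, 0] if len(idx) else [])}",
        f"j = {arr(idx[:, 1] if len(idx) else [])}",
        f"r0 = {arr(r0, '{:.6g}')}",
        f"k = {arr(kb, '{:.6g}')}",
        "",
        "[angles]",
        f"i = {arr(aidx[:, 0] if len(aidx) else [])}",
        f"j = {arr(aidx[:, 1] if len(aidx) else [])}",
        f"k = {arr(aidx[:, 2] if len(aidx) else [])}",
        f"theta0 = {arr(th0, '{:.8g}')}",
        f"ka = {arr(ka, '{:.6g}')}",
        "",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_topology(path) -> Topology:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    top = Topology(molecules=raw.get("molecules", {}))
    b = raw.get("bonds", {})
    for i, j, r0, k in zip(b.get("i", []), b.get("j", []), b.get("r0", []), b.get("k", [])):
        top.bonds.append(BondRecord(int(i), int(j), float(r0), float(k)))
    a = raw.get("angles", {})
    for i, j, k, th0, ka in zip(a.get("i", []), a.get("j", []), a.get("k", []),
                                a.get("theta0", []), a.get("ka", [])):
        top.angles.append(AngleRecord(int(i), int(j), int(k), float(th0), float(ka)))
    return top
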