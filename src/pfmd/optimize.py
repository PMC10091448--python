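"""Parametrization machinery: EOS calibration and Bayesian optimization.

``calibrate_a`` tunes the equation-of-state offset a so that a homogeneous
NPT run reproduces the density of water.  ``bayes_opt`` is a batch-parallel
Gaussian-process optimizer with an upper-confidence-bound acquisition and
full data sharing between instances, used to fit type-mixing parameters
against reference density profiles through the SMAPE-based fitness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as _field

import numpy as np

from .builders import build_homogeneous
from .dynamics import Simulation
from .model import FieldParams, IntegratorParams, ThermoBaroParams

__all__ = [
    "FitnessSpec",
    "BOConfig",
    "smape_fitness",
    "calibrate_a",
    "bayes_opt",
    "BOResult",
]


@dataclass
class FitnessSpec:
    """Reference data for the profile-matching fitness."""

    ref_profiles: np.ndarray  # (n_types, n_bins), nm^-3
    ref_area_per_lipid: float = 0.63  # nm^2
    area_weight: float = 1.0

    def __post_init__(self):
        self.ref_profiles = np.atleast_2d(np.asarray(self.ref_profiles, dtype=float))
        if np.any(self.ref_profiles < 0):
            raise ValueError("reference profiles must be non-negative")


def smape_fitness(profiles, area_per_lipid: float, spec: FitnessSpec) -> float:
    """Symmetric mean absolute percentage error fitness.

    eta = sum_l mean_i [ 2 |phi_l(x_i) - ref_l(x_i)| / (phi_l + ref_l) ]
          + w (A_L - A_ref)^2

    The SMAPE term is scale-free per bin (fraction convention); bins where
    both profile and reference vanish contribute zero.
    """
    p = np.atleast_2d(np.asarray(profiles, dtype=float))
    if p.shape != spec.ref_profiles.shape:
        raise ValueError("profiles and reference are on different bins")
    r = spec.ref_profiles
    denom = p + r
    term = np.where(denom > 0, 2.0 * np.abs(p - r) / np.where(denom > 0, denom, 1.0), 0.0)
    eta = float(term.mean(axis=1).sum())
    eta += spec.area_weight * (area_per_lipid - spec.ref_area_per_lipid) ** 2
    return eta


def _npt_density(a, kappa, sigma, temperature, pressure, n, box_length, t_run,
                 t_equil, seed, mass=72.0):
    state, box = build_homogeneous(n=n, box_lengths=(box_length,) * 3,
                                   temperature=temperature, mass=mass, seed=seed)
    params = FieldParams(chi=[[0.0]], kappa=kappa, a=a, sigma=sigma)
    thermo = ThermoBaroParams(temperature=temperature, pressure=pressure,
                              tau_t=0.1, tau_p=1.0, barostat="berendsen")
    sim = Simulation(state, box, field_params=params, thermo=thermo, seed=seed + 1)
    integ = sim.integrator
    n_total = int(round(t_run / integ.dt_outer))
    n_equil = int(round(t_equil / integ.dt_outer))
    sim.run(n_total)
    vol = np.asarray(sim.diagnostics["volume"][n_equil:])
    mass_total = float(np.sum(state.masses))
    return float(np.mean(mass_total / 602.214 / vol))  # g/cm^3


def calibrate_a(
    kappa: float = 0.05,
    sigma: float = 0.238,
    temperature: float = 300.0,
    pressure: float = 1.0,
    target_density: float = 1.0,
    n: int = 1171,
    box_length: float = 5.2,
    t_run: float = 1000.0,
    t_equil: float = 100.0,
    bracket=(8.5, 10.0),
    a0: float | None = None,
    tol_density: float = 0.002,
    tol_a: float = 0.01,
    seed: int = 0,
    verbose: bool = False,
):
    """Calibrate a (nm^-3) so NPT density equals ``target_density`` g/cm^3.

    Each evaluation is a seeded homogeneous NPT run of duration ``t_run``
    (ps); the root in a is found by bisection (density is monotonically
    increasing in a).  If ``a0`` is supplied and already yields the target
    density within ``tol_density``, it is returned unchanged.
    """

    def density_at(a):
        rho = _npt_density(a, kappa, sigma, temperature, pressure, n, box_length,
                           t_run, t_equil, seed)
        if verbose:
            print(f"  a = {a:.4f} -> rho = {rho:.5f} g/cm^3")
        return rho

    history = []
    if a0 is not None:
        rho0 = density_at(a0)
        history.append((a0, rho0))
        if abs(rho0 - target_density) <= tol_density:
            return {"a": float(a0), "density": rho0, "history": history}
    lo, hi = bracket
    f_lo = density_at(lo) - target_density
    f_hi = density_at(hi) - target_density
    history += [(lo, f_lo + target_density), (hi, f_hi + target_density)]
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            f"bracket ({lo}, {hi}) does not contain the target density: "
            f"rho({lo}) = {f_lo + target_density:.4f}, "
            f"rho({hi}) = {f_hi + target_density:.4f} g/cm^3"
        )
    while hi - lo > tol_a:
        mid = 0.5 * (lo + hi)
        f_mid = density_at(mid) - target_density
        history.append((mid, f_mid + target_density))
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    a_star = 0.5 * (lo + hi)
    return {"a": float(a_star), "density": history[-1][1], "history": history}


@dataclass
class BOConfig:
    """Batch-parallel Bayesian-optimization settings."""

    bounds: np.ndarray  # (d, 2)
    n_instances: int = 4
    betas: np.ndarray | None = None  # exploration parameter per instance
    n_replicates: int = 1
    n_init: int = 5
    n_rounds: int = 10
    n_candidates: int = 512
    seed: int = 0
    history_path: str | None = None

    def __post_init__(self):
        self.bounds = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if not np.all(np.isfinite(self.bounds)):
            raise ValueError("bounds must be finite")
        if self.betas is None:
            # log-spaced exploration parameters from exploitation to exploration
            self.betas = np.logspace(-3, 3, self.n_instances)
        self.betas = np.asarray(self.betas, dtype=float)
        if np.any(self.betas <= 0):
            raise ValueError("beta must be positive")
        if len(self.betas) != self.n_instances:
            raise ValueError("need one beta per instance")


@dataclass
class BOResult:
    best_x: np.ndarray
    best_value: float
    history: list = _field(default_factory=list)  # dicts: x, value, round, instance


def _fit_gp(X, y, seed):
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.ones(X.shape[1]), length_scale_bounds=(1e-2, 1e2), nu=2.5
    ) + WhiteKernel(1e-6, (1e-10, 1e1))
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True, random_state=seed)
    gp.fit(X, y)
    return gp


def bayes_opt(objective, config: BOConfig) -> BOResult:
    """Minimize a (possibly noisy) objective by batch-parallel GP-UCB.

    Every instance fits a Matern-5/2 GP surrogate to the shared evaluation
    pool and proposes the maximizer of (-mean + beta * sd) over a random
    candidate set, using its own exploration parameter beta.  Evaluations
    are averaged over ``n_replicates`` calls; failures are excluded with a
    warning.  Fully reproducible for a fixed seed.
    """
    import warnings

    rng = np.random.default_rng(config.seed)
    d = config.bounds.shape[0]
    lo, hi = config.bounds[:, 0], config.bounds[:, 1]
    history = []

    def evaluate(x, round_idx, instance):
        vals = []
        for rep in range(config.n_replicates):
            try:
                vals.append(float(objective(np.asarray(x))))
            except Exception as exc:  # noqa: BLE001 - objective is user code
                warnings.warn(f"objective evaluation failed: {exc}", stacklevel=2)
        if not vals:
            return None
        rec = {"x": list(map(float, x)), "value": float(np.mean(vals)),
               "round": round_idx, "instance": instance}
        history.append(rec)
        if config.history_path:
            with open(config.history_path, "a") as fh:
                fh.write(json.dumps(rec) + "\n")
        return rec

    for i in range(config.n_init):
        evaluate(rng.uniform(lo, hi), -1, i % config.n_instances)

    for rnd in range(config.n_rounds):
        X = np.array([h["x"] for h in history])
        y = np.array([h["value"] for h in history])
        proposals = []
        for inst in range(config.n_instances):
            gp = _fit_gp(X, y, seed=config.seed + rnd)
            cand = rng.uniform(lo, hi, (config.n_candidates, d))
            best = X[np.argmin(y)]
            local = np.clip(best + 0.05 * (hi - lo) * rng.standard_normal((32, d)), lo, hi)
            cand = np.vstack([cand, local])
            mean, sd = gp.predict(cand, return_std=True)
            acq = -mean + config.betas[inst] * sd
            proposals.append(cand[int(np.argmax(acq))])
        for inst, x in enumerate(proposals):
            evaluate(x, rnd, inst)  # shared pool: visible to the next round

    if not history:
        raise RuntimeError("no successful evaluations")
    best = min(history, key=lambda h: h["value"])
    return BOResult(np.asarray(best["x"]), best["value"], history)
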