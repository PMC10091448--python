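# Methods

## Model

`pfmd` simulates coarse-grained beads whose nonbonded interactions enter through
a functional of filtered number densities. Each configuration is deposited on a
regular mesh with cloud-in-cell (trilinear) weights; the raw per-type grids are
convolved with a Gaussian of spread σ_t (spectrally, transfer function
exp(−k²σ²/2)), giving filtered densities φ̃_t in nm⁻³. The local energy density
is

    w({φ̃}) = (1/2ρ₀) [ Σ_lm χ̃_lm φ̃_l φ̃_m + (1/κ)(Σ_l φ̃_l − a)² ]

and W = Σ_cells w·ΔV. The χ̃ term drives mixing/demixing between types; the κ
term penalizes deviations of the total density from the offset *a*, acting as a
soft equation of state. Because two Gaussian-filtered clouds interact through
their overlap, the model is equivalent to beads coupled by a Gaussian pair
kernel of variance 2σ² (plus, on a finite mesh, h²/3 per axis from the two
assignment windows; this correction vanishes under mesh refinement and is used
by the pair-force test oracle).

Intramolecular structure uses harmonic bonds U = ½k_b(r−r₀)² and
harmonic-cosine angles U = ½k_a(cosθ−cosθ₀)², with minimum-image displacements
and cosθ clamped to [−1, 1] for degenerate geometries.

### Units and defaults

Internal units: nm, ps, g/mol, kJ/mol, K; k_B = 0.00831446 kJ mol⁻¹ K⁻¹;
pressures are converted to bar (×16.6054) at reporting boundaries. Default bead
mass 72 g/mol (four waters per bead); ρ₀ = 8.364 nm⁻³, the number density of
4:1-mapped water at 1 g/cm³. Default filter spread σ = 0.238 nm; default
κ = 0.05 mol/kJ with the matching calibrated a ≈ 9.21–9.26 nm⁻³. The default
mesh has cell spacing ≤ min σ_t, rounded up to FFT-friendly sizes; resolution
is a convergence parameter, guarded by the pair-force oracle. Boxes are
orthorhombic and periodic; shapes change only through barostat scaling.

## Pressure

The diagonal pressure tensor is assembled per Cartesian axis from

* kinetic: 2T_a/V;
* bonded: the virial Σ r_a F_a over bonds and angle triplets (relative vectors
  from the vertex for angles), which equals −L_a ∂U/∂L_a under affine scaling;
* field: differentiating W with respect to one box length at fixed fractional
  coordinates. The mesh quadrature weight contributes −W/V plus
  ∫(∂w/∂φ̃_t)φ̃_t; the filter's transfer function depends on L_a through the
  wave vectors and contributes the anisotropic part
  ∫(∂w/∂φ̃_t)·σ_t²·∂²φ̃_t/∂a², with the second derivative evaluated spectrally
  (−k_a² multiplication).

The implementation is validated by a finite-difference virial oracle (scale one
box length by 1±ε at fixed fractional coordinates, recompute the total
potential energy, compare −(L_a/V)∂E/∂L_a per axis); agreement is at the
10⁻¹¹ level, i.e. the analytic pressure is the exact derivative of the discrete
energy. In homogeneous systems the anisotropic term vanishes; at interfaces it
produces the extra normal pressure responsible for surface tension.

Lateral pressure profiles are slab-resolved along a chosen axis: field terms
from the local integrand of the field pressure collapsed onto slabs, kinetic
terms from the particles in each slab, bonded virials attributed to the slab of
the interaction midpoint (a Harasima-like convention chosen because it keeps
the profile's integral exactly consistent with the global tensor, which is the
testable contract; Irving–Kirkwood contours are out of scope).

## Forces

The force on a bead is obtained from the external potential V_t (the filtered
functional derivative of w). Two interpolation paths are provided:

* `cic-grad` (default): differentiate the trilinear interpolant of V_t
  analytically. This makes F_i = −∂W/∂r_i *exactly* on the mesh (central
  differences of W agree to ~10⁻⁶ relative, limited by floating-point
  cancellation), so the sampled ensemble is Boltzmann-consistent with the same
  W that the pressure differentiates.
* `spectral`: interpolate the spectrally differentiated gradient grids with the
  plain CIC weights. This conserves total momentum exactly but is not the exact
  gradient of the discrete W.

With `cic-grad` the small net artifact force (mesh breaking of continuous
translation invariance) is removed by subtracting the mean force each step
(`remove_net_force=True`).

## Dynamics

Integration is reversible rRESPA: a half-kick with field forces at Δt₁, an
inner velocity-Verlet loop with bonded forces at Δt₂ = Δt₁/n, a final field
half-kick. Defaults Δt₁ = 0.3 ps, Δt₂ = 0.03 ps. With the thermostat off the
scheme shows no secular energy drift (the shadow-energy oscillation at these
steps is ~0.5% for a stiff dimer, which is why conservation is asserted on
early-versus-late time averages rather than instantaneous values).

Temperature: CSVR thermostat — deterministic relaxation of the kinetic energy
toward n_dof k_B T/2 plus the stochastic term that makes the sampled kinetic
energy Gamma(n_dof/2)-distributed; n_dof = 3N−3 (center-of-mass momentum is
removed at initialization only). Default τ = 0.1 ps.

Pressure: Berendsen scaling μ_a = [1 − (Δt/τ_P)β(P₀ − P_a)]^{1/3} per coupling
group (isotropic; semi-isotropic with x,y jointly and z independent;
constant-area with z only), or SCR — the same relaxation in log-volume plus a
Wiener term of variance 2k_BTβΔt/(Vτ_P), which yields correct NPT sampling
(verified against the exact ideal-gas ⟨V⟩ and volume fluctuations). Defaults
τ_P = 1.0 ps, β = 4.6×10⁻⁵ bar⁻¹ (water); a warning is issued if τ_P < τ.
Scale factors outside [0.95, 1.05] are clamped with a warning as a spike guard.
The pressure decomposition is evaluated at every outer step, before the
thermostat/barostat updates, and the barostat preserves fractional coordinates
exactly.

## Observables

* Surface tension: γ = (L_n/2)(P_N − P_L) with P_L the mean of the two lateral
  axes; 1 bar·nm = 0.1 mN/m. The ½ accounts for the two interfaces of a
  periodic slab.
* Area per lipid: lateral area / lipids per leaflet.
* Area compressibility: least-squares fit of ⟨γ⟩ = K̄(A_L − A_L0)/A_L0 over
  constant-area runs (linear in the transformed parameters; K̄ and the
  tensionless A_L0 are recovered from slope and intercept).
* Membrane surface: marker beads (the glycerol "G" bead by convention) are
  binned on an (x,y) grid; leaflets are split by the local midplane (per-bin
  mean marker height — robust for undulating membranes), u = (z_up+z_down)/2,
  empty bins filled by periodic neighbor interpolation; an error is raised if
  a leaflet is empty in more than 10% of bins (grid too fine).
* Undulation spectrum: S_u(q) = N_lip⟨|ũ(q)|²⟩ with ũ the Fourier-series
  coefficients of u, radially shell-averaged, so the Helfrich prediction is
  S_u(q) = k_BT/(A_L K_c q⁴). K_c comes from a free-slope straight-line fit of
  log S_u vs log q over the first 11 wave numbers (q ≲ 1 nm⁻¹, below the
  protrusion regime), evaluating the Helfrich amplitude over the fitted window
  (geometric mean). The normalization and fit space are validated by a
  recovery oracle on synthetic surfaces drawn from the Helfrich distribution
  with known modulus (recovered within a few percent) and by Parseval
  consistency between Var(u) and the multiplicity-weighted spectrum.

## Parametrization

* `calibrate_a` bisects on *a* until a seeded homogeneous NPT run (1171 beads,
  5.2³ nm start) reproduces 1 g/cm³. Density is monotone in *a*, so bisection
  is safe; each evaluation defaults to 1 ns with the first 100 ps discarded
  (the acceptance script uses 450 ps evaluations, which the density-estimate
  noise of ~10⁻³ g/cm³ comfortably supports).
* Fitness for χ̃ optimization: η = Σ_types mean over bins of
  2|φ−φ^ref|/(φ+φ^ref) (fraction-convention SMAPE; bins with φ = φ^ref = 0
  contribute zero) plus the squared error of A_L against 0.63 nm². The SMAPE
  term is scale-free; the area term carries nm⁴.
* `bayes_opt` is batch-parallel GP-UCB: each instance fits a Matérn-5/2 GP
  (automatic length scales, white-noise term) to the *shared* evaluation pool
  and proposes the maximizer of −mean + β·sd over a random candidate set plus
  local jitter around the incumbent; β is log-spaced over [10⁻³, 10³] across
  instances (exploitation to exploration). Objective evaluations are averaged
  over replicates; failures are excluded with a warning; the history is
  JSON-lines persistable and the whole trace is seed-reproducible. A full
  lipid χ̃ campaign is cluster-scale and is deliberately a recipe (plug a
  bilayer-simulation fitness into `bayes_opt`), not a test; tests exercise the
  machinery on analytic objectives.

## Synthetic systems

Builders generate the study systems: a 1171-bead homogeneous fluid in 5.2³ nm;
a two-species slab-initialized immiscible mixture (χ̃_AB = 36 kJ/mol by
default); and a lamellar bilayer of 12-bead lipids (3-bead head N–P–G, second
G, two 4-bead C tails) on a per-leaflet lattice with tails inward, optional
10-bead triglycerides between the leaflets, and solvent filling the water
slabs. Bonded defaults (r₀ = 0.47 nm, k_b = 1250 kJ mol⁻¹ nm⁻², θ₀ = 180°,
k_a = 25 kJ/mol) and the lipid χ̃ matrix are documented placeholders of
Martini-like magnitude — sufficient to hold a lamellar phase and exercise every
observable, but not a validated lipid force field; real parametrizations are
supplied via config. Builder velocities are Maxwell–Boltzmann with the total
momentum removed.

What passing tests show — and don't: the synthetic systems validate the
statistical mechanics (pressure algebra, ensemble sampling, observable
definitions) at desk scale. They do not demonstrate quantitative lipid
thermodynamics (experimental A_L, K̄, K_c), which requires optimized χ̃
parameters and 100-ns runs of 10⁴–10⁶-particle systems; those remain
long-running recipes supported by, but not exercised in, the test suite.

## Numerical choices and limitations

* Mesh sizes are products of 2/3/5; spectral operations use real FFTs.
* Gaussian filtering leaves the k = 0 mode untouched, so filtering conserves
  mass to ~10⁻¹⁰ relative; tiny negative ringing (≲10⁻⁸ of the maximum) is
  tolerated.
* Problem sizes in tests and the acceptance script (≈0.5-ns calibration
  evaluations, ~2000-particle capillary, 64-lipid bilayer) were chosen as the
  smallest systems for which the measured quantities are statistically
  decisive; all are seeded and deterministic on one platform.
* Out of scope: electrostatics, triclinic boxes, dihedrals/constraints,
  Parrinello–Rahman/Nosé–Hoover coupling, higher-order assignment windows,
  Irving–Kirkwood local pressure, MPI/GPU parallelism.
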