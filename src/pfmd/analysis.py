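"""Membrane and interfacial observables.

Covers per-type density profiles, surface tension from the pressure
tensor, area compressibility from a series of constant-area runs, and
Helfrich undulation analysis (surface tracing, fluctuation spectrum,
bending modulus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import KB, ParticleState, SimulationBox
from .pressure import PressureDecomposition

__all__ = [
    "density_profile",
    "surface_tension",
    "area_compressibility",
    "area_per_lipid",
    "trace_surface",
    "undulation_spectrum",
    "MembraneSurface",
]

#: Boltzmann constant in J/K, for moduli reported in SI units.
KB_J = 1.380649e-23

#: bar * nm expressed in mN/m.
MN_PER_M_PER_BAR_NM = 0.1


def density_profile(frames, axis: int = 2, n_bins: int = 50, center: bool = False,
                    center_types=None):
    """Frame-averaged per-type number-density profiles along one axis (nm^-3).

    ``frames`` iterates over (ParticleState, SimulationBox).  With
    ``center=True`` each frame is shifted (periodically) so that the center
    of mass of ``center_types`` (default: all non-solvent beads) sits at
    the box middle before binning — useful for drifting bilayers.
    """
    acc = None
    n_frames = 0
    L = None
    type_names = None
    for state, box in frames:
        n_frames += 1
        L = box.lengths[axis]
        type_names = state.type_names
        z = state.positions[:, axis].copy()
        if center:
            sel = (
                np.isin(state.types, center_types)
                if center_types is not None
                else np.ones(state.n, dtype=bool)
            )
            if not np.any(sel):
                raise ValueError("empty selection for centering")
            # circular mean for a periodic coordinate
            ang = z[sel] / L * 2 * np.pi
            mid = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi) * L
            z = np.mod(z - mid + 0.5 * L, L)
        nt = state.n_types
        if acc is None:
            acc = np.zeros((nt, n_bins))
        slab_vol = box.volume / n_bins
        bins = np.clip((z / L * n_bins).astype(int), 0, n_bins - 1)
        for t in range(nt):
            acc[t] += np.bincount(bins[state.types == t], minlength=n_bins) / slab_vol
    if n_frames == 0:
        raise ValueError("no frames supplied")
    centers = (np.arange(n_bins) + 0.5) * L / n_bins
    return {"z": centers, "profiles": acc / n_frames, "type_names": list(type_names),
            "dz": L / n_bins}


def surface_tension(pressure, box: SimulationBox, normal_axis: int = 2) -> float:
    """Surface tension gamma = (L_n / 2) (P_N - P_L) in mN/m.

    ``pressure`` is a PressureDecomposition or a per-axis total in bar;
    P_L is the mean of the two lateral components.  The 1/2 accounts for
    the two interfaces a periodic slab geometry necessarily contains.
    """
    if isinstance(pressure, PressureDecomposition):
        p = pressure.per_axis
    else:
        p = np.asarray(pressure, dtype=float)
    lat = [a for a in range(3) if a != normal_axis]
    p_l = 0.5 * (p[lat[0]] + p[lat[1]])
    p_n = p[normal_axis]
    return 0.5 * box.lengths[normal_axis] * (p_n - p_l) * MN_PER_M_PER_BAR_NM


def area_per_lipid(box: SimulationBox, n_lipids_per_leaflet: int,
                   normal_axis: int = 2) -> float:
    """Lateral box area divided by lipids per leaflet (nm^2)."""
    if n_lipids_per_leaflet <= 0:
        raise ValueError("need at least one lipid per leaflet")
    lat = [a for a in range(3) if a != normal_axis]
    return float(box.lengths[lat[0]] * box.lengths[lat[1]] / n_lipids_per_leaflet)


def area_compressibility(areas, tensions, tension_errors=None):
    """Stretching modulus from mean tension versus area per lipid.

    Least-squares fit of <gamma> = Kbar (A_L - A_L0)/A_L0 over constant-area
    runs.  Returns (Kbar, A_L0, Kbar_stderr); units follow the inputs
    (mN/m for tensions, nm^2 for areas).
    """
    A = np.asarray(areas, dtype=float)
    g = np.asarray(tensions, dtype=float)
    if len(A) < 3:
        raise ValueError("need at least three area points")
    if len(np.unique(A)) < 2:
        raise ValueError("area points are degenerate; fit is rank-deficient")
    w = None if tension_errors is None else 1.0 / np.asarray(tension_errors) ** 2
    # gamma = m A + b with Kbar = -b, A_L0 = -b/m
    (m, b), cov = np.polyfit(A, g, 1, w=w, cov="unscaled" if w is not None else True)
    if m == 0:
        raise ValueError("zero slope; cannot determine A_L0")
    kbar = -b
    a_l0 = -b / m
    return float(kbar), float(a_l0), float(np.sqrt(cov[1, 1]))


@dataclass
class MembraneSurface:
    """Gridded mid-surface u(x, y) of a bilayer for one frame (nm)."""

    u: np.ndarray
    lateral_lengths: tuple  # (Lx, Ly) nm


def _fill_periodic(grid, filled):
    """Fill empty bins by iterative periodic neighbor averaging."""
    g = grid.copy()
    todo = ~filled
    while np.any(todo):
        neigh_sum = np.zeros_like(g)
        neigh_cnt = np.zeros(g.shape)
        have = ~todo
        for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            neigh_sum += np.roll(np.where(have, g, 0.0), shift, axis=(0, 1))
            neigh_cnt += np.roll(have.astype(float), shift, axis=(0, 1))
        fillable = todo & (neigh_cnt > 0)
        if not np.any(fillable):  # pragma: no cover - fully empty grid
            raise ValueError("surface grid has no occupied bins")
        g[fillable] = neigh_sum[fillable] / neigh_cnt[fillable]
        todo = todo & ~fillable
    return g


def trace_surface(positions, box: SimulationBox, grid_shape=(16, 16),
                  normal_axis: int = 2, max_empty_frac: float = 0.10) -> MembraneSurface:
    """Trace the bilayer mid-surface from marker-bead (G) positions.

    Beads are binned on an (x, y) grid; each bin's local midplane is the
    mean marker height, and beads above/below it form the upper/lower
    leaflet.  u = (z_up + z_down)/2 per bin; bins left empty by one leaflet
    are filled by periodic neighbor interpolation, but if more than
    ``max_empty_frac`` of bins lack a leaflet the grid is too fine and an
    error is raised.
    """
    pos = np.asarray(positions, dtype=float)
    lat = [a for a in range(3) if a != normal_axis]
    nx, ny = grid_shape
    ix = np.clip((pos[:, lat[0]] / box.lengths[lat[0]] * nx).astype(int), 0, nx - 1)
    iy = np.clip((pos[:, lat[1]] / box.lengths[lat[1]] * ny).astype(int), 0, ny - 1)
    z = pos[:, normal_axis]
    flat = ix * ny + iy
    cnt = np.bincount(flat, minlength=nx * ny).astype(float)
    zsum = np.bincount(flat, weights=z, minlength=nx * ny)
    with np.errstate(invalid="ignore"):
        midplane = np.where(cnt > 0, zsum / np.maximum(cnt, 1), np.nan)
    global_mid = z.mean()
    midplane = np.where(np.isnan(midplane), global_mid, midplane)
    upper = z >= midplane[flat]
    surf = {}
    for name, sel in (("up", upper), ("down", ~upper)):
        c = np.bincount(flat[sel], minlength=nx * ny).astype(float)
        s = np.bincount(flat[sel], weights=z[sel], minlength=nx * ny)
        filled = c > 0
        if np.mean(~filled) > max_empty_frac:
            raise ValueError(
                f"{name} leaflet empty in {np.mean(~filled):.0%} of bins; use a coarser grid"
            )
        g = np.where(filled, s / np.maximum(c, 1), 0.0).reshape(nx, ny)
        surf[name] = _fill_periodic(g, filled.reshape(nx, ny))
    u = 0.5 * (surf["up"] + surf["down"])
    return MembraneSurface(u, (box.lengths[lat[0]], box.lengths[lat[1]]))


def undulation_spectrum(surfaces, n_lipids_per_leaflet: int, temperature: float,
                        n_fit: int = 11):
    """Radially binned fluctuation spectrum S_u(q) and bending modulus K_c.

    S_u(q) = N_lip <|u(q)|^2> with u(q) the Fourier-series coefficients of
    the mid-surface, so that the Helfrich continuum prediction reads
    S_u(q) = k_B T / (A_L K_c q^4).  K_c (J) is obtained from a free-slope
    straight-line fit of log S_u against log q over the first ``n_fit``
    wave numbers (q below ~1 nm^-1 for the systems of interest), evaluating
    the Helfrich amplitude over the fitted window.
    """
    surfaces = list(surfaces)
    if not surfaces:
        raise ValueError("no surfaces supplied")
    lx, ly = surfaces[0].lateral_lengths
    nx, ny = surfaces[0].u.shape
    qx = 2 * np.pi * np.fft.fftfreq(nx, d=lx / nx)
    qy = 2 * np.pi * np.fft.fftfreq(ny, d=ly / ny)
    qmag = np.sqrt(qx[:, None] ** 2 + qy[None, :] ** 2)
    power = np.zeros((nx, ny))
    for s in surfaces:
        du = s.u - s.u.mean()
        uq = np.fft.fft2(du) / (nx * ny)
        power += np.abs(uq) ** 2
    power /= len(surfaces)
    # radial shells on distinct |q| magnitudes
    qr = np.round(qmag, 9).ravel()
    pw = power.ravel()
    qs, inverse = np.unique(qr, return_inverse=True)
    s_u = np.bincount(inverse, weights=pw) / np.bincount(inverse)
    keep = qs > 0
    qs, s_u = qs[keep], s_u[keep] * n_lipids_per_leaflet
    n_avail = min(n_fit, len(qs))
    if n_avail < n_fit:
        import warnings

        warnings.warn(f"only {n_avail} q values available for the spectral fit", stacklevel=2)
    qw, sw = qs[:n_avail], s_u[:n_avail]
    if np.any(sw <= 1e-300):
        # degenerate (e.g. perfectly flat or single-mode) spectra carry no
        # fittable Helfrich amplitude
        import warnings

        warnings.warn("non-positive spectral values in the fit window; "
                      "no Helfrich fit performed", stacklevel=2)
        return {"q": qs, "S_u": s_u, "K_c": np.inf, "slope": np.nan,
                "n_fit": 0}
    c1, c0 = np.polyfit(np.log(qw), np.log(sw), 1)
    a_l = lx * ly / n_lipids_per_leaflet
    s_fit = np.exp(c0 + c1 * np.log(qw))
    kc_q = KB_J * temperature / (a_l * s_fit * qw**4)
    kc = float(np.exp(np.mean(np.log(kc_q))))
    return {"q": qs, "S_u": s_u, "K_c": kc, "slope": float(c1), "n_fit": n_avail}
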