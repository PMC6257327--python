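"""Implicit-solvent solvation energy: polar (PB or GB) + nonpolar (SASA-linear).

The polar reference engine solves the finite-difference linear
Poisson–Boltzmann equation on a uniform grid: trilinear charge spreading,
a two-dielectric map (eps_in inside the probe-inflated van der Waals region,
eps_out elsewhere, harmonic averaging on cell faces), Debye–Hückel boundary
potentials, and a preconditioned conjugate-gradient solve.  The reaction-field
energy is the difference between the heterogeneous-dielectric solve and a
uniform eps_in solve on the same grid, so the grid self-energy cancels.

The fast alternative is a generalized Born model: Hawkins–Cramer–Truhlar
pairwise-descreening effective radii in the Still equation.

The nonpolar term is gamma * SASA + beta with the classic MM-PBSA
parameterization (gamma = 0.00542 kcal/mol/Å², beta = 0.92 kcal/mol); SASA
comes from a deterministic golden-spiral Shrake–Rupley sampler.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg

from .constants import K_E
from .model_io import ForceField, Frame, Selection

__all__ = [
    "SolvationConfig",
    "ConvergenceError",
    "sphere_points",
    "shrake_rupley_sasa",
    "nonpolar_solvation",
    "pb_polar_solvation",
    "gb_polar_solvation",
    "gb_effective_radii",
    "polar_solvation",
    "solvation_energy",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolvationConfig:
    eps_in: float = 1.0
    eps_out: float = 80.0
    grid_spacing: float = 0.5      # Å
    grid_padding: float = 12.0     # Å
    probe_radius: float = 1.4      # Å
    gamma: float = 0.00542         # kcal/mol/Å²
    beta: float = 0.92             # kcal/mol
    n_sphere_points: int = 960
    engine: str = "gb"             # "pb" (reference) or "gb" (fast)
    ionic_strength: float = 0.0    # mol/L
    pb_tol: float = 1e-8
    pb_max_iter: int = 20000

    def __post_init__(self):
        if not (self.eps_out >= self.eps_in >= 1.0):
            raise ValueError("require eps_out >= eps_in >= 1")
        if self.grid_spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.engine not in ("pb", "gb"):
            raise ValueError(f"unknown polar engine {self.engine!r}")


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere point set (n, 3)."""
    k = np.arange(n, dtype=float)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * math.pi * k / phi
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def shrake_rupley_sasa(
    frame: Frame, selection: Selection, ff: ForceField,
    cfg: SolvationConfig = SolvationConfig(),
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (Å²) of the selection.

    Only atoms inside the selection occlude each other, so monomer areas are
    computed on the isolated monomer, as the thermodynamic cycle requires.
    """
    if cfg.n_sphere_points < 10:
        raise ValueError("n_sphere_points must be at least 10")
    idx = selection.atom_indices
    coords = frame.coordinates[idx]
    radii = ff.intrinsic_radius[idx] + cfg.probe_radius
    n = idx.size
    unit = sphere_points(cfg.n_sphere_points)
    areas = np.zeros(n)
    if n == 0:
        return areas
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    for i in range(n):
        cutoff2 = (radii[i] + radii) ** 2
        nb = np.where((d2[i] < cutoff2) & (np.arange(n) != i))[0]
        pts = coords[i] + radii[i] * unit
        if nb.size:
            dd = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(-1)
            accessible = np.all(dd >= radii[nb][None, :] ** 2, axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * frac
    return areas


def nonpolar_solvation(total_sasa: float, cfg: SolvationConfig = SolvationConfig()) -> float:
    """Cavity/dispersion term, linear in SASA: gamma * SASA + beta."""
    if total_sasa < 0:
        raise ValueError("SASA must be non-negative")
    return cfg.gamma * total_sasa + cfg.beta


# ---------------------------------------------------------------------------
# finite-difference linear Poisson–Boltzmann
# ---------------------------------------------------------------------------

def _debye_kappa(cfg: SolvationConfig) -> float:
    """Inverse Debye length in 1/Å for a 1:1 salt at 298 K."""
    if cfg.ionic_strength <= 0:
        return 0.0
    return math.sqrt(cfg.ionic_strength) / 3.047


def _grid_axes(coords: np.ndarray, cfg: SolvationConfig):
    h = cfg.grid_spacing
    lo = coords.min(axis=0) - cfg.grid_padding
    hi = coords.max(axis=0) + cfg.grid_padding
    ns = np.maximum(np.ceil((hi - lo) / h).astype(int) + 1, 2)
    axes = [lo[d] + h * np.arange(ns[d]) for d in range(3)]
    return axes, ns


def _spread_charges(coords, q, axes, ns, h):
    """Trilinear (cloud-in-cell) charge assignment onto grid nodes."""
    grid = np.zeros(tuple(ns))
    for x, qi in zip(coords, q):
        if qi == 0.0:
            continue
        f = [(x[d] - axes[d][0]) / h for d in range(3)]
        i0 = [int(math.floor(f[d])) for d in range(3)]
        w = [f[d] - i0[d] for d in range(3)]
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wt = ((w[0] if dx else 1 - w[0])
                          * (w[1] if dy else 1 - w[1])
                          * (w[2] if dz else 1 - w[2]))
                    grid[i0[0] + dx, i0[1] + dy, i0[2] + dz] += qi * wt
    return grid


def _dielectric_map(coords, radii, axes, ns, cfg) -> np.ndarray:
    """eps at nodes: eps_in within any probe-inflated atom sphere, else eps_out."""
    eps = np.full(tuple(ns), cfg.eps_out)
    h = cfg.grid_spacing
    for x, r in zip(coords, radii):
        rr = r + cfg.probe_radius
        lo = [max(int(math.floor((x[d] - rr - axes[d][0]) / h)), 0) for d in range(3)]
        hi = [min(int(math.ceil((x[d] + rr - axes[d][0]) / h)) + 1, ns[d])
              for d in range(3)]
        ax = [axes[d][lo[d]:hi[d]] - x[d] for d in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        sub = eps[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[d2 <= rr * rr] = cfg.eps_in
    return eps


def _boundary_potential(points, coords, q, eps, kappa):
    """Screened-Coulomb Dirichlet values at given points."""
    phi = np.zeros(len(points))
    for x, qi in zip(coords, q):
        if qi == 0.0:
            continue
        r = np.linalg.norm(points - x, axis=1)
        r = np.maximum(r, 1e-6)
        phi += K_E * qi * np.exp(-kappa * r) / (eps * r)
    return phi


def _solve_grid(eps_nodes, rho, axes, ns, cfg, coords, q, eps_boundary, kappa):
    """CG solve of the 7-point variable-coefficient Laplacian; returns phi grid."""
    h = cfg.grid_spacing
    nx, ny, nz = (int(v) for v in ns)
    shape = (nx, ny, nz)
    n_total = nx * ny * nz

    interior = np.zeros(shape, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    int_flat = np.flatnonzero(interior.ravel())
    n_int = int_flat.size
    order = np.full(n_total, -1, dtype=np.int64)
    order[int_flat] = np.arange(n_int)

    # boundary Dirichlet values
    phi = np.zeros(shape)
    bmask = ~interior
    bidx = np.argwhere(bmask)
    bpts = np.column_stack([axes[d][bidx[:, d]] for d in range(3)])
    phi[bmask] = _boundary_potential(bpts, coords, q, eps_boundary, kappa)

    # face dielectrics: harmonic mean of node eps along each axis
    def face(axis):
        a = eps_nodes
        sl1 = [slice(None)] * 3
        sl2 = [slice(None)] * 3
        sl1[axis] = slice(0, -1)
        sl2[axis] = slice(1, None)
        return 2.0 * a[tuple(sl1)] * a[tuple(sl2)] / (a[tuple(sl1)] + a[tuple(sl2)])

    fx, fy, fz = face(0), face(1), face(2)

    strides = (ny * nz, nz, 1)
    diag = np.zeros(n_int)
    rows, cols, vals = [], [], []
    rhs = 4.0 * math.pi * K_E * rho.ravel()[int_flat] / h

    if kappa > 0.0:
        solvent = eps_nodes.ravel()[int_flat] >= cfg.eps_out - 1e-12
        diag += np.where(solvent, cfg.eps_out * (kappa * h) ** 2, 0.0)

    for axis, fe in ((0, fx), (1, fy), (2, fz)):
        for sign in (-1, 1):
            # face between node and its neighbour in this direction
            idx3 = np.unravel_index(int_flat, shape)
            fi = list(idx3)
            if sign < 0:
                fi[axis] = fi[axis] - 1
            eps_face = fe[tuple(fi)]
            diag += eps_face
            nb_flat = int_flat + sign * strides[axis]
            nb_order = order[nb_flat]
            is_int = nb_order >= 0
            rows.append(np.arange(n_int)[is_int])
            cols.append(nb_order[is_int])
            vals.append(-eps_face[is_int])
            # Dirichlet neighbour -> move to RHS
            if np.any(~is_int):
                rhs_add = np.zeros(n_int)
                rhs_add[~is_int] = eps_face[~is_int] * phi.ravel()[nb_flat[~is_int]]
                rhs += rhs_add

    a_mat = sparse.csr_matrix(
        (np.concatenate(vals + [diag]),
         (np.concatenate(rows + [np.arange(n_int)]),
          np.concatenate(cols + [np.arange(n_int)]))),
        shape=(n_int, n_int),
    )
    m_inv = 1.0 / diag
    precond = LinearOperator((n_int, n_int), matvec=lambda v: m_inv * v)
    x, info = cg(a_mat, rhs, rtol=cfg.pb_tol, atol=0.0, maxiter=cfg.pb_max_iter,
                 M=precond)
    if info != 0:
        resid = float(np.linalg.norm(a_mat @ x - rhs) / max(np.linalg.norm(rhs), 1e-300))
        raise ConvergenceError(
            f"PB solver did not converge in {cfg.pb_max_iter} iterations "
            f"(relative residual {resid:.3e})"
        )
    phi.ravel()[int_flat] = x
    return phi


def _interp_at(points, phi, axes, h):
    vals = np.zeros(len(points))
    ns = phi.shape
    for k, x in enumerate(points):
        f = [(x[d] - axes[d][0]) / h for d in range(3)]
        i0 = [int(math.floor(f[d])) for d in range(3)]
        for d in range(3):
            if not (0 <= i0[d] < ns[d] - 1):
                raise ValueError("atom outside the PB grid")
        w = [f[d] - i0[d] for d in range(3)]
        acc = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wt = ((w[0] if dx else 1 - w[0])
                          * (w[1] if dy else 1 - w[1])
                          * (w[2] if dz else 1 - w[2]))
                    acc += wt * phi[i0[0] + dx, i0[1] + dy, i0[2] + dz]
        vals[k] = acc
    return vals


def pb_polar_solvation(
    frame: Frame, selection: Selection, ff: ForceField,
    cfg: SolvationConfig = SolvationConfig(), return_grid: bool = False,
):
    """Finite-difference linear-PB reaction-field energy (kcal/mol).

    Delta-G_pol = 1/2 sum_i q_i (phi_i[eps map] - phi_i[uniform eps_in]); both
    potentials come from the same grid so the self-energy artefacts cancel.
    """
    idx = selection.atom_indices
    coords = frame.coordinates[idx]
    q = ff.charges[idx]
    radii = ff.intrinsic_radius[idx]
    if not np.any(q):
        return (0.0, None) if return_grid else 0.0
    if cfg.eps_out == cfg.eps_in:
        return (0.0, None) if return_grid else 0.0

    axes, ns = _grid_axes(coords, cfg)
    h = cfg.grid_spacing
    rho = _spread_charges(coords, q, axes, ns, h)
    eps_map = _dielectric_map(coords, radii, axes, ns, cfg)
    kappa = _debye_kappa(cfg)

    phi_het = _solve_grid(eps_map, rho, axes, ns, cfg, coords, q,
                          eps_boundary=cfg.eps_out, kappa=kappa)
    eps_hom = np.full(tuple(ns), cfg.eps_in)
    phi_hom = _solve_grid(eps_hom, rho, axes, ns, cfg, coords, q,
                          eps_boundary=cfg.eps_in, kappa=0.0)
    dphi = phi_het - phi_hom
    energy = 0.5 * float(np.dot(q, _interp_at(coords, dphi, axes, h)))
    if return_grid:
        return energy, (dphi, axes)
    return energy


def write_dx(grid_and_axes, path) -> None:
    """Dump a scalar grid (e.g. the reaction-field potential) as OpenDX."""
    from gridData import Grid

    grid, axes = grid_and_axes
    origin = [float(a[0]) for a in axes]
    delta = [float(a[1] - a[0]) for a in axes]
    Grid(grid, origin=origin, delta=delta).export(str(path), file_format="dx")


# ---------------------------------------------------------------------------
# generalized Born
# ---------------------------------------------------------------------------

def gb_effective_radii(coords: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """HCT pairwise-descreening effective Born radii (Å)."""
    n = len(coords)
    if n == 1:
        return radii.astype(float).copy()
    r = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(r, np.inf)  # self term excluded
    rho_i = radii[:, None]
    rho_j = radii[None, :]
    live = r + rho_j > rho_i  # neighbour not fully buried inside atom i
    lower = np.maximum(np.abs(r - rho_j), rho_i)
    upper = r + rho_j
    with np.errstate(divide="ignore", invalid="ignore"):
        term = (
            (1.0 / lower - 1.0 / upper)
            + (r / 4.0) * (1.0 / upper ** 2 - 1.0 / lower ** 2)
            + (1.0 / (2.0 * r)) * np.log(lower / upper)
            + (rho_j ** 2 / (4.0 * r)) * (1.0 / lower ** 2 - 1.0 / upper ** 2)
        )
    term = np.where(live & np.isfinite(term), term, 0.0)
    inv = 1.0 / radii - 0.5 * term.sum(axis=1)
    if np.any(inv <= 0):
        raise ValueError("non-positive effective Born radius (overlapping atoms?)")
    return 1.0 / inv


def gb_polar_solvation(
    frame: Frame, selection: Selection, ff: ForceField,
    cfg: SolvationConfig = SolvationConfig(),
) -> float:
    """Still-equation GB reaction-field energy (kcal/mol)."""
    idx = selection.atom_indices
    q = ff.charges[idx]
    if not np.any(q):
        return 0.0
    if cfg.eps_out == cfg.eps_in:
        return 0.0
    coords = frame.coordinates[idx]
    a = gb_effective_radii(coords, ff.intrinsic_radius[idx])
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    aa = np.outer(a, a)
    f_gb = np.sqrt(d2 + aa * np.exp(-d2 / (4.0 * aa)))
    qq = np.outer(q, q)
    pref = -0.5 * K_E * (1.0 / cfg.eps_in - 1.0 / cfg.eps_out)
    return float(pref * (qq / f_gb).sum())


def polar_solvation(frame, selection, ff, cfg: SolvationConfig = SolvationConfig()):
    if cfg.engine == "pb":
        return pb_polar_solvation(frame, selection, ff, cfg)
    return gb_polar_solvation(frame, selection, ff, cfg)


def solvation_energy(
    frame: Frame, selection: Selection, ff: ForceField,
    cfg: SolvationConfig = SolvationConfig(),
) -> float:
    """E_sol = polar (selected engine) + gamma*SASA + beta."""
    sasa = float(shrake_rupley_sasa(frame, selection, ff, cfg).sum())
    return polar_solvation(frame, selection, ff, cfg) + nonpolar_solvation(sasa, cfg)
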